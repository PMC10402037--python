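"""Brain-structure hierarchy: an Allen-structure-graph style tree of ROIs.

The atlas is a rooted tree of named structures. Two regions "overlap
anatomically" exactly when one is an ancestor of the other; sibling
structures never overlap. This is the semantics used by the exclusive
ROI selection step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StructureNode:
    """One atlas structure: integer id, short acronym, long name, parent id."""

    id: int
    acronym: str
    name: str
    parent_id: int | None


class AtlasHierarchy:
    """Rooted tree of brain structures with ancestor/descendant queries.

    Invariants enforced on construction: unique ids and acronyms, exactly
    one root (``parent_id is None``), every parent id resolves, no cycles.
    """

    def __init__(self, nodes: Iterable[StructureNode]):
        self.nodes = list(nodes)
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate structure ids in atlas")
        acros = [n.acronym for n in self.nodes]
        if len(set(acros)) != len(acros):
            raise ValueError("duplicate acronyms in atlas")
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"atlas must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._by_id = {n.id: n for n in self.nodes}
        self._by_acronym = {n.acronym: n for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None and n.parent_id not in self._by_id:
                raise ValueError(f"node {n.acronym} has unknown parent id {n.parent_id}")
        # depth computation doubles as the cycle check
        self._depth: dict[str, int] = {}
        for n in self.nodes:
            seen, cur, d = set(), n, 0
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValueError(f"cycle detected at structure {n.acronym}")
                seen.add(cur.id)
                cur = self._by_id[cur.parent_id]
                d += 1
                if d > len(self.nodes):
                    raise ValueError(f"cycle detected at structure {n.acronym}")
            self._depth[n.acronym] = d

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._by_acronym

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def acronyms(self) -> list[str]:
        return [n.acronym for n in self.nodes]

    def depth(self, acronym: str) -> int:
        self._require(acronym)
        return self._depth[acronym]

    def ancestors(self, acronym: str) -> list[str]:
        """Acronyms of all strict ancestors, nearest first, root last."""
        self._require(acronym)
        out = []
        cur = self._by_acronym[acronym]
        while cur.parent_id is not None:
            cur = self._by_id[cur.parent_id]
            out.append(cur.acronym)
        return out

    def leaves(self) -> list[str]:
        parents = {n.parent_id for n in self.nodes if n.parent_id is not None}
        return [n.acronym for n in self.nodes if n.id not in parents]

    def children(self, acronym: str) -> list[str]:
        self._require(acronym)
        pid = self._by_acronym[acronym].id
        return [n.acronym for n in self.nodes if n.parent_id == pid]

    def relation(self, a: str, b: str) -> str:
        """Relation of ``a`` to ``b``: same | ancestor | descendant | unrelated."""
        self._require(a)
        self._require(b)
        if a == b:
            return "same"
        if a in self.ancestors(b):
            return "ancestor"
        if b in self.ancestors(a):
            return "descendant"
        return "unrelated"

    def _require(self, acronym: str) -> None:
        if acronym not in self._by_acronym:
            raise KeyError(f"unknown structure acronym: {acronym!r}")

    # ---- I/O (Allen structure-graph field names) ----

    def to_records(self) -> list[dict]:
        return [
            {
                "id": n.id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_structure_id": n.parent_id,
            }
            for n in self.nodes
        ]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "AtlasHierarchy":
        return cls(
            StructureNode(
                id=int(r["id"]),
                acronym=str(r["acronym"]),
                name=str(r.get("name", r["acronym"])),
                parent_id=None
                if r.get("parent_structure_id") is None
                else int(r["parent_structure_id"]),
            )
            for r in records
        )

    @classmethod
    def from_json(cls, path) -> "AtlasHierarchy":
        with open(path) as fh:
            return cls.from_records(json.load(fh))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_records())


def is_related(atlas: AtlasHierarchy, a: str, b: str) -> str:
    """Relation of unit ``a`` to unit ``b`` in the structure tree."""
    return atlas.relation(a, b)


def generate_atlas(n_leaves: int, depth: int, seed: int = 0) -> AtlasHierarchy:
    """Generate a random but valid structure hierarchy.

    ``depth`` is the number of levels below the root; leaves sit at the
    deepest level. Level widths interpolate geometrically between 1 and
    ``n_leaves`` so the tree branches gradually, like a real atlas
    ontology. Deterministic given ``seed``.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [StructureNode(id=1, acronym="root", name="root", parent_id=None)]
    next_id = 2
    prev_level = [1]
    for level in range(1, depth + 1):
        if level == depth:
            width = n_leaves
        else:
            width = max(1, min(n_leaves, round(n_leaves ** (level / depth))))
        # keep widths non-decreasing and give every node of the previous
        # level at least one child, so no internal node is accidentally a leaf
        width = max(width, len(prev_level))
        parents = list(prev_level) + [
            int(rng.choice(prev_level)) for _ in range(width - len(prev_level))
        ]
        rng.shuffle(parents)
        level_ids = []
        for i in range(width):
            parent = parents[i]
            if level == depth:
                acro = f"L{i:04d}"
                name = f"leaf structure {i}"
            else:
                acro = f"N{level}_{i:03d}"
                name = f"internal structure {level}.{i}"
            nodes.append(StructureNode(id=next_id, acronym=acro, name=name, parent_id=parent))
            level_ids.append(next_id)
            next_id += 1
        prev_level = level_ids
    return AtlasHierarchy(nodes)
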