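"""Exclusive ROI selection over the atlas hierarchy.

Significant atlas structures are nested (a significant nucleus sits
inside a significant parent area), so the screen's hit list is reduced
to a mutually exclusive set: whenever two significant ROIs overlap
anatomically (ancestor/descendant in the structure tree), the one with
the higher ANOVA F is kept. Because focal effects concentrate F in
small structures, this preferentially keeps localized regions over the
larger areas containing them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasHierarchy


@dataclass
class SelectionResult:
    chosen: pd.DataFrame  # unit, F (sorted by F descending)
    rejected: pd.DataFrame  # unit, F, displaced_by

    @property
    def chosen_units(self) -> list[str]:
        return list(self.chosen["unit"])


def select_exclusive(atlas: AtlasHierarchy, significant: pd.DataFrame) -> SelectionResult:
    """Greedy reduction of significant ROIs to an exclusive set.

    ``significant`` needs columns ``unit`` and ``F``. Units are visited
    by F descending and accepted iff unrelated (no ancestor/descendant
    link) to every unit already accepted. Ties on F go to the deeper
    (more localized) node, then lexicographic acronym order, so the
    result is deterministic and independent of input row order.
    """
    units = list(significant["unit"])
    if len(set(units)) != len(units):
        raise ValueError("duplicate unit labels in significant set")
    f = np.asarray(significant["F"], dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("F statistics must be finite")
    for u in units:
        if u not in atlas:
            raise KeyError(f"unit {u!r} not in atlas")

    order = sorted(
        range(len(units)),
        key=lambda i: (-f[i], -atlas.depth(units[i]), units[i]),
    )
    chosen: list[tuple[str, float]] = []
    rejected: list[tuple[str, float, str]] = []
    for i in order:
        u = units[i]
        blocker = next(
            (c for c, _ in chosen if atlas.relation(u, c) in ("ancestor", "descendant")),
            None,
        )
        if blocker is None:
            chosen.append((u, f[i]))
        else:
            rejected.append((u, f[i], blocker))
    return SelectionResult(
        chosen=pd.DataFrame(chosen, columns=["unit", "F"]),
        rejected=pd.DataFrame(rejected, columns=["unit", "F", "displaced_by"]),
    )
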