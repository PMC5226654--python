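"""Agreement between ground-truth and detected assembly structure.

The Rand index over unit pairs, R = (r + s) / (n(n-1)/2), quantifies the
match between two partitions of units into assemblies: ``r`` counts pairs
co-assembled in both, ``s`` pairs separated in both.  Retrieval metrics
match each detected assembly to the true assembly of maximal unit overlap
and report the fraction of true members recovered and the fraction of units
incorrectly pulled into an assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agglomeration import Assembly, AssemblyCatalog
from .synthetic import GroundTruth

__all__ = [
    "PartitionComparison",
    "rand_index",
    "retrieval_metrics",
    "assignment_matrix",
]


@dataclass
class PartitionComparison:
    r: int              # pairs co-assembled in both partitions
    s: int              # pairs separated in both partitions
    n: int              # units in the comparison universe
    rand_index: float

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


def _as_groups(partition) -> list[set]:
    if isinstance(partition, AssemblyCatalog):
        return partition.partition()
    if isinstance(partition, GroundTruth):
        return partition.partition()
    return [set(g) for g in partition]


def _co_assembled(groups: list[set], a, b) -> bool:
    return any(a in g and b in g for g in groups)


def rand_index(truth, detected, universe: Iterable | None = None
               ) -> PartitionComparison:
    """Rand index between two assembly memberships.

    Units absent from every assembly act as singletons.  The comparison
    universe defaults to the union of all units appearing in either
    partition's assemblies; an explicit universe (e.g. all recorded units)
    may be supplied.
    """
    gt = _as_groups(truth)
    gd = _as_groups(detected)
    if universe is None:
        universe = set().union(*gt, *gd) if (gt or gd) else set()
    universe = sorted(universe, key=repr)
    n = len(universe)
    if n == 0:
        raise ValueError("empty comparison universe")
    r = s = 0
    for a, b in combinations(universe, 2):
        t = _co_assembled(gt, a, b)
        d = _co_assembled(gd, a, b)
        if t and d:
            r += 1
        elif not t and not d:
            s += 1
    n_pairs = n * (n - 1) // 2
    R = (r + s) / n_pairs if n_pairs else 1.0
    return PartitionComparison(r=r, s=s, n=n, rand_index=R)


def match_assemblies(truth: GroundTruth, catalog: AssemblyCatalog
                     ) -> list[tuple[Assembly, int | None]]:
    """Match each detected assembly to the true assembly of maximal unit
    overlap (ties broken toward the detected assembly's lower p)."""
    out = []
    for a in sorted(catalog.assemblies, key=lambda x: x.p_value):
        overlaps = [len(set(t.members) & a.unit_set)
                    for t in truth.assemblies]
        if overlaps and max(overlaps) > 0:
            out.append((a, int(np.argmax(overlaps))))
        else:
            out.append((a, None))
    return out


def retrieval_metrics(truth: GroundTruth, catalog: AssemblyCatalog,
                      n_units_total: int | None = None) -> dict:
    """Retrieval score and false-assignment fraction.

    ``retrieval``: fraction of true assembly members recovered in their
    matched detected assembly.  ``false_fraction``: fraction of units (of
    ``n_units_total``, default the union universe) that appear in some
    detected assembly without belonging to its matched true assembly.
    """
    matches = match_assemblies(truth, catalog)
    true_members = truth.member_units()
    recovered: set = set()
    false_units: set = set()
    for a, ti in matches:
        if ti is None:
            false_units |= a.unit_set
            continue
        t_members = set(truth.assemblies[ti].members)
        recovered |= (a.unit_set & t_members)
        false_units |= (a.unit_set - t_members)
    if n_units_total is None:
        n_units_total = len(true_members | {u for a in catalog.assemblies
                                            for u in a.units})
    retrieval = len(recovered) / len(true_members) if true_members else 1.0
    false_fraction = (len(false_units) / n_units_total
                      if n_units_total else 0.0)
    return {"retrieval": retrieval,
            "false_fraction": false_fraction,
            "n_detected": len(catalog.assemblies),
            "n_true": len(truth.assemblies)}


def assignment_matrix(catalog: AssemblyCatalog,
                      unit_ids: Sequence | None = None) -> pd.DataFrame:
    """Unit-by-assembly table of lags (NaN for non-members).

    Columns are assemblies ordered by bin width then p-value; a final
    ``delta`` row records each assembly's bin width.  A unit belonging to
    several assemblies appears in several columns.
    """
    ids = list(unit_ids) if unit_ids is not None else list(catalog.unit_ids)
    cols = {}
    order = sorted(catalog.assemblies, key=lambda a: (a.delta, a.p_value))
    for j, a in enumerate(order):
        units, lags = a.normalized()
        col = {u: float(l) for u, l in zip(units, lags)}
        col["delta"] = a.delta
        cols[f"A{j + 1}"] = col
    index = ids + ["delta"]
    return pd.DataFrame(cols, index=index)
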