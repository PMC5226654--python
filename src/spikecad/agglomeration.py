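"""Recursive agglomeration of significant unit pairs into assemblies.

Detection at one bin width starts from all significant pairwise interactions
(Bonferroni-corrected over every pair and lag tested), then recursively
extends each assembly by single units: the assembly's activation series is
treated exactly like a unit count series and pair-tested against candidate
units, so each extension step tests the factorization P(set, candidate) =
P(set) P(candidate) — genuine higher-order structure, not aggregated
pairwise information.  Candidates are restricted to units already
significantly related to at least one assembly member.  The recursion stops
when no assembly gains a member; same-unit-set lag variants keep only the
lowest p, and strict unit-subsets are pruned.  The whole scheme is repeated
over a user-provided set of bin widths, and each assembly's characteristic
scale is the width with the lowest p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CountSeries, SpikeDataset, bin_dataset
from . import stats as _st
from .stats import PairTestResult, SegmentScheme

__all__ = [
    "Assembly",
    "AssemblyCatalog",
    "TestBudget",
    "DetectionConfig",
    "seed_pairs",
    "extend_assembly",
    "agglomerate_at_scale",
    "agglomerate_hierarchical",
    "prune_catalog",
    "detect_assemblies",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Assembly:
    """An ordered set of units with a lag constellation at one bin width.

    ``lags[j]`` is the lag (in bins) of ``units[j]`` relative to the
    activation time of the first unit; the first lag is always 0 and later
    entries may be negative (a member leading the first unit).  Each fusion
    step constrains only the newly added relative lag to ``|l| <= l_max``;
    cumulative spans may exceed it.
    """

    units: tuple
    lags: tuple
    delta: float
    p_value: float
    joint_count: int
    activation_counts: np.ndarray = field(repr=False)
    delta_star: float | None = None

    def __post_init__(self) -> None:
        if len(self.units) < 2 or len(self.units) != len(self.lags):
            raise ValueError("assembly needs >= 2 units with one lag each")
        if self.lags[0] != 0:
            raise ValueError("first lag must be 0")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_set(self) -> frozenset:
        return frozenset(self.units)

    def normalized(self) -> tuple[tuple, tuple]:
        """(units, lags) reordered so the earliest-firing unit carries lag 0."""
        order = np.argsort(np.asarray(self.lags), kind="stable")
        shift = min(self.lags)
        units = tuple(self.units[i] for i in order)
        lags = tuple(int(self.lags[i] - shift) for i in order)
        return units, lags

    def to_dict(self) -> dict:
        units, lags = self.normalized()
        return {
            "units": list(units),
            "lags": [int(l) for l in lags],
            "delta": float(self.delta),
            "delta_star": None if self.delta_star is None else float(self.delta_star),
            "p_value": float(self.p_value),
            "joint_count": int(self.joint_count),
        }


@dataclass
class TestBudget:
    """Bonferroni bookkeeping across the agglomeration steps.

    The seed step spends ``R1 = N(N-1)(2 l_max + 1) / 2`` tests; iteration
    ``i`` spends ``R_{i,a} = N_{a,i} N_{u,a} (2 l_max + 1)`` for assembly
    ``a``, where ``N_{a,i}`` counts assemblies tested in that iteration and
    ``N_{u,a}`` the candidate units eligible for ``a``.  Corrected levels
    are ``alpha / R``.
    """

    alpha: float = 0.05
    l_max: int = 10
    n_units: int = 0
    steps: list[dict] = field(default_factory=list)

    @property
    def n_lags(self) -> int:
        return 2 * self.l_max + 1

    @property
    def seed_tests(self) -> int:
        return self.n_units * (self.n_units - 1) * self.n_lags // 2

    def seed_level(self) -> float:
        return self.alpha / max(self.seed_tests, 1)

    def extension_level(self, n_assemblies: int, n_candidates: int) -> float:
        r = n_assemblies * n_candidates * self.n_lags
        return self.alpha / max(r, 1)

    def record(self, step: str, n_tests: int) -> None:
        self.steps.append({"step": step, "tests": int(n_tests)})


@dataclass
class DetectionConfig:
    """Tunable parameters of the detection pipeline."""

    deltas: tuple = (0.015, 0.05, 0.1, 0.15, 1.0)
    l_max: int = 10
    alpha: float = 0.05
    reference_policy: str = "mirror"   # or "fixed"
    sync_reference: int = -2
    segment_length: int = 100
    dof_policy: str = "auto"
    mean_gate: float = 4.0
    apply_floor: bool = True
    min_rate: float | None = None      # optional low-rate unit exclusion (Hz)
    prune_cosine: float | None = None  # optional across-scale cosine pruning
    prune_across_scale_subsets: bool = False

    def __post_init__(self) -> None:
        deltas = tuple(float(d) for d in self.deltas)
        if not deltas or any(d <= 0 for d in deltas):
            raise ValueError("bin widths must be positive")
        if list(deltas) != sorted(deltas):
            raise ValueError("bin widths must be strictly increasing")
        self.deltas = deltas
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.l_max < 0:
            raise ValueError("l_max must be non-negative")

    def test_kwargs(self) -> dict:
        return dict(reference_policy=self.reference_policy,
                    sync_reference=self.sync_reference,
                    dof_policy=self.dof_policy,
                    mean_gate=self.mean_gate)


@dataclass
class AssemblyCatalog:
    """Assemblies detected across all tested bin widths."""

    assemblies: list[Assembly]
    unit_ids: list
    deltas: tuple
    l_max: int
    alpha: float
    pair_tests: pd.DataFrame | None = None  # seed-step tallies per (pair, Δ)

    def __len__(self) -> int:
        return len(self.assemblies)

    def at_delta(self, delta: float) -> list[Assembly]:
        return [a for a in self.assemblies if a.delta == delta]

    def partition(self) -> list[set]:
        """Detected unit memberships as a list of sets."""
        return [set(a.units) for a in self.assemblies]

    def to_dict(self) -> dict:
        return {
            "unit_ids": list(self.unit_ids),
            "deltas": [float(d) for d in self.deltas],
            "l_max": int(self.l_max),
            "alpha": float(self.alpha),
            "assemblies": [a.to_dict() for a in self.assemblies],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AssemblyCatalog":
        d = json.loads(Path(path).read_text())
        assemblies = [
            Assembly(units=tuple(a["units"]), lags=tuple(a["lags"]),
                     delta=a["delta"], p_value=a["p_value"],
                     joint_count=a["joint_count"],
                     activation_counts=np.zeros(0, dtype=np.int64),
                     delta_star=a.get("delta_star"))
            for a in d["assemblies"]
        ]
        return cls(assemblies=assemblies, unit_ids=d["unit_ids"],
                   deltas=tuple(d["deltas"]), l_max=d["l_max"],
                   alpha=d["alpha"])


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _shifted(c: np.ndarray, lag: int) -> np.ndarray:
    """``c`` advanced by ``lag`` bins (``out[t] = c[t + lag]``), zero-padded."""
    out = np.zeros_like(c)
    T = c.size
    if lag >= 0:
        out[:T - lag] = c[lag:]
    else:
        out[-lag:] = c[:T + lag]
    return out


def pattern_series(counts: dict, units: Sequence, lags: Sequence[int]) -> np.ndarray:
    """Activation count series of a lag constellation, anchored at the first
    unit: per anchor bin, the number of complete pattern occurrences
    (min over members of their lag-shifted counts, matching the layered
    joint-count identity)."""
    z = counts[units[0]].copy()
    for u, l in zip(units[1:], lags[1:]):
        np.minimum(z, _shifted(counts[u], int(l)), out=z)
    return z


def _sorted_ids(ids: Iterable) -> list:
    try:
        return sorted(ids)
    except TypeError:
        return sorted(ids, key=repr)


# --------------------------------------------------------------------------
# step 1: seed pairs
# --------------------------------------------------------------------------

def seed_pairs(counts: dict, delta: float, l_max: int, budget: TestBudget,
               scheme: SegmentScheme | None = None,
               apply_floor: bool = True,
               **test_kwargs) -> tuple[list[Assembly], dict, list[PairTestResult]]:
    """Test every unit pair once; significant pairs become 2-unit assemblies.

    Returns the elementary assemblies, the symmetric significance relation
    ``Z`` (dict of frozenset pairs -> bool) used to restrict extension
    candidates, and all per-pair test results (the per-(pair, Δ) tallies).
    """
    ids = _sorted_ids(counts.keys())
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two units")
    budget.n_units = n
    level = budget.seed_level()
    budget.record("seed", budget.seed_tests)
    scheme = scheme or SegmentScheme()

    T = counts[ids[0]].size
    bounds = scheme.bounds(T, l_max)
    lengths = np.array([hi - lo for lo, hi in bounds], dtype=np.int64)
    # per-unit caches: floored counts and per-segment layer marginals
    floored, segm = {}, {}
    for u in ids:
        c = counts[u]
        m = int(c.min()) if c.size else 0
        floored[u] = (m, c - m if m > 0 else c)
        segm[u] = _st.segment_layer_matrix(c, bounds)

    assemblies: list[Assembly] = []
    results: list[PairTestResult] = []
    Z: dict[frozenset, bool] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            mA, cA = floored[a]
            mB, cB = floored[b]
            if apply_floor and mA > 0 and mB > 0:
                # floor removal shifts layers down: drop the first m columns
                segA, segB = segm[a][:, mA:], segm[b][:, mB:]
            else:
                (_, cA), (_, cB) = (0, counts[a]), (0, counts[b])
                segA, segB = segm[a], segm[b]
            prof = _st.lag_profile(cA, cB, l_max, pair=(a, b))
            sel = prof.selected_lag
            ref = _st.resolve_reference(sel, l_max,
                                        test_kwargs.get("reference_policy", "mirror"),
                                        test_kwargs.get("sync_reference", -2))
            s2 = _st._segmented_var_from_marginals(segA, segB, lengths)
            res = _st._core_test(
                cA, cB, sel, ref, prof.testable, s2, delta=delta,
                corrected_alpha=level,
                dof_policy=test_kwargs.get("dof_policy", "auto"),
                mean_gate=test_kwargs.get("mean_gate", 4.0), pair=(a, b))
            results.append(res)
            if res.significant:
                Z[frozenset((a, b))] = True
                z = pattern_series(counts, (a, b), (0, sel))
                assemblies.append(Assembly(
                    units=(a, b), lags=(0, sel), delta=delta,
                    p_value=res.p_value, joint_count=res.joint_count,
                    activation_counts=z))
    return assemblies, Z, results


# --------------------------------------------------------------------------
# step 2: recursive extension
# --------------------------------------------------------------------------

def eligible_candidates(assembly: Assembly, unit_ids: Sequence,
                        Z: dict) -> list:
    """Units not in the assembly that are significantly paired with at least
    one member (the apriori-style candidate restriction)."""
    members = assembly.unit_set
    out = []
    for u in unit_ids:
        if u in members:
            continue
        if any(Z.get(frozenset((u, m)), False) for m in members):
            out.append(u)
    return out


def extend_assembly(assembly: Assembly, candidate, counts: dict,
                    l_max: int, corrected_alpha: float,
                    scheme: SegmentScheme | None = None,
                    apply_floor: bool = True,
                    **test_kwargs) -> Assembly | None:
    """Pair-test an assembly's activation series against a candidate unit.

    Returns the extended assembly (candidate appended at the winning lag,
    relative to the assembly anchor) when significant, else ``None``.
    """
    if candidate in assembly.unit_set:
        raise ValueError("candidate already a member")
    res = _st.pair_test(assembly.activation_counts, counts[candidate],
                        delta=assembly.delta, l_max=l_max, scheme=scheme,
                        corrected_alpha=corrected_alpha,
                        apply_floor=apply_floor,
                        pair=("assembly", candidate), **test_kwargs)
    if not res.significant:
        return None
    units = assembly.units + (candidate,)
    lags = assembly.lags + (res.selected_lag,)
    z = np.minimum(assembly.activation_counts,
                   _shifted(counts[candidate], res.selected_lag))
    return Assembly(units=units, lags=lags, delta=assembly.delta,
                    p_value=res.p_value, joint_count=res.joint_count,
                    activation_counts=z)


def _dedupe_lowest_p(assemblies: Iterable[Assembly]) -> list[Assembly]:
    """Among same-unit-set assemblies keep only the lowest p-value."""
    best: dict[frozenset, Assembly] = {}
    for a in assemblies:
        k = a.unit_set
        if k not in best or a.p_value < best[k].p_value:
            best[k] = a
    return sorted(best.values(),
                  key=lambda a: (-a.n_units, a.p_value,
                                 [repr(u) for u in a.units]))


def _prune_subsets(assemblies: list[Assembly]) -> list[Assembly]:
    """Remove assemblies whose unit set is a strict subset of another's."""
    keep = []
    for a in assemblies:
        if not any(a.unit_set < b.unit_set for b in assemblies):
            keep.append(a)
    return keep


def agglomerate_at_scale(counts: dict, delta: float, l_max: int = 10,
                         budget: TestBudget | None = None,
                         scheme: SegmentScheme | None = None,
                         apply_floor: bool = True,
                         **test_kwargs
                         ) -> tuple[list[Assembly], dict, list[PairTestResult]]:
    """Full agglomeration at a single bin width.

    Seeds from significant pairs, then repeatedly extends every assembly
    formed in the previous iteration by eligible single units until no
    additions occur; lag variants of the same unit set keep the lowest p and
    strict subsets are pruned at the end.
    """
    budget = budget or TestBudget(l_max=l_max)
    scheme = scheme or SegmentScheme()
    ids = _sorted_ids(counts.keys())
    seeds, Z, results = seed_pairs(counts, delta, l_max, budget, scheme,
                                   apply_floor=apply_floor, **test_kwargs)
    best: dict[frozenset, Assembly] = {a.unit_set: a for a in seeds}
    generation = _dedupe_lowest_p(seeds)
    it = 0
    while generation:
        it += 1
        candidates = {id(a): eligible_candidates(a, ids, Z) for a in generation}
        n_assemblies = len(generation)
        new: list[Assembly] = []
        n_tests = 0
        for a in generation:
            cand = candidates[id(a)]
            if not cand:
                continue
            level = budget.extension_level(n_assemblies, len(cand))
            n_tests += len(cand) * budget.n_lags
            for u in cand:
                ext = extend_assembly(a, u, counts, l_max, level, scheme,
                                      apply_floor=apply_floor, **test_kwargs)
                if ext is not None:
                    new.append(ext)
        budget.record(f"extension_{it}", n_tests)
        added: list[Assembly] = []
        for a in _dedupe_lowest_p(new):
            k = a.unit_set
            if k not in best or a.p_value < best[k].p_value:
                best[k] = a
                added.append(a)
        generation = added
    final = _prune_subsets(_dedupe_lowest_p(best.values()))
    return final, Z, results


def agglomerate_hierarchical(counts: dict, delta: float, l_max: int = 10,
                             alpha: float = 0.05,
                             scheme: SegmentScheme | None = None,
                             apply_floor: bool = True,
                             **test_kwargs) -> list[Assembly]:
    """Strict hierarchical fusion variant (optional mode, off by default).

    Instead of extending assemblies by single units, at each step all pairs
    of current lists (single units and previously fused sets) are tested and
    only the pair with the lowest p-value is fused, as in classical
    agglomerative clustering.  Yields a dendrogram-like nesting, at the cost
    of missing partially overlapping assemblies and many higher-order sets.
    """
    scheme = scheme or SegmentScheme()
    ids = _sorted_ids(counts.keys())
    # current lists start as the single units
    items: list[tuple[tuple, tuple]] = [((u,), (0,)) for u in ids]
    zs: dict[int, np.ndarray] = {i: counts[u] for i, u in enumerate(ids)}
    fused: list[Assembly] = []
    n_lags = 2 * l_max + 1
    while len(items) > 1:
        n = len(items)
        level = alpha / (n * (n - 1) // 2 * n_lags)
        best: tuple[float, int, int, object] | None = None
        for i in range(n):
            for j in range(i + 1, n):
                res = _st.pair_test(zs[i], zs[j], delta=delta, l_max=l_max,
                                    scheme=scheme, corrected_alpha=level,
                                    apply_floor=apply_floor,
                                    pair=(i, j), **test_kwargs)
                if res.significant and (best is None or res.p_value < best[0]):
                    best = (res.p_value, i, j, res)
        if best is None:
            break
        p, i, j, res = best
        units = items[i][0] + items[j][0]
        lags = items[i][1] + tuple(l + res.selected_lag for l in items[j][1])
        z = np.minimum(zs[i], _shifted(zs[j], res.selected_lag))
        a = Assembly(units=units, lags=lags, delta=delta, p_value=p,
                     joint_count=res.joint_count, activation_counts=z)
        fused.append(a)
        keep = [k for k in range(n) if k not in (i, j)]
        items = [items[k] for k in keep] + [(units, lags)]
        zs = {m: zs[k] for m, k in enumerate(keep)}
        zs[len(items) - 1] = z
    return fused


# --------------------------------------------------------------------------
# catalog-level pruning and the multi-scale outer loop
# --------------------------------------------------------------------------

def prune_catalog(catalog: AssemblyCatalog,
                  cosine_threshold: float | None = None,
                  across_scale_subsets: bool = False) -> AssemblyCatalog:
    """Within-scale pruning (always) plus optional across-scale pruning.

    Within each bin width, same-unit-set lag variants keep the lowest p and
    strict subsets are removed.  Optionally, across scales: assemblies whose
    membership indicator vectors lie within ``cosine_threshold`` cosine
    distance keep only the lowest p, and/or strict subsets are removed
    regardless of scale (presentation aids, off by default).
    """
    if cosine_threshold is not None and not 0 < cosine_threshold <= 1:
        raise ValueError("cosine threshold must lie in (0, 1]")
    kept: list[Assembly] = []
    for d in sorted({a.delta for a in catalog.assemblies}):
        at_d = [a for a in catalog.assemblies if a.delta == d]
        kept.extend(_prune_subsets(_dedupe_lowest_p(at_d)))

    if across_scale_subsets:
        kept = _prune_subsets(kept)

    if cosine_threshold is not None:
        universe = _sorted_ids(catalog.unit_ids)
        index = {u: i for i, u in enumerate(universe)}

        def vec(a: Assembly) -> np.ndarray:
            v = np.zeros(len(universe))
            for u in a.units:
                v[index[u]] = 1.0
            return v

        survivors: list[Assembly] = []
        for a in sorted(kept, key=lambda x: (x.p_value, -x.n_units)):
            va = vec(a)
            close = False
            for b in survivors:
                vb = vec(b)
                cos = 1.0 - float(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
                if cos < cosine_threshold:
                    close = True
                    break
            if not close:
                survivors.append(a)
        kept = survivors

    kept = sorted(kept, key=lambda a: (a.delta, a.p_value,
                                       [repr(u) for u in a.units]))
    return replace(catalog, assemblies=kept)


def detect_assemblies(dataset: SpikeDataset,
                      deltas: Sequence[float] | None = None,
                      l_max: int = 10, alpha: float = 0.05,
                      config: DetectionConfig | None = None) -> AssemblyCatalog:
    """Run the full multi-scale detection scheme on a spike dataset.

    The agglomeration is repeated for every bin width in ``deltas``; each
    assembly is assigned the characteristic scale ``delta_star`` at which its
    unit set attains the lowest p-value across scales.
    """
    if config is None:
        config = DetectionConfig(deltas=tuple(deltas) if deltas is not None
                                 else DetectionConfig.deltas,
                                 l_max=l_max, alpha=alpha)
    if config.min_rate is not None:
        dataset = dataset.exclude_low_rate(config.min_rate)
    ids = _sorted_ids(dataset.units.keys())
    scheme = SegmentScheme(config.segment_length)

    all_assemblies: list[Assembly] = []
    tallies: list[dict] = []
    for d in config.deltas:
        series = bin_dataset(dataset, d)
        counts = {s.unit_id: s.counts for s in series}
        budget = TestBudget(alpha=config.alpha, l_max=config.l_max)
        found, _, results = agglomerate_at_scale(
            counts, d, config.l_max, budget, scheme,
            apply_floor=config.apply_floor, **config.test_kwargs())
        all_assemblies.extend(found)
        for r in results:
            tallies.append({"unit_a": r.pair[0], "unit_b": r.pair[1],
                            "delta": d, "lag": r.selected_lag,
                            "p_value": r.p_value,
                            "significant": r.significant})

    # characteristic scale: lowest p across scales for the same unit set
    by_set: dict[frozenset, float] = {}
    best_p: dict[frozenset, float] = {}
    for a in all_assemblies:
        k = a.unit_set
        if k not in best_p or a.p_value < best_p[k]:
            best_p[k] = a.p_value
            by_set[k] = a.delta
    for a in all_assemblies:
        a.delta_star = by_set[a.unit_set]

    catalog = AssemblyCatalog(
        assemblies=sorted(all_assemblies,
                          key=lambda a: (a.delta, a.p_value,
                                         [repr(u) for u in a.units])),
        unit_ids=ids, deltas=config.deltas, l_max=config.l_max,
        alpha=config.alpha,
        pair_tests=pd.DataFrame(tallies) if tallies else None)
    if config.prune_cosine is not None or config.prune_across_scale_subsets:
        catalog = prune_catalog(catalog, config.prune_cosine,
                                config.prune_across_scale_subsets)
    return catalog
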