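"""Pairwise dependence test with local non-stationarity correction.

Under the null hypothesis of independence at the tested bin width, each
layer-pair coincidence count is hypergeometric given the layer marginals, and
the nested-layer structure yields closed-form first and second moments of the
total joint count.  Because slow (co-)rate fluctuations bias these moments,
testing is based on the *difference* between the joint count at the selected
lag and at a reference lag (the mirrored lag, or lag -2 for synchrony): rate
non-stationarity on time scales slower than the lag span affects both counts
alike and cancels.  The variance of the difference count is estimated from
short segments, within which the processes are approximately stationary, and
the squared standardized difference Q is referred to an F(1, v) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import numpy as np
from scipy import stats as sps

from .counting import (
    as_counts,
    joint_count,
    lag_profile,
    layer_totals,
    overlap_windows,
)

__all__ = [
    "MomentEstimate",
    "SegmentScheme",
    "PairTestResult",
    "hypergeometric_moments",
    "uncorrected_statistic",
    "uncorrected_test",
    "difference_count",
    "segmented_variance",
    "pair_test",
]


# --------------------------------------------------------------------------
# layered hypergeometric moments
# --------------------------------------------------------------------------

def _layer_mean(nA: np.ndarray, nB: np.ndarray, n: int) -> float:
    """E[#AB] = sum_alpha #A^a #B^a / n over rank-matched layers."""
    M = min(nA.size, nB.size)
    if M == 0:
        return 0.0
    return float(np.sum(nA[:M] * nB[:M]) / n)

def _layer_var(nA: np.ndarray, nB: np.ndarray, n: int) -> float:
    """Variance of the layered joint count under the hypergeometric null.

    sum_a var(#AB^a) + 2 sum_{a<g} cov(#AB^a, #AB^g) with
    var(#AB^a)      = (#A^a #B^a / n) (n-#A^a)(n-#B^a) / (n(n-1))
    cov(#AB^a,#AB^g)= (#A^g #B^g / n) (n-#A^a)(n-#B^a) / (n(n-1)),  g > a.
    Evaluated as sum_a G_a (2 S_a - P_a) with P_a the product term, S_a its
    suffix sum and G_a the depletion factor.
    """
    M = min(nA.size, nB.size)
    if M == 0 or n <= 1:
        return 0.0
    A = nA[:M].astype(float)
    B = nB[:M].astype(float)
    P = A * B / n
    S = np.cumsum(P[::-1])[::-1]
    G = (n - A) * (n - B) / (n * (n - 1))
    return float(np.sum(G * (2.0 * S - P)))

def _layer_cov_cross_lag(nA: np.ndarray, nB: np.ndarray, n: int) -> float:
    """Covariance between joint counts at two distinct lags, same marginals.

    Derived under the permutation null; each term of the variance picks up a
    factor -1/(n-1), hence cov = -var/(n-1).
    """
    if n <= 1:
        return 0.0
    return -_layer_var(nA, nB, n) / (n - 1)


@dataclass
class MomentEstimate:
    """First two moments of the lagged joint count under independence."""

    mean: float
    variance: float
    effective_length: int   # number of overlapping bins at this lag


def hypergeometric_moments(A, B, lag: int) -> MomentEstimate:
    """Null mean and variance of ``#AB,lag`` with window-recomputed marginals.

    Marginal layer totals are taken on the overlapping window of length
    ``T - |lag|`` so that forward and reference counts use comparable
    marginals.
    """
    cA, cB = as_counts(A), as_counts(B)
    T = cA.size
    n = T - abs(lag)
    if n <= 1:
        raise ValueError("effective length must exceed 1 bin")
    wa, wb = overlap_windows(T, lag)
    nA = layer_totals(cA, wa)
    nB = layer_totals(cB, wb)
    return MomentEstimate(mean=_layer_mean(nA, nB, n),
                          variance=_layer_var(nA, nB, n),
                          effective_length=n)


# --------------------------------------------------------------------------
# uncorrected statistic (calibration baseline, not used by detection)
# --------------------------------------------------------------------------

def uncorrected_statistic(A, B, lag: int) -> float:
    """Standardized joint count S = (#AB,l - mu) / sigma.

    Approximately t-distributed with ``2(T-l)M - 1`` degrees of freedom under
    independence *and* stationarity; breaks down under coupled rate
    non-stationarity, which is why detection uses the difference statistic
    instead.
    """
    mom = hypergeometric_moments(A, B, lag)
    if mom.variance <= 0:
        raise ValueError("zero null variance: statistic undefined")
    return (joint_count(A, B, lag) - mom.mean) / np.sqrt(mom.variance)


def uncorrected_test(A, B, lag: int) -> tuple[float, int, float]:
    """(S, dof, two-sided p) for the uncorrected statistic."""
    cA, cB = as_counts(A), as_counts(B)
    s = uncorrected_statistic(cA, cB, lag)
    M = min(int(cA.max(initial=0)), int(cB.max(initial=0)))
    dof = 2 * (cA.size - abs(lag)) * max(M, 1) - 1
    p = 2.0 * sps.t.sf(abs(s), dof)
    return float(s), int(dof), float(p)


# --------------------------------------------------------------------------
# difference statistic and segmented variance
# --------------------------------------------------------------------------

def difference_count(A, B, selected_lag: int, reference_lag: int) -> int:
    """Non-stationarity-corrected count ``#AB,l - #AB,l*``."""
    if selected_lag == reference_lag:
        raise ValueError("reference lag must differ from the selected lag")
    return joint_count(A, B, selected_lag) - joint_count(A, B, reference_lag)


@dataclass
class SegmentScheme:
    """Contiguous segmentation of the bin axis for local variance estimation.

    ``segment_length`` is in bins (default 100).  A trailing remainder of at
    least ``2 (|lag| + 1)`` bins forms a final shorter segment; a smaller
    remainder is merged into the previous segment.
    """

    segment_length: int = 100

    def __post_init__(self) -> None:
        if self.segment_length <= 1:
            raise ValueError("segment length must exceed 1 bin")

    def bounds(self, T: int, lag: int = 0) -> list[tuple[int, int]]:
        k = self.segment_length
        if k <= abs(lag) + 1:
            raise ValueError(
                f"segment length {k} too short for lag {lag} (need > |lag|+1)")
        C = T // k
        if C == 0:
            return [(0, T)]
        out = [(i * k, (i + 1) * k) for i in range(C)]
        rem = T - C * k
        if rem > 0:
            if rem >= 2 * (abs(lag) + 1):
                out.append((C * k, T))
            else:
                out[-1] = (out[-1][0], T)
        return out


def segment_layer_matrix(counts: np.ndarray,
                         bounds: list[tuple[int, int]],
                         n_layers: int | None = None) -> np.ndarray:
    """Per-segment layer marginals, shape ``(C, M)``.

    Row ``c``, column ``a-1`` holds the number of bins of segment ``c`` with
    count >= ``a``.  Shared across all pairs involving this unit, so callers
    cache it.
    """
    c = np.asarray(counts)
    M = int(c.max(initial=0)) if n_layers is None else n_layers
    C = len(bounds)
    out = np.zeros((C, M), dtype=np.int64)
    if M == 0:
        return out
    starts = np.array([lo for lo, _ in bounds], dtype=np.intp)
    for a in range(1, M + 1):
        out[:, a - 1] = np.add.reduceat((c >= a).astype(np.int64), starts)
    return out


def _segmented_var_from_marginals(segA: np.ndarray, segB: np.ndarray,
                                  lengths: np.ndarray) -> float:
    """sum_c [ 2 var_c - 2 cov_c ] from cached per-segment layer marginals.

    With identical marginals in both terms, cov_c = -var_c/(k_c - 1), so each
    segment contributes ``2 var_c k_c / (k_c - 1)``.
    """
    M = min(segA.shape[1], segB.shape[1])
    if M == 0:
        return 0.0
    A = segA[:, :M].astype(float)
    B = segB[:, :M].astype(float)
    n = lengths.astype(float)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        P = A * B / n
        S = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]
        G = (n - A) * (n - B) / (n * (n - 1))
        var_c = np.sum(G * (2.0 * S - P), axis=1)
        contrib = 2.0 * var_c * lengths / np.maximum(lengths - 1, 1)
    contrib[lengths <= 1] = 0.0
    return float(np.sum(contrib))


def segmented_variance(A, B, selected_lag: int, reference_lag: int,
                       scheme: SegmentScheme | None = None) -> float:
    """Variance estimate of the difference count from local segments.

    Combines per-segment layered variances and within-segment forward/
    reference covariances: ``2 sum_c var(#AB,l^c) - 2 sum_c cov_c``.
    Cross-segment covariances are neglected.  Marginals are the segment-local
    layer totals.
    """
    scheme = scheme or SegmentScheme()
    cA, cB = as_counts(A), as_counts(B)
    T = cA.size
    for l in (selected_lag, reference_lag):
        if abs(l) >= T:
            raise ValueError(f"|lag| = {abs(l)} must be < series length {T}")
    bounds = scheme.bounds(T, selected_lag)
    segA = segment_layer_matrix(cA, bounds)
    segB = segment_layer_matrix(cB, bounds)
    lengths = np.array([hi - lo for lo, hi in bounds], dtype=np.int64)
    return _segmented_var_from_marginals(segA, segB, lengths)


# --------------------------------------------------------------------------
# the full pair test
# --------------------------------------------------------------------------

@dataclass
class PairTestResult:
    """Outcome of the corrected dependence test for one unit pair."""

    pair: tuple[Hashable, Hashable]
    delta: float | None
    selected_lag: int
    reference_lag: int
    joint_count: int
    reference_count: int
    difference: int
    null_mean: float            # plug-in mean of the difference count
    variance_estimate: float
    Q: float
    dof: int
    p_value: float
    significant: bool
    gate_passed: bool           # expected joint count above the validity gate
    testable: bool


def resolve_dof(T: int, lag: int, M: int, policy: str = "auto") -> int:
    """Denominator degrees of freedom for the F test.

    ``"full"``: v = 2(T-|l|)M - 1 (default in large samples);
    ``"conservative"``: v = T - |l| (recommended for short series);
    ``"auto"``: conservative when T < 50, full otherwise.
    """
    if policy == "auto":
        policy = "conservative" if T < 50 else "full"
    if policy == "full":
        return 2 * (T - abs(lag)) * max(M, 1) - 1
    if policy == "conservative":
        return T - abs(lag)
    raise ValueError(f"unknown dof policy {policy!r}")


def resolve_reference(selected_lag: int, l_max: int,
                      policy: str = "mirror", sync_reference: int = -2) -> int:
    """Reference lag for the difference statistic.

    ``"mirror"``: the time-reversed lag ``-l`` (``sync_reference``, default
    -2, for the synchronous case ``l = 0``);
    ``"fixed"``: ``-(l_max + 1)`` regardless of the selected lag (sign chosen
    opposite to the selected lag's direction).
    """
    if policy == "mirror":
        return sync_reference if selected_lag == 0 else -selected_lag
    if policy == "fixed":
        return -(l_max + 1) if selected_lag >= 0 else (l_max + 1)
    raise ValueError(f"unknown reference policy {policy!r}")


def _core_test(cA: np.ndarray, cB: np.ndarray, sel: int, ref: int,
               testable: bool, s2: float, *, delta: float | None,
               corrected_alpha: float, dof_policy: str, mean_gate: float,
               pair: tuple[Hashable, Hashable]) -> PairTestResult:
    """Assemble a :class:`PairTestResult` given a variance estimate."""
    fwd = joint_count(cA, cB, sel)
    rev = joint_count(cA, cB, ref)
    d = fwd - rev

    mom_fwd = hypergeometric_moments(cA, cB, sel)
    mom_ref = hypergeometric_moments(cA, cB, ref)
    mu_d = mom_fwd.mean - mom_ref.mean
    gate_passed = mom_fwd.mean > mean_gate

    M = min(int(cA.max(initial=0)), int(cB.max(initial=0)))
    dof = resolve_dof(cA.size, sel, M, dof_policy)

    if M == 0 or s2 <= 0.0:
        # degenerate: silent unit, or zero variance (then a nonzero
        # difference cannot be assessed and is never called significant)
        return PairTestResult(pair=pair, delta=delta, selected_lag=sel,
                              reference_lag=ref, joint_count=fwd,
                              reference_count=rev, difference=d,
                              null_mean=mu_d, variance_estimate=s2, Q=0.0,
                              dof=dof, p_value=1.0, significant=False,
                              gate_passed=gate_passed, testable=False)

    Q = (d - mu_d) ** 2 / s2
    p = float(sps.f.sf(Q, 1, dof))
    significant = bool(testable and gate_passed and d > 0
                       and p <= corrected_alpha)
    return PairTestResult(pair=pair, delta=delta, selected_lag=sel,
                          reference_lag=ref, joint_count=fwd,
                          reference_count=rev, difference=d, null_mean=mu_d,
                          variance_estimate=s2, Q=float(Q), dof=dof,
                          p_value=p, significant=significant,
                          gate_passed=gate_passed, testable=testable)


def apply_pair_floor(cA: np.ndarray, cB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Floor-count correction for a pair: subtract each series' minimum,
    applied only when *both* minima are positive (coarse-bin regime)."""
    mA = int(cA.min()) if cA.size else 0
    mB = int(cB.min()) if cB.size else 0
    if mA > 0 and mB > 0:
        return cA - mA, cB - mB
    return cA, cB


def pair_test(A, B, delta: float | None = None, l_max: int = 10,
              scheme: SegmentScheme | None = None,
              corrected_alpha: float = 0.05, *,
              lag: int | None = None,
              reference_policy: str = "mirror",
              sync_reference: int = -2,
              dof_policy: str = "auto",
              mean_gate: float = 4.0,
              apply_floor: bool = True,
              pair: tuple[Hashable, Hashable] | None = None) -> PairTestResult:
    """Corrected dependence test between two count series at bin width Δ.

    Selects the lag with the maximal joint count over ``-l_max..l_max``
    (unless ``lag`` fixes it), forms the difference against the reference
    lag, estimates its variance from segments, and refers
    ``Q = (difference - mu)^2 / variance`` to ``F(1, v)``.

    A pair whose expected joint count under the null is at or below
    ``mean_gate`` (default 4) is flagged untested: the distributional
    approximations are unreliable in that regime.  Significance additionally
    requires a positive difference (excess in the selected direction).
    """
    cA, cB = as_counts(A), as_counts(B)
    if cA.size != cB.size:
        raise ValueError("count series must share the same length")
    T = cA.size
    if pair is None:
        pair = (getattr(A, "unit_id", 0), getattr(B, "unit_id", 1))
    scheme = scheme or SegmentScheme()

    if apply_floor:
        cA, cB = apply_pair_floor(cA, cB)

    if lag is None:
        prof = lag_profile(cA, cB, l_max, pair=pair)
        sel = prof.selected_lag
        testable = prof.testable
    else:
        sel = int(lag)
        testable = bool(cA.max(initial=0) > 0 and cB.max(initial=0) > 0)
    ref = resolve_reference(sel, l_max, reference_policy, sync_reference)
    if abs(ref) >= T:
        raise ValueError("reference lag outside series")

    s2 = segmented_variance(cA, cB, sel, ref, scheme)
    return _core_test(cA, cB, sel, ref, testable, s2, delta=delta,
                      corrected_alpha=corrected_alpha, dof_policy=dof_policy,
                      mean_gate=mean_gate, pair=pair)
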