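"""Binary-layer decomposition and lagged joint coincidence counts.

A spike-count series ``{c_t}`` with maximum count ``M`` decomposes into an
overlay of ``M`` nested binary sub-processes (layers): layer ``alpha`` has a
one wherever ``c_t >= alpha``.  The joint count of two units at lag ``l`` is
the sum over rank-matched layer pairs of coincidences, which — because the
layers are nested — collapses to the exact identity

    #AB,l = sum_t min(c_A[t], c_B[t + l]),

used as the fast computational path throughout (the layer form is kept for
moment computations and as an independent oracle in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .io import CountSeries

__all__ = [
    "BinaryLayerStack",
    "PairProfile",
    "binary_layers",
    "joint_count",
    "lag_profile",
    "lag_order",
    "layer_totals",
    "overlap_windows",
]


def as_counts(x) -> np.ndarray:
    """Coerce a CountSeries / BinaryLayerStack / array to an int64 count array."""
    if isinstance(x, CountSeries):
        return x.counts
    if isinstance(x, BinaryLayerStack):
        return x.to_counts()
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("spike counts must be integers")
        arr = np.round(arr).astype(np.int64)
    return arr.astype(np.int64, copy=False)


@dataclass
class BinaryLayerStack:
    """Nested binary decomposition of a count series.

    ``layers[alpha - 1][t] = 1`` iff ``c_t >= alpha`` for ``alpha = 1..M``.
    Layers are nested (higher layers are elementwise <= lower layers) and sum
    back to the original counts.  A silent unit (all-zero counts) has an
    empty stack.
    """

    unit_id: Hashable
    layers: np.ndarray = field(repr=False)  # shape (M, T), uint8

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=np.uint8)
        if self.layers.ndim != 2:
            raise ValueError("layers must be a 2-D (M, T) array")

    @property
    def n_layers(self) -> int:
        return int(self.layers.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.layers.shape[1])

    @property
    def silent(self) -> bool:
        return self.n_layers == 0

    @property
    def layer_totals(self) -> np.ndarray:
        """Number of ones per layer (``#A^alpha`` for ``alpha = 1..M``)."""
        return self.layers.sum(axis=1).astype(np.int64)

    def to_counts(self) -> np.ndarray:
        if self.silent:
            raise ValueError("empty stack carries no bin-count information")
        return self.layers.sum(axis=0).astype(np.int64)


def binary_layers(counts: CountSeries | np.ndarray,
                  unit_id: Hashable | None = None) -> BinaryLayerStack:
    """Decompose a count series into its stack of nested binary layers."""
    if isinstance(counts, CountSeries):
        unit_id = counts.unit_id if unit_id is None else unit_id
        c = counts.counts
    else:
        c = as_counts(counts)
    M = int(c.max(initial=0))
    alphas = np.arange(1, M + 1)[:, None]
    layers = (c[None, :] >= alphas).astype(np.uint8)
    return BinaryLayerStack(unit_id=unit_id, layers=layers)


def overlap_windows(T: int, lag: int) -> tuple[slice, slice]:
    """Index windows of the two series that overlap at a given lag.

    For ``lag >= 0`` the leading series contributes bins ``0..T-lag`` and the
    lagging one ``lag..T``; mirrored for negative lags.  Both windows have
    length ``T - |lag|``.
    """
    if abs(lag) >= T:
        raise ValueError(f"|lag| = {abs(lag)} must be < series length {T}")
    if lag >= 0:
        return slice(0, T - lag), slice(lag, T)
    return slice(-lag, T), slice(0, T + lag)


def joint_count(A, B, lag: int) -> int:
    """Total lagged coincidence count ``#AB,l`` between two units.

    Counts a spike in ``A`` matched by a spike in ``B`` ``lag`` bins later,
    summed over rank-matched binary layers — equivalently
    ``sum_t min(c_A[t], c_B[t+lag])``.  Negative lags count ``B`` leading
    ``A``.
    """
    cA, cB = as_counts(A), as_counts(B)
    T = cA.size
    if cB.size != T:
        raise ValueError("count series must share the same length")
    wa, wb = overlap_windows(T, lag)
    return int(np.minimum(cA[wa], cB[wb]).sum())


def lag_order(l_max: int) -> np.ndarray:
    """Lags ``-l_max..l_max`` ordered by the argmax tie-break.

    Smallest ``|l|`` first; within a tie the non-negative lag precedes the
    negative one (0, 1, -1, 2, -2, ...).
    """
    out = [0]
    for l in range(1, l_max + 1):
        out += [l, -l]
    return np.array(out, dtype=np.int64)


@dataclass
class PairProfile:
    """Joint counts of one unit pair across a symmetric range of lags."""

    pair: tuple[Hashable, Hashable]
    lags: np.ndarray            # -l_max..l_max ascending
    joint_counts: np.ndarray    # #AB,l per lag, aligned with ``lags``
    selected_lag: int           # argmax lag after tie-break
    testable: bool              # False when every joint count is zero

    def count_at(self, lag: int) -> int:
        i = int(lag - self.lags[0])
        if not (0 <= i < self.lags.size):
            raise ValueError(f"lag {lag} outside profile range")
        return int(self.joint_counts[i])


def lag_profile(A, B, l_max: int,
                pair: tuple[Hashable, Hashable] | None = None) -> PairProfile:
    """Joint counts at every lag in ``-l_max..l_max`` and the selected lag.

    The selected lag maximizes the joint count; ties are broken in favour of
    the smallest ``|l|`` and then the non-negative lag, so a perfectly
    symmetric profile selects synchrony.
    """
    if l_max < 0:
        raise ValueError("l_max must be non-negative")
    cA, cB = as_counts(A), as_counts(B)
    T = cA.size
    if l_max >= T:
        raise ValueError(f"l_max = {l_max} must be < series length {T}")
    lags = np.arange(-l_max, l_max + 1, dtype=np.int64)
    counts = np.empty(lags.size, dtype=np.int64)
    for i, l in enumerate(lags):
        counts[i] = joint_count(cA, cB, int(l))
    order = lag_order(l_max)
    ordered_counts = counts[order + l_max]
    best = int(order[int(np.argmax(ordered_counts))])
    if pair is None:
        pair = (getattr(A, "unit_id", 0), getattr(B, "unit_id", 1))
    return PairProfile(pair=pair, lags=lags, joint_counts=counts,
                       selected_lag=best, testable=bool(counts.max(initial=0) > 0))


def layer_totals(counts: np.ndarray, window: slice | None = None) -> np.ndarray:
    """Layer marginals ``#A^alpha`` (alpha = 1..M) of a count series window.

    ``layer_totals(c)[a-1]`` is the number of bins with count >= a, computed
    without materialising the layer stack.
    """
    c = counts if window is None else counts[window]
    M = int(c.max(initial=0))
    if M == 0:
        return np.zeros(0, dtype=np.int64)
    hist = np.bincount(c, minlength=M + 1)
    return np.cumsum(hist[::-1])[::-1][1:M + 1].astype(np.int64)
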