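"""Locating assembly activations in spike data.

An activation instance occurs whenever member spikes appear in the bin
constellation prescribed by the assembly's lag vector at its bin width; the
activation time point is that of the earliest-spiking member.  Every
matching combination of member spikes is counted, so the per-bin activation
score is the product of member bin counts and can exceed one, especially
for coarse-scale rate assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agglomeration import Assembly
from .io import SpikeDataset, bin_dataset

__all__ = ["ActivationRecord", "activation_times", "activation_score"]


@dataclass
class ActivationRecord:
    assembly: Assembly
    instants: np.ndarray       # activation times (s), sorted, with multiplicity
    scores: np.ndarray         # activations per bin at the assembly's delta

    def __post_init__(self) -> None:
        total = int(self.scores.sum())
        if total != self.instants.size:
            raise ValueError("score series must sum to the number of instants")


def _member_counts(dataset: SpikeDataset, assembly: Assembly,
                   delta: float) -> dict:
    missing = [u for u in assembly.units if u not in dataset.units]
    if missing:
        raise ValueError(f"assembly units missing from dataset: {missing}")
    series = bin_dataset(dataset, delta)
    return {s.unit_id: s.counts for s in series}


def activation_score(dataset: SpikeDataset, assembly: Assembly,
                     delta: float | None = None) -> np.ndarray:
    """Per-bin activation counts of the assembly's lag constellation.

    ``score[t]`` is the number of member-spike combinations matching the
    pattern with the earliest member in bin ``t``: the product over members
    of their counts in the prescribed bins (zero if any member is silent
    there).
    """
    delta = assembly.delta if delta is None else delta
    if delta <= 0:
        raise ValueError("bin width must be positive")
    counts = _member_counts(dataset, assembly, delta)
    units, lags = assembly.normalized()   # earliest member carries lag 0
    T = counts[units[0]].size
    score = np.ones(T, dtype=np.int64)
    for u, l in zip(units, lags):
        shifted = np.zeros(T, dtype=np.int64)
        shifted[:T - l] = counts[u][l:] if l else counts[u]
        score *= shifted
    return score


def activation_times(dataset: SpikeDataset, assembly: Assembly) -> np.ndarray:
    """Sorted activation instants, one per matching spike combination.

    Each instance is timed by the earliest-spiking member: its actual spike
    times within the anchor bin, each repeated once per combination of the
    other members' spikes in their bins.
    """
    delta = assembly.delta
    counts = _member_counts(dataset, assembly, delta)
    units, lags = assembly.normalized()
    anchor = units[0]
    T = counts[anchor].size
    score = activation_score(dataset, assembly, delta)
    t0 = dataset.span[0]
    anchor_times = dataset.units[anchor]
    out = []
    for t in np.flatnonzero(score):
        c_anchor = counts[anchor][t]
        mult = score[t] // c_anchor     # combinations of the other members
        lo, hi = t0 + t * delta, t0 + (t + 1) * delta
        in_bin = anchor_times[(anchor_times >= lo) & (anchor_times < hi)]
        out.append(np.repeat(in_bin, mult))
    if not out:
        return np.zeros(0)
    return np.sort(np.concatenate(out))


def activation_record(dataset: SpikeDataset, assembly: Assembly) -> ActivationRecord:
    return ActivationRecord(assembly=assembly,
                            instants=activation_times(dataset, assembly),
                            scores=activation_score(dataset, assembly))
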