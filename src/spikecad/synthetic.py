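"""Synthetic ground-truth recordings for validating assembly detection.

Background activity emulates in-vivo-like non-stationary spiking: each
unit is an inhomogeneous Poisson process whose instantaneous rate follows a
stable first-order autoregressive latent process pushed through an
error-function sigmoid, with a constant refractory delay added to every
inter-spike interval.  Five archetypal assembly structures can be embedded
on top as disjoint unit groups:

I    precise synchronous spikes;
II   a precise sequence with frozen pairwise lags;
III  a frozen multi-spike temporal pattern without strict ordering;
IV   a sequence of short windows of extra spikes, redrawn per occurrence;
V    a coherent firing-rate step (5 -> 10 Hz) across members.

Two further two-unit calibration scenarios are provided: Bernoulli
processes with step-like rate states, and a common 4-Hz oscillatory drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.special import erf

from .io import SpikeDataset

__all__ = [
    "BackgroundConfig",
    "AssemblySpec",
    "TrueAssembly",
    "GroundTruth",
    "StepRateConfig",
    "OscillationConfig",
    "generate_background",
    "embed_assembly",
    "corrupt_sorting",
    "generate_scenario",
]


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# background process
# --------------------------------------------------------------------------

@dataclass
class BackgroundConfig:
    """Parameters of the AR-latent inhomogeneous Poisson background.

    The latent state advances every ``ar_step`` seconds as
    ``s_{t+1} = D s_t + eps_t`` with ``eps ~ N(0, noise_scale^2 I)``; the
    rate is ``lambda_t = (1 + erf(gain (s_t - mean_s)/noise_scale))
    mean_rate``, bounded in ``(0, 2 mean_rate)``.  ``refractory`` seconds
    are added to every inter-spike interval.
    """

    n_units: int = 50
    duration: float = 1400.0
    mean_rate: float = 5.0          # Hz
    refractory: float = 0.015       # s
    ar_coeff: float | np.ndarray = 0.9
    noise_scale: float = 0.01
    sigmoid_gain: float = 0.2
    ar_step: float = 0.01           # s; latent update interval
    seed: int | None = None

    def coeff_matrix(self) -> np.ndarray:
        D = self.ar_coeff
        if np.isscalar(D):
            return float(D) * np.eye(self.n_units)
        D = np.asarray(D, dtype=float)
        if D.shape != (self.n_units, self.n_units):
            raise ValueError("AR coefficient matrix shape mismatch")
        return D

    def validate(self) -> None:
        if self.n_units < 1 or self.duration <= 0 or self.mean_rate <= 0:
            raise ValueError("invalid background configuration")
        eig = np.abs(np.linalg.eigvals(self.coeff_matrix())).max()
        if eig >= 1.0:
            raise ValueError(f"unstable AR process (spectral radius {eig:.3f})")


def _latent_rates(config: BackgroundConfig, rng: np.random.Generator,
                  burn_in: int = 1000) -> np.ndarray:
    """Latent AR rates, shape (n_units, n_steps)."""
    D = config.coeff_matrix()
    n_steps = int(np.ceil(config.duration / config.ar_step)) + 1
    total = burn_in + n_steps
    noise = rng.normal(0.0, config.noise_scale, size=(config.n_units, total))
    diag = np.diag(np.diag(D))
    if np.allclose(D, diag):
        from scipy.signal import lfilter
        out = np.empty_like(noise)
        for i in range(config.n_units):
            out[i] = lfilter([1.0], [1.0, -D[i, i]], noise[i])
    else:
        out = np.empty_like(noise)
        s = np.zeros(config.n_units)
        for t in range(total):
            s = D @ s + noise[:, t]
            out[:, t] = s
    out = out[:, burn_in:]
    arg = config.sigmoid_gain * out / config.noise_scale
    return (1.0 + erf(arg)) * config.mean_rate


def _sample_inhomogeneous(rates: np.ndarray, step: float, duration: float,
                          refractory: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson ISIs (exact, by time rescaling) plus refractory.

    Each inter-spike interval is drawn from the exponential process with the
    (piecewise-constant) instantaneous rate, inverted through the cumulative
    hazard; the constant refractory delay is then added to the interval.
    """
    lam = np.maximum(rates, 1e-12)
    cum = np.concatenate([[0.0], np.cumsum(lam * step)])  # hazard at grid pts
    n = lam.size

    def hazard_at(t: float) -> float:
        i = min(int(t / step), n - 1)
        return cum[i] + lam[i] * (t - i * step)

    def invert(h: float) -> float:
        i = int(np.searchsorted(cum, h, side="right")) - 1
        if i >= n:
            return duration + 1.0
        return i * step + (h - cum[i]) / lam[i]

    block = rng.exponential(size=max(int(duration * rates.mean() * 2), 64))
    ptr = 0
    t = 0.0
    out = []
    while True:
        if ptr >= block.size:
            block = rng.exponential(size=block.size)
            ptr = 0
        t = invert(hazard_at(t) + block[ptr]) + refractory
        ptr += 1
        if t >= duration:
            break
        out.append(t)
    return np.asarray(out)


def generate_background(config: BackgroundConfig,
                        seed=None) -> tuple[SpikeDataset, np.ndarray]:
    """Generate the background recording; returns (dataset, latent rates)."""
    config.validate()
    rng = as_rng(config.seed if seed is None else seed)
    rates = _latent_rates(config, rng)
    units = {}
    for i in range(config.n_units):
        units[i] = _sample_inhomogeneous(rates[i], config.ar_step,
                                         config.duration, config.refractory,
                                         rng)
    ds = SpikeDataset(units=units, span=(0.0, config.duration))
    return ds, rates


# --------------------------------------------------------------------------
# assembly embedding
# --------------------------------------------------------------------------

@dataclass
class AssemblySpec:
    """Specification of one embedded assembly."""

    atype: str                       # "I".."V"
    members: tuple
    n_occurrences: int
    lag_range: tuple[float, float] = (0.0, 0.1)    # II: gap distribution, s
    pattern_window: float = 0.2                    # III: pattern extent, s
    pattern_rate: float = 10.0                     # III/IV: extra-spike rate, Hz
    burst_window: float = 0.3                      # IV: window length, s
    window_gap_range: tuple[float, float] = (0.0, 0.4)  # IV: window lags, s
    rate_window: float = 1.0                       # V: elevated-rate period, s
    rate_increase: float = 5.0                     # V: added rate, Hz

    def __post_init__(self) -> None:
        if self.atype not in ("I", "II", "III", "IV", "V"):
            raise ValueError(f"unknown assembly type {self.atype!r}")
        if self.n_occurrences < 1:
            raise ValueError("need at least one occurrence")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members")


@dataclass
class TrueAssembly:
    """Ground-truth record of one embedded assembly."""

    atype: str
    members: tuple
    activations: np.ndarray          # occurrence anchor times, sorted, s
    member_offsets: list             # per-member frozen offsets (s), if any


@dataclass
class GroundTruth:
    """Embedded structure of a synthetic recording."""

    assemblies: list[TrueAssembly] = field(default_factory=list)
    assembly_spikes: dict = field(default_factory=dict)  # unit -> inserted times
    meta: dict = field(default_factory=dict)

    def partition(self) -> list[set]:
        return [set(a.members) for a in self.assemblies]

    def member_units(self) -> set:
        out: set = set()
        for a in self.assemblies:
            out |= set(a.members)
        return out

    def n_assembly_spikes(self) -> int:
        return int(sum(v.size for v in self.assembly_spikes.values()))

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        spikes = dict(self.assembly_spikes)
        for u, t in other.assembly_spikes.items():
            spikes[u] = np.sort(np.concatenate([spikes.get(u, np.zeros(0)), t]))
        return GroundTruth(assemblies=self.assemblies + other.assemblies,
                           assembly_spikes=spikes,
                           meta={**self.meta, **other.meta})


def _pattern_extent(spec: AssemblySpec, rng: np.random.Generator):
    """Frozen per-member offset structure and total extent for a spec."""
    k = len(spec.members)
    if spec.atype == "I":
        offsets = [np.zeros(1) for _ in range(k)]
    elif spec.atype == "II":
        gaps = rng.uniform(*spec.lag_range, size=k - 1)
        starts = np.concatenate([[0.0], np.cumsum(gaps)])
        offsets = [np.array([s]) for s in starts]
    elif spec.atype == "III":
        offsets = []
        for _ in range(k):
            n = 0
            while n == 0:   # every member must contribute at least one spike
                n = rng.poisson(spec.pattern_rate * spec.pattern_window)
            offsets.append(np.sort(rng.uniform(0, spec.pattern_window, size=n)))
    elif spec.atype == "IV":
        gaps = rng.uniform(*spec.window_gap_range, size=k - 1)
        starts = np.concatenate([[0.0], np.cumsum(gaps)])
        offsets = [np.array([s]) for s in starts]   # window starts, not spikes
    else:  # V
        offsets = [np.zeros(1) for _ in range(k)]
    if spec.atype == "III":
        extent = spec.pattern_window
    elif spec.atype == "IV":
        extent = float(offsets[-1][0]) + spec.burst_window
    elif spec.atype == "V":
        extent = spec.rate_window
    else:
        extent = float(max(o.max() for o in offsets))
    return offsets, extent


def _occurrence_spikes(spec: AssemblySpec, offsets, t0: float,
                       rng: np.random.Generator) -> list[np.ndarray]:
    """Spike times inserted for one occurrence, per member."""
    out = []
    for j in range(len(spec.members)):
        if spec.atype in ("I", "II", "III"):
            out.append(t0 + offsets[j])
        elif spec.atype == "IV":
            n = rng.poisson(spec.pattern_rate * spec.burst_window)
            w0 = t0 + float(offsets[j][0])
            out.append(np.sort(w0 + rng.uniform(0, spec.burst_window, size=n)))
        else:  # V: extra Poisson spikes double the rate in the window
            n = rng.poisson(spec.rate_increase * spec.rate_window)
            out.append(np.sort(t0 + rng.uniform(0, spec.rate_window, size=n)))
    return out


def _erase_near(background: np.ndarray, inserted: np.ndarray,
                half_window: float) -> np.ndarray:
    """Drop background spikes within +-half_window of any inserted spike."""
    if inserted.size == 0 or background.size == 0:
        return background
    idx = np.searchsorted(inserted, background)
    left = inserted[np.clip(idx - 1, 0, inserted.size - 1)]
    right = inserted[np.clip(idx, 0, inserted.size - 1)]
    near = (np.abs(background - left) <= half_window) | \
           (np.abs(background - right) <= half_window)
    return background[~near]


def embed_assembly(dataset: SpikeDataset, spec: AssemblySpec,
                   seed=None, erase_window: float = 0.015
                   ) -> tuple[SpikeDataset, GroundTruth]:
    """Insert one assembly into a copy of the dataset.

    Occurrence anchor times are uniform over the recording (overlaps
    permitted); background spikes within ``+-erase_window`` of each inserted
    spike are erased to preserve the refractory period.
    """
    rng = as_rng(seed)
    missing = [m for m in spec.members if m not in dataset.units]
    if missing:
        raise ValueError(f"members not in dataset: {missing}")
    t0_, t1_ = dataset.span
    offsets, extent = _pattern_extent(spec, rng)
    if extent >= (t1_ - t0_):
        raise ValueError("pattern extent exceeds recording span")
    anchors = np.sort(rng.uniform(t0_, t1_ - extent, size=spec.n_occurrences))

    inserted: dict = {m: [] for m in spec.members}
    for t0 in anchors:
        for m, sp in zip(spec.members, _occurrence_spikes(spec, offsets, t0, rng)):
            inserted[m].append(sp)
    units = dict(dataset.units)
    spikes_by_unit = {}
    for m in spec.members:
        ins = np.sort(np.concatenate(inserted[m])) if inserted[m] else np.zeros(0)
        bg = _erase_near(units[m], ins, erase_window)
        units[m] = np.sort(np.concatenate([bg, ins]))
        spikes_by_unit[m] = ins

    truth = GroundTruth(
        assemblies=[TrueAssembly(atype=spec.atype, members=tuple(spec.members),
                                 activations=anchors, member_offsets=offsets)],
        assembly_spikes=spikes_by_unit)
    return SpikeDataset(units=units, span=dataset.span), truth


def corrupt_sorting(dataset: SpikeDataset, truth: GroundTruth | None,
                    fraction: float, seed=None) -> SpikeDataset:
    """Simulate spike-sorting errors: reassign a fraction of all spikes to
    uniformly chosen other units.  The total spike count is conserved."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = as_rng(seed)
    ids = list(dataset.units.keys())
    if fraction == 0 or len(ids) < 2:
        return dataset
    labels = np.concatenate([np.full(dataset.units[u].size, i)
                             for i, u in enumerate(ids)])
    times = np.concatenate([dataset.units[u] for u in ids])
    n = times.size
    n_move = int(np.floor(fraction * n))
    move = rng.choice(n, size=n_move, replace=False)
    # uniform among the other N-1 units
    shift = rng.integers(1, len(ids), size=n_move)
    labels[move] = (labels[move] + shift) % len(ids)
    units = {u: np.sort(times[labels == i]) for i, u in enumerate(ids)}
    return SpikeDataset(units=units, span=dataset.span)


# --------------------------------------------------------------------------
# calibration scenarios
# --------------------------------------------------------------------------

@dataclass
class StepRateConfig:
    """Two Bernoulli units with randomly interspersed high-rate states.

    Rates are expressed per elementary bin; ``m`` high states of ``L``
    elementary bins are placed at random (non-overlapping) within
    ``total_bins``.  ``coupled`` makes both units share the same state
    sequence.
    """

    total_bins: int = 1_000_000
    m: int = 25
    L: int = 3000
    pi_low: tuple[float, float] = (0.01, 0.03)     # (unit A, unit B)
    pi_high: tuple[float, float] = (0.05, 0.15)
    coupled: bool = True

    def __post_init__(self) -> None:
        for p in (*self.pi_low, *self.pi_high):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.m * self.L > self.total_bins:
            raise ValueError("high states exceed total length")

    def _state_mask(self, rng: np.random.Generator) -> np.ndarray:
        """Boolean high-state indicator over elementary bins."""
        free = self.total_bins - self.m * self.L
        cuts = np.sort(rng.integers(0, free + 1, size=self.m))
        starts = cuts + np.arange(self.m) * self.L
        mask = np.zeros(self.total_bins, dtype=bool)
        for s in starts:
            mask[s:s + self.L] = True
        return mask

    def binned_counts(self, delta_bins: int,
                      seed=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Counts of both units at bin width ``delta_bins`` elementary bins.

        Exact: each detection bin aggregates Bernoulli draws, i.e. a sum of
        two binomials with the bin's low/high elementary-bin occupancies.
        Returns (counts_A, counts_B, high-state mask at elementary
        resolution).
        """
        rng = as_rng(seed)
        T = self.total_bins // delta_bins
        used = T * delta_bins
        mask = self._state_mask(rng)
        counts = []
        for k, (plo, phi) in enumerate(zip(self.pi_low, self.pi_high)):
            mk = mask if (self.coupled or k == 0) else self._state_mask(rng)
            n_high = mk[:used].reshape(T, delta_bins).sum(axis=1)
            c = rng.binomial(delta_bins - n_high, plo) + rng.binomial(n_high, phi)
            counts.append(c.astype(np.int64))
            if k == 0:
                mask0 = mk
        return counts[0], counts[1], mask0

    def dataset(self, seed=None) -> tuple[SpikeDataset, GroundTruth]:
        """Spike-time view at elementary resolution (one time unit per bin)."""
        rng = as_rng(seed)
        cA, cB, mask = self.binned_counts(1, rng)
        units = {"A": np.flatnonzero(cA) + 0.5, "B": np.flatnonzero(cB) + 0.5}
        ds = SpikeDataset(units=units, span=(0.0, float(self.total_bins)))
        truth = GroundTruth(meta={"high_state_bins": int(mask.sum()),
                                  "m": self.m, "L": self.L,
                                  "coupled": self.coupled})
        return ds, truth


@dataclass
class OscillationConfig:
    """Two units under a common 4-Hz oscillatory rate drive.

    ``rate(t) = base (0.6 sin(2 pi theta t) + a)`` with amplitudes
    ``a_A = 1`` and ``a_B = 0.5`` (long-run means 5 and 2.5 Hz; negative
    instantaneous rates for B are clipped at zero, slightly raising its
    realized mean).  Optionally a fixed number of A->B patterns with a 20-ms
    delay is inserted at randomly chosen oscillation peaks.
    """

    base: float = 5.0
    amplitude_a: float = 1.0
    amplitude_b: float = 0.5
    frequency: float = 4.0
    duration: float = 1500.0
    with_patterns: bool = False
    pattern_count: int = 90
    pattern_delay: float = 0.020

    def rate(self, t: np.ndarray, amplitude: float) -> np.ndarray:
        lam = self.base * (0.6 * np.sin(2 * np.pi * self.frequency * t) + amplitude)
        return np.clip(lam, 0.0, None)

    def _thin(self, amplitude: float, rng: np.random.Generator) -> np.ndarray:
        lam_max = self.base * (0.6 + amplitude)
        n = rng.poisson(lam_max * self.duration)
        t = np.sort(rng.uniform(0, self.duration, size=n))
        keep = rng.random(n) < self.rate(t, amplitude) / lam_max
        return t[keep]

    def dataset(self, seed=None) -> tuple[SpikeDataset, GroundTruth]:
        rng = as_rng(seed)
        a = self._thin(self.amplitude_a, rng)
        b = self._thin(self.amplitude_b, rng)
        truth = GroundTruth(meta={"frequency": self.frequency})
        if self.with_patterns:
            n_cycles = int(self.duration * self.frequency)
            peaks = (1.0 / (4 * self.frequency)
                     + rng.choice(n_cycles, size=self.pattern_count,
                                  replace=False) / self.frequency)
            ta = np.sort(peaks + self.pattern_delay)
            tb = ta + self.pattern_delay
            a = np.sort(np.concatenate([_erase_near(a, ta, 0.015), ta]))
            b = np.sort(np.concatenate([_erase_near(b, tb, 0.015), tb]))
            truth.assemblies.append(TrueAssembly(
                atype="oscillation_pattern", members=("A", "B"),
                activations=ta, member_offsets=[np.zeros(1),
                                                np.array([self.pattern_delay])]))
            truth.assembly_spikes = {"A": ta, "B": tb}
        ds = SpikeDataset(units={"A": a, "B": b}, span=(0.0, self.duration))
        return ds, truth


# --------------------------------------------------------------------------
# named scenarios
# --------------------------------------------------------------------------

_FIGURE1_TYPES = ("I", "II", "III", "IV", "V")
_FIGURE1_OCCURRENCES = {"I": 350, "II": 350, "III": 350, "IV": 350, "V": 200}


def figure1_specs(n_members: int = 5,
                  occurrences: dict | None = None) -> list[AssemblySpec]:
    """The five-assembly benchmark: disjoint 5-member groups, one per type."""
    occ = dict(_FIGURE1_OCCURRENCES)
    if occurrences:
        occ.update(occurrences)
    specs = []
    for k, atype in enumerate(_FIGURE1_TYPES):
        members = tuple(range(k * n_members, (k + 1) * n_members))
        specs.append(AssemblySpec(atype=atype, members=members,
                                  n_occurrences=int(occ[atype])))
    return specs


def generate_scenario(name: str, overrides: dict | None = None,
                      seed=None) -> tuple[SpikeDataset, GroundTruth]:
    """Generate a named benchmark scenario.

    ``"figure1"``: 50 AR-driven Poisson units with five disjoint 5-member
    assemblies (one per type I-V) embedded.  ``"step_rate"``: two Bernoulli
    units with step-like rate states (overrides: ``variant`` in
    {"fast", "slow"}, ``coupled``, ``total_bins``).  ``"oscillation"``: two
    units under common 4-Hz drive (override ``with_patterns``).
    """
    ov = dict(overrides or {})
    rng = as_rng(seed)
    if name == "figure1":
        bg = BackgroundConfig(n_units=int(ov.pop("n_units", 50)),
                              duration=float(ov.pop("duration", 1400.0)))
        specs = figure1_specs(occurrences=ov.pop("occurrences", None))
        if ov:
            raise ValueError(f"unknown overrides {sorted(ov)}")
        ds, _ = generate_background(bg, rng)
        truth = GroundTruth()
        for spec in specs:
            ds, t = embed_assembly(ds, spec, rng)
            truth = truth.merged(t)
        return ds, truth
    if name == "step_rate":
        variant = ov.pop("variant", "fast")
        m, L = (25, 3000) if variant == "fast" else (1, 75000)
        total = int(ov.pop("total_bins", 1_000_000))
        scale = total / 1_000_000
        cfg = StepRateConfig(total_bins=total,
                             m=int(ov.pop("m", max(int(round(m * scale)), 1))),
                             L=int(ov.pop("L", max(int(round(L * scale)), 1))),
                             coupled=bool(ov.pop("coupled", True)))
        if ov:
            raise ValueError(f"unknown overrides {sorted(ov)}")
        return cfg.dataset(rng)
    if name == "oscillation":
        cfg = OscillationConfig(
            duration=float(ov.pop("duration", 1500.0)),
            with_patterns=bool(ov.pop("with_patterns", False)),
            pattern_count=int(ov.pop("pattern_count", 90)))
        if ov:
            raise ValueError(f"unknown overrides {sorted(ov)}")
        return cfg.dataset(rng)
    raise ValueError(f"unknown scenario {name!r}")
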