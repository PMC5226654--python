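# Methods

## Problem and model

Given `N` simultaneously recorded spike trains over a common span, the goal
is to find groups of units whose joint spiking at some temporal resolution
Δ exceeds what independent firing would produce, together with the lag
constellation of the pattern.  Detection must not be fooled by firing-rate
non-stationarity: slow (co-)modulations of rate — oscillatory drive,
behavioural state changes, stimulus responses — produce excess coincidences
at every fine scale without any fine-scale coupling.

### Counting layer

Spike trains are binned at width Δ into `T = floor(span/Δ)` half-open
bins (`[left, right)`, trailing partial bin dropped).  A count series with
maximum count `M` decomposes into `M` nested binary layers (layer α marks
bins with count ≥ α); rank-matched layer pairs give the lagged joint count,
which collapses exactly to `Σ_t min(c_A[t], c_B[t+l])`.  The package uses
the min-sum form computationally and keeps the layer form for moments and
as an independent oracle in the tests.

For a pair, the lag with the maximal joint count over `{-l_max..l_max}` is
selected (tie-break: smallest `|l|`, then the non-negative lag — favouring
the synchrony/parsimony reading; ties are rare in real data).  Selecting
the maximal count is equivalent to testing every lag and keeping the
smallest p, and the multiple-testing budget below charges for all
`2 l_max + 1` lags accordingly.

### Null moments

Conditional on the per-layer marginal totals, each layer coincidence count
is hypergeometric under independence; with the nested-layer covariances the
joint count has closed-form mean `Σ_α #A^α #B^α / T̃` (`T̃ = T − |l|`) and
variance with layer-depletion factors.  Marginal totals are recomputed on
the overlapping window of length `T̃` for every lag so that counts at
different lags use comparable marginals.

### Non-stationarity correction

The test statistic is the difference between the selected-lag count and a
reference-lag count, `#ABBA,l = #AB,l − #AB,l*`, with `l* = −l` for
directed patterns and `l* = −2` for synchrony (`l = 0`); a fixed reference
`l* = −(l_max+1)` for all lags is available as a configuration option.
Rate fluctuations slower than the lag span affect both counts alike and
cancel.  Under the null the difference has expectation zero; the plug-in
mean term `μ̂` (difference of the window-marginal means at the two lags) is
retained rather than set to zero — the two counts run over slightly
different windows, and dropping the term measurably miscalibrates the far
tail.

The variance of the difference is estimated segment-wise: the series is cut
into segments of `k = 100` bins (a trailing remainder of at least
`2(|l|+1)` bins forms a last shorter segment, smaller remainders merge into
the previous one), and per-segment layered variances and forward/reference
covariances are combined as `σ̂² = 2 Σ_c var_c − 2 Σ_c cov_c`,
neglecting cross-segment covariance.  Within a segment the forward and
reference counts share marginals, and the cross-lag covariance of the
layered counts under the permutation null works out to `−var_c/(k_c − 1)`
(derived by summing position covariances of a permuted series; a
Monte-Carlo permutation oracle confirms that `2var − 2cov` matches the
empirical variance of the difference count to better than 1%).  The
covariance term is therefore a small positive correction to `2 var`.

Finally `Q = (#ABBA − μ̂)²/σ̂²` is referred to `F(1, v)` with
`v = 2(T−|l|)M − 1` (`M = min(M_A, M_B)`); for short series (`T < 50`) the
conservative `v = T − |l|` is auto-selected.  Pairs whose expected joint
count is ≤ 4 are flagged untestable (the distributional approximations
degrade in that regime), and significance additionally requires a positive
difference (excess in the selected direction).

At coarse Δ, counts may never fall to zero; the non-informative floor
(series minimum) is subtracted from both series before testing whenever
both minima are positive.

## Agglomeration

Detection at one Δ starts from all `N(N−1)/2` pair tests at the Bonferroni
level `α / R₁`, `R₁ = N(N−1)(2 l_max + 1)/2`.  Significant pairs become
two-unit assemblies; the activation series of an assembly (per anchor bin,
the min over members of their lag-shifted counts — the same multiplicity
rule as the joint count) is then treated exactly like a unit and tested
against every candidate unit that is significantly paired with at least
one member (the apriori-style restriction).  Each extension iteration
spends `R_i = N_{a,i} · N_{u,a} · (2 l_max + 1)` per assembly.  After each
iteration, same-unit-set assemblies with different lag vectors keep only
the lowest p; the loop ends when nothing is added, and strict unit-subsets
are pruned.  Assemblies store lags relative to the first (anchor) unit;
only each fusion step's *new* relative lag is bounded by `l_max`, so
cumulative lag spans may exceed it (chains).  The scheme is repeated across
the user's Δ grid, and each unit set's characteristic scale Δ* is the Δ of
its lowest p.  Optional across-scale pruning (membership cosine distance
< 0.3 keeps the lowest p; across-scale subset removal) is off by default —
it is a presentation aid.

Iteration order over units and assemblies is fixed (sorted unit ids), so
detection is fully deterministic given the input and configuration.

The package exposes this as a scikit-learn estimator (`AssemblyDetector`,
with `fit`, `fit_predict`, `labels_`, `catalog_`).  A dendrogram-style
strict hierarchical variant (`agglomerate_hierarchical`) is provided as an
optional mode, off by default: at each step only the lowest-p pair of
current lists fuses, which reveals strictly nested structure but by
construction suppresses partially overlapping assemblies and misses many
higher-order sets — use it for hierarchy inspection, not as the primary
detector.

## User-facing activation

An activation instance of a detected assembly exists wherever the member
bins at the prescribed lag offsets are all non-zero; its multiplicity is
the *product* of member bin counts (every combination of member spikes in
the right order counts), and the instance is timed by the earliest-spiking
member's actual spike times within its bin.  Note the deliberate asymmetry:
the internal agglomeration series uses min-multiplicity (consistent with
the joint-count identity), while the reported activation score uses the
combinatorial product, which can far exceed one for coarse-scale rate
assemblies.

## Synthetic ground truth

The background emulates non-stationary in-vivo-like activity: each unit is
an inhomogeneous Poisson process whose latent state follows a stable AR(1)
(`D = 0.9·I`, noise sd `σ_s = 0.01`) pushed through
`λ_t = (1 + erf(υ s_t / σ_s)) λ̄` (`υ = 0.2`, `λ̄ = 5 Hz`), so rates stay
in `(0, 2λ̄)`.  The AR latent advances every 10 ms (the update interval is
a package choice; it puts rate fluctuations on a ~0.1 s correlation time,
i.e. slower than the fine detection scales and faster than the coarsest).
Inter-spike intervals are drawn exactly by time-rescaling inversion of the
piecewise-constant rate, and a constant 15-ms refractory delay is added to
every interval.  The refractory delay biases realized rates to
`≈ 1/(1/λ̄ + τ_ref) = 4.65 Hz`; the construction is kept as specified
rather than re-normalised.

Five assembly archetypes are embedded at uniformly random anchor times
(overlaps allowed), with background spikes within ±15 ms of every inserted
spike erased to preserve the refractory period:

* **I** — one synchronous spike per member;
* **II** — a sequence with successive gaps drawn once from U[0, 0.1] s and
  then frozen;
* **III** — a frozen multi-spike pattern (per member a 10-Hz Poisson draw
  over 0.2 s, redrawn until every member has ≥ 1 spike);
* **IV** — sequential 0.3-s windows (gaps U[0, 0.4] s, frozen) of extra
  10-Hz Poisson spikes redrawn per occurrence;
* **V** — 1-s windows of +5 Hz extra Poisson spikes in all members
  simultaneously (5 → 10 Hz rate step).

The five-assembly benchmark (`generate_scenario("figure1")`) embeds one
assembly per type as disjoint 5-unit groups among 50 units over 1400 s.
Default occurrence counts (350 for I–IV, 200 for V, whose occurrences
each contribute ~10 spikes per member) put every type in the saturated
regime of the occurrence-rate sweep — the regime the benchmark presumes;
they are tunable per type.  Spike-sorting errors are simulated by
reassigning a chosen fraction of all spikes to uniformly drawn other
units, conserving total spike count.

Two-unit calibration scenarios: Bernoulli processes with `m` high-rate
states of `L` elementary bins (coupled or independent; the step-rate
scenario emits series at elementary resolution and is binned in
elementary-bin units), and a common 4-Hz oscillatory drive
`λ = 5(0.6 sin(2π·4t) + a)` with `a_A = 1`, `a_B = 0.5` — read with 0.6
multiplying the sinusoid, the only reading that yields the stated 5 and
2.5 Hz means; unit B's negative instantaneous rates are clipped at zero,
which lifts its realized mean a few percent.

What the generator does *not* emulate: bursting, spike-waveform overlap,
cross-unit refractoriness, behavioural covariates, or electrode drift.
Passing the benchmark therefore shows correctness of the statistics and
the agglomeration on controlled pattern structure, not robustness to every
real-data pathology.

## Evaluation

The Rand index over unit pairs, `R = (r + s)/(n(n−1)/2)`, compares the
detected membership partition with the ground truth; units outside any
assembly act as singletons, and the comparison universe defaults to the
union of true and detected assembly units (the natural choice when the two
memberships differ; an explicit universe can be passed).  Retrieval
metrics match each detected assembly to the true assembly of maximal unit
overlap (ties toward lower p): `retrieval` is the fraction of true members
recovered, `false_fraction` the fraction of units pulled into an assembly
they do not belong to.  An assignment matrix (units × assemblies, cells =
lag, plus a Δ row) mirrors the catalogue for inspection.

## Numerical and design choices

* Bins half-open, trailing partial bin dropped; all units share `T`.
* Duplicate (unit, time) rows are kept as two spikes (representable after
  binning); a warning is logged.
* Units below 0.2 Hz can be excluded via `min_rate` (off by default).
* Null-calibration checks use multi-valued counts (Bernoulli series
  aggregated over 100 elementary bins per detection bin): with purely
  binary counts the difference statistic is too discrete for a meaningful
  comparison against the continuous F reference, although its tail
  rejection rates remain calibrated.
* The exact denominator d.f. under segmented variance estimation are
  unknown; `v` is configurable (`full`, `conservative`, `auto`).
* Degenerate inputs: silent units are flagged untestable; zero estimated
  variance with a nonzero difference is flagged untestable and never
  significant.

## Problem sizes

The test suite and the acceptance script run everything at desk scale by
design: the five-assembly benchmark at four bin widths; calibration with
4000 stationary pairs of 2000 bins plus scaled non-stationary variants;
family-wise error on 200 ten-unit datasets of 200 s; and ten replicates
per condition for the occurrence-rate, sorting-error and false-assignment
sweeps (types tested separately, 30 units, 700–1400 s).  These sizes give
standard errors comfortably inside the assertion tolerances while keeping
a full run in the tens of minutes on one core.

## Known limitations

* Exactly time-reversed patterns at the same scale cancel in the mirrored
  difference statistic (use the fixed-reference option to probe this).
* Sequential patterns suffer bin-phase noise: a frozen lag of, say, 4.7
  bins quantizes to 4 or 5 depending on the anchor's phase, reducing
  single-lag-vector activation recall for type-II-like structure; purely
  synchronous patterns are immune.
* The apriori-style agglomeration cannot find higher-order structure none
  of whose unit pairs is marginally significant (a triplet test in the
  suite demonstrates both the limitation and that the extension statistic
  itself sees such structure once a pair is formed).
* The gate on expected joint counts interacts with fusion depth for very
  sparse activation series at coarse Δ; the gate is applied uniformly.
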