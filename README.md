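# spikecad

Multi-timescale cell-assembly detection in multivariate spike recordings.

Neurons are thought to organize into *cell assemblies*: groups of units
whose spiking forms recurring supra-chance patterns with specific lag
constellations — from sharp synchrony and precise sequences to coordinated
rate co-modulations extending over seconds.  `spikecad` detects such
structure in multiple parallel spike-time series at user-chosen temporal
resolutions, for users analysing multi-single-unit electrophysiology
(tetrode/silicon-probe recordings) or validating detection pipelines on
simulated ground truth.

## The statistic

Spike trains are binned at width Δ, and every count series `{c_t}` is split
into `M = max(c_t)` nested binary layers (layer α marks bins with
`c_t ≥ α`).  The joint count of two units at lag `l` is the layer-matched
coincidence sum

    #AB,l = Σ_α Σ_t a_t^α b_{t+l}^α = Σ_t min(c_A[t], c_B[t+l]),

whose null mean and variance follow from multivariate-hypergeometric layer
moments given the marginals.  Because slow firing-rate (co-)fluctuations
corrupt these moments, significance is assessed on the **difference count**

    #ABBA,l = #AB,l − #AB,l*,    l* = −l  (or −2 when l = 0),

in which non-stationarity on scales slower than the lag span cancels
locally.  Its variance is estimated from short segments (k = 100 bins), and

    Q_l = (#ABBA,l − μ̂)² / σ̂²  ~  F(1, v),    v = 2(T−l)M − 1,

is used for fast, surrogate-free parametric testing.  Significant pairs are
recursively agglomerated into higher-order assemblies — each formed set's
activation series is tested against candidate units exactly like a unit,
so the scheme tests genuine higher-order factorizations — under strict
Bonferroni budgeting, and the whole procedure is repeated over a range of
bin widths; each assembly's characteristic scale Δ* is the width of its
lowest p-value.

## Worked example

```python
from spikecad import AssemblyDetector, generate_scenario, retrieval_metrics

# 50 units, 1400 s; five disjoint 5-unit assemblies of types I-V embedded
ds, truth = generate_scenario("figure1", seed=1)

det = AssemblyDetector(bin_widths=(0.015, 0.05, 0.15, 1.0), l_max=10).fit(ds)
for a in det.assemblies_:
    units, lags = a.normalized()
    print(f"Δ={a.delta:<5} Δ*={a.delta_star:<5} units={units} lags={lags} "
          f"p={a.p_value:.1e}")
print(retrieval_metrics(truth, det.catalog_, n_units_total=50))
```

Output (abridged):

```
Δ=0.015 Δ*=0.015 units=(0, 2, 4, 3, 1)      lags=(0, 0, 0, 0, 0)  p=0.0e+00
Δ=0.015 Δ*=0.015 units=(5, 6, 7, 8, 9)      lags=(0, 4, 6, 11, 14) p=1.9e-141
Δ=0.015 Δ*=0.015 units=(10, 11, 13, 14, 12) lags=(0, 0, 2, 2, 6)  p=0.0e+00
Δ=0.15  Δ*=0.15  units=(15, 16, 17, 18, 19) lags=(0, 2, 3, 5, 6)  p=6.7e-15
Δ=1.0   Δ*=1.0   units=(23, 24, 20, 22, 21) lags=(0, 0, 0, 0, 0)  p=1.4e-13
{'retrieval': 1.0, 'false_fraction': 0.0, 'n_detected': 13, 'n_true': 5}
```

The synchronous assembly (units 0–4) is found at the finest width with all
lags zero; the sequence (5–9) carries its embedded lag vector in 15-ms
bins; the window-sequence (15–19) and the rate assembly (20–24) emerge at
their own coarser scales.  All 25 embedded units are recovered
(`retrieval = 1.0`) and no background unit is pulled into any assembly
(`false_fraction = 0.0`); the remaining catalogue entries are the same
assemblies re-detected at neighbouring widths (the characteristic scale
Δ* marks each unit set's best width).

A command-line interface covers the same pipeline end to end:

```sh
spikecad simulate --scenario figure1 --seed 1 --out spikes.csv
spikecad detect --input spikes.csv --binwidths 0.015,0.05,0.15,1 \
    --maxlag 10 --alpha 0.05 --out catalog.json
spikecad activation --input spikes.csv --catalog catalog.json
spikecad evaluate --truth spikes.truth.json --detected catalog.json
```

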