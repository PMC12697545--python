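# axistrace

Axis-weighted discovery of 3D-genome features — chromatin loops, TAD
boundaries (with hierarchy) and A/B compartments — from chromatin tracing
data (multiplexed DNA FISH / seqFISH+ style experiments).

## The problem

Chromatin tracing localizes consecutive genomic segments (e.g. sixty
25-Kb bins) in 3D across hundreds to thousands of chromosome copies.
Localization precision differs between the lateral and the optical axes,
often by a factor of two or more.  Tools that analyze the 3D Euclidean
distance matrix mix the axes with equal weight and inherit the worst
axis's noise; their loop, TAD and compartment calls degrade quickly as
axial noise grows.

`axistrace` instead models each centered trace per axis as
`x = x̃ + ε_x` with shared signal `x̃ ~ N_p(0, K)` and axis noise
`ε_a ~ N_p(0, σ²_a I)`.  It (1) estimates σ²_a from the median diagonal
of each axis's sample covariance (a spiked-covariance argument) and forms
inverse-variance weights `w_a ∝ 1/σ̂²_a`; (2) reduces each axis's pairwise
differences `x_ij − x_ik` to a normalized p×p variance matrix (robust
median-based variance, lowess distance-decay curve, 4-SD outlier filter,
distance normalization); (3) runs per-axis tests — a lower-tail F test
against a 25–50 Kb local background ring for loops, an upper-tail
inter- vs intra-domain F test in a 200-Kb window for boundaries, a
second-eigenvector embedding for compartments; and (4) recombines axes
with the weights, via the aggregated Cauchy combination

    T = Σ_a w_a tan((0.5 − p_a)π),   p = 0.5 − arctan(T)/π

for the tests, or weight-scaled 2-means clustering for compartments.
See `docs/methods.md` for the full model, conventions and limitations.

Input is the 4DN FISH Omics Format for Chromatin Tracing (FOF-CT core
CSV); outputs are plain CSV/BEDPE/BED/bedGraph tables.

## Worked example

Simulate a dataset with three planted loops and call features:

```bash
axistrace simulate --out sim.csv --truth truth.json --seed 3
axistrace weights --input sim.csv --chrom chrSim --out-dir out
axistrace loops   --input sim.csv --chrom chrSim --out-dir out
```

Or from Python:

```python
import axistrace as ax
from axistrace.synthetic import loop_scenario, simulate_planted

ds, truth = simulate_planted(loop_scenario(seed=3))   # 250 traces x 60 bins
ds = ax.center_traces(ds)
field = ax.build_field(ds)                 # normalized per-axis variance matrices
w = ax.compute_axis_weights(ds)
print(dict(zip("xyz", w.w.round(3))))
calls = ax.call_loops(ds, field, w)
print(calls.loc[calls.is_final, ["j", "k", "p", "fdr", "contact_freq"]])
```

which prints (axis weights near 1/3 on this uniform-noise simulation, and
all three planted anchor pairs as final loops):

```
{'x': 0.336, 'y': 0.329, 'z': 0.335}
       j   k             p           fdr  contact_freq
531   10  30  9.992007e-16  1.594724e-12      0.311881
951   20  45  3.361089e-12  2.682149e-09      0.168269
1381  35  55  7.747958e-08  2.473148e-05      0.195980
```

The planted pairs were simulated with proximity factors 0.30, 0.40 and
0.50 (anchor difference variance shrunk to that fraction of its local
background), and the recovered p-values grade accordingly, from the clip
floor ~1e−15 up to ~8e−8 — all below the 1e−5 summit cutoff.
`contact_freq` is the fraction of traces with the anchors within 500 nm.
TAD and compartment calling follow the same pattern via `ax.call_tads`
and `ax.call_compartments`.

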