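# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order data flows through it.

## Graph model and metrics

A connectivity matrix is an `N × N` symmetric non-negative matrix with an
exactly-zero diagonal; weights are expected in `[0, 1]` (correlation-type
inputs are absolute-valued and max-normalized by the reader when requested).
Distances are point-wise inverses, `d = 1/w`, with `+inf` for absent edges.

- **Global efficiency** averages inverse shortest-path lengths; disconnected
  pairs contribute `1/inf = 0` (the standard Latora–Marchiori convention —
  the defining formula is silent on disconnection). GE is therefore defined
  for every graph, lies in `[0, 1]` when weights do, and equals 1 exactly on
  the complete unit-weight graph.
- **Local efficiency** of a node is the global efficiency of the subgraph
  induced by its neighbours, weights retained; fewer than two neighbours
  gives 0.
- **Weighted clustering** uses the Onnela geometric-mean form (normalized by
  the maximum weight), as computed by networkx; the choice is isolated in
  one function and cross-checked against a direct triple-loop computation in
  the tests.
- Shortest paths use Dijkstra (scipy.sparse.csgraph). An edge is "used by a
  shortest path" iff it completes some pair's optimal path within an
  additive tolerance of `1e-12`, absorbing floating-point path-sum noise.

## OMST filtering

Kruskal's algorithm processes edges in ascending `(distance, i, j)` order —
a deterministic tie-break; the MST itself is unique only for unique weights.
Orthogonal rounds repeatedly extract an MST and set its edges to `+inf`.
Rounds stop when the residual graph can no longer span (or, in the
spanning-forest mode used on masked window-graphs, has no edges), when the
round cap `⌊E/(N−1)⌋` is reached, or — during filtering — after a full round
fails to improve the best `J`: the cost term grows monotonically while GE is
bounded by 1, so late rounds cannot win.

`J = GE − Cost` is evaluated after every single edge addition, in round
order and within-round Kruskal acceptance order. Cost is the weighted form:
retained weight over the total strength of the original graph. The selected
prefix is the first global maximizer of `J`, floored at the complete first
MST so the backbone is always connected. Note a structural consequence: if a
planted backbone carries a large fraction of total strength (e.g. three
strong trees over weak noise), its full cost can exceed any attainable GE
gain, and the `J`-optimum legitimately retains only part of it — selection
is then backbone-pure (high precision) but not exhaustive (partial recall).
The acceptance script reports both numbers.

The threshold-sweep comparison (`gce_sweep_filter`) scans absolute
thresholds from the smallest to the largest positive weight and reports both
the weighted-cost `J` (commensurable with the OMST curve; the default) and
the binary-cost variant (retained edges over possible edges), since the
original formulation of cost-efficiency sweeps is stated with binary cost.
Proportional thresholding resolves ties at the cutoff weight in ascending
index order so the edge-count contract is exact. Frobenius matching scans
the scheme grid (default steps 0.01 absolute, 1% proportional, 0.1 mean
degree) and returns the first norm-minimizing parameter.

## Dynamic iPLV layer

Signals are band-pass filtered with 3rd-order Butterworth filters applied
forward-backward (zero phase), phases taken from the Hilbert analytic
signal. The eight default bands are 0.5–4, 4–8, 8–10, 10–13, 13–20, 20–30,
30–48 and 52–70 Hz. Sliding windows are `cycles / f_center` seconds wide
(default 10 cycles of the band's centre frequency, configurable — published
window-count conventions are not mutually consistent, so the convention is
explicit here) and step by 20 ms by default; window counts therefore differ
per band and the 4-D tensor is NaN-padded past each band's own count.

Statistical masking uses time-rotation surrogates: each channel is cut once
at a uniform random point inside a central window (default the middle 10 s)
and the two segments are exchanged — the sample multiset is preserved
exactly and phase dynamics minimally distorted. A pair's surrogate couples
the *original* first channel with the *rotated* partner: this is what makes
the central cut window meaningful, since it guarantees the surrogate pair is
misaligned by at least the window's lower edge — far beyond the band's phase
coherence time — whereas two independently rotated channels can land at a
near-zero relative offset and reproduce the genuine coupling. One-sided
p-values use the `(1 + #{surr ≥ obs})/(1 + S)` permutation correction
(default `S = 1000`; reducible for speed). Benjamini–Hochberg FDR at
`q = 0.01` is applied across sensor pairs within each band and window
(optionally pooled over windows); surviving iPLV values are kept unchanged,
others set to 0.

Note the attainability arithmetic: the smallest possible p-value is
`1/(S+1)`, so a coupled pair can only ever survive BH over `m` pairs if
`1/(S+1) ≤ q/m`. Calibration runs must respect this (e.g. 200 surrogates at
`q = 0.01` support a single-pair recording but not six pairs per window).

## Fingerprinting

Per band and node, the masked window-graphs are filtered (the OMST scheme
runs in spanning-forest mode there, since masked slices may be
disconnected) and a nodal metric — nodal global efficiency by default —
yields one time series per (band, node). Each series is split into halves
(odd length: extra sample to the first half).

Delay embedding follows the Ragwitz principle: choose `(d_e, d_t)`
minimizing the local-constant one-step prediction error (k = 5 nearest
neighbours, error normalized by the series sd) over `d_e ∈ 1..8`,
`d_t ∈ 1..10`; ties go to the smallest `d_e`, then `d_t`. Candidate halves
are embedded with the query's parameters so all clouds share one space.

The WW runs statistic builds the Euclidean MST of the pooled clouds (exact
O(N²) Prim on the dense distance matrix; exact duplicates are perturbed by
an index-keyed `1e-12` jitter to keep the MST unique), counts
`R = (cross-sample edges) + 1` and standardizes with the Friedman–Rafsky
moments (`E[R] = 2mn/N + 1`; the variance uses `C = Σ deg(deg−1)/2`, the
number of MST edge pairs sharing a node). The classification distance is
`w_dist = |w|·H(−w)`: only a deficit of runs (segregated clouds) counts as
dissimilarity. Identification is nearest-candidate voting per feature
(candidates: both halves of every other subject plus the target's remaining
half) with a majority across features; ties resolve to the smallest mean
distance. Greedy forward feature selection maximizes the in-sample
split-half recognition rate (an out-of-sample variant is a flag, since
published practice is ambiguous); the recognition rate is 100 × the mean
diagonal of the row-normalized confusion matrix.

## Reliability

ICC uses nodes as targets and scans as raters — for a single subject with
many scans, nodal values are the only dimension yielding a defined ICC. The
default form is ICC(2,1) (two-way random effects, single measure, absolute
agreement), computed from two-way ANOVA mean squares and verified against
pingouin's ICC(A,1); ICC(3,1) is available. Zero between-target variance is
an explicit error. Threshold optimization filters every scan at each grid
value and maximizes `ICC(GE) + ICC(LE)`, first grid value on ties.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (spec, seed).

- **Planted-backbone graphs** (default N = 32): the union of `m_true = 3`
  random edge-disjoint spanning trees weighted 0.7–1.0 over noise edges
  0.05–0.3, Gaussian jitter σ = 0.02 (small relative to the class gap),
  clipped and max-normalized. Emulates a strong sparse scaffold inside a
  dense weak background; it does not emulate spatially correlated weights or
  modular community structure.
- **Coupled oscillators**: narrowband-filtered white noise channels; a
  coupled destination mixes the source's analytic signal rotated by the
  prescribed phase lag with its own oscillator (weight κ), so ground-truth
  coupling lives purely in phase — exactly what iPLV measures. No volume
  conduction, no 1/f background, no artifacts.
- **Cohort NMTS**: per subject an AR(2) process with subject-specific pole
  angle (equally spaced over [0.15π, 0.85π], pole radius 0.95) normalized to
  unit sd plus a subject-specific level (0.8 sd spacing) and shared
  observation noise (σ = 0.05). "Strong signatures" means exactly this:
  separation sufficient for deterministic split-half identification, the
  regime the fingerprinting claim describes; the identical-signatures switch
  is the chance-level control. Real between-subject differences are weaker
  and higher-dimensional, so passing tests demonstrate the pipeline's
  mechanics, not field accuracy.
- **Multi-scan replicates**: base graph plus symmetric Gaussian edge noise
  (σ = 0.10 in the reliability head-to-head — comparable to the noise-edge
  weight scale), clipped and renormalized. Clipping at the interval edges is
  a small acknowledged bias.

## Problem sizes and numerical notes

The test suite and acceptance script run on deliberately modest sizes — the
package's own choice of desk-scale study conditions: complete graphs N ≤ 7
for exhaustive tree enumeration (all `N^(N−2)` Prüfer trees), N = 30–40 for
structure and `J`-dominance comparisons, 20-second 128-Hz recordings with
200 surrogates for masking calibration, 20-subject cohorts of 240-window
series, and 5-scan ICC replicates. Floating-point comparisons use additive
tolerances of `1e-12` (path membership, nodal-mean consistency) and the
filters never rescale retained weights, so filtered matrices are
bitwise-identical to the originals on kept edges.

## Known limitations

- OMST extraction is O(rounds × E log N); for dense graphs with hundreds of
  nodes the per-edge GE evaluation dominates and the early-stop rule
  matters.
- The 4-D tensor keeps all bands in one array; very different band centre
  frequencies waste padding.
- The WW identification cost grows linearly in subjects × features ×
  candidate halves; Ragwitz search is the other hot spot and can be bypassed
  with a fixed embedding.
- Directed or signed graphs are out of scope; correlation-type inputs are
  absolute-valued upstream of everything.
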