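# Methods notes

This note records the models, algorithmic choices, and defaults behind
`isletnet`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Signal model and preprocessing

A recording is a frames × cells fluorescence matrix at sampling rate `fs`
with planar cell coordinates in micrometers. Band separation uses a
second-order Butterworth band-pass applied forward and backward
(`sosfiltfilt`), i.e. an effective fourth-order zero-phase filter: the
cross-correlation peak between an in-band sinusoid and its filtered
version sits at exactly zero lag. Default bands: fast 0.05–2.0 Hz, slow
0.001–0.07 Hz, and a combined oscillatory band 0.005–0.25 Hz for isolated
islets. The filter order and the smoothing window (centered moving
average, shrinking at the edges so no values are fabricated) are
configurable; defaults are order 2 and window 1 (off).

**Binarization.** The active/inactive raster is produced per cell by a
Schmitt trigger on a robust amplitude scale: baseline = 10th percentile,
peak = 95th percentile of the filtered trace; a frame turns active above
`baseline + on_frac·(peak − baseline)` and stays active until the signal
drops below `baseline + off_frac·(peak − baseline)`. Defaults
`on_frac = 0.5`, `off_frac = 0.3`; hysteresis prevents threshold chatter
from fragmenting events, and events shorter than two frames (configurable
in seconds) are discarded. Cells whose amplitude range does not exceed
four robust high-frequency noise SDs (estimated from the first difference)
are marked all-inactive rather than binarizing noise. Whether percentile
scaling is computed per protocol interval or globally is up to the caller;
the pipeline computes it on whatever window it is given (per analyzed
interval by default). An optional SNR screen (`snr_screen`) automates the
rejection of artifact-laden cells; it is off by default.

## Similarity measures

Pearson correlation operates on filtered traces; coactivity and mutual
information on binarized rasters. Coactivity is implemented as the cosine
of the two binary vectors, `Σ x_i x_j / √(Σ x_i · Σ x_j)`, which is the
form consistent with its description as a normalized dot product and with
the endpoints 0 (no overlap) and 1 (identical rasters); the un-rooted
variant is available behind `literal_denominator=True` for comparison but
does not reach 1 for identical vectors. Entropies are frequency-count
estimates in bits; mutual information is `H_i + H_j − H_ij` over the four
joint states, normalized by the geometric mean `√(H_i H_j)` — the one
normalization for which a series paired with itself scores exactly 1.
Degenerate cells (zero variance, no active frames, zero entropy) receive
NaN rows/columns and never form edges. Matrices are explicitly
symmetrized to remove BLAS rounding asymmetry.

## Network construction

- *Fixed threshold*: edge iff `SC_ij > SC_th`, strictly — ties at the
  threshold are excluded.
- *Fixed average degree*: bisection on the threshold (≤ 60 iterations,
  tolerance 0.1 on `k_avg` by default); with tied similarity values the
  nearest achievable density is used and the applied threshold is
  recorded. Default target 8, mimicking realistic beta-cell connectivity.
- *Multilayer MST*: distances `D_ij = 2(1 − SC_ij)`; each layer is a
  Kruskal MST over the pairs unused by previous layers, with equal
  distances broken lexicographically on the cell-id pair for
  reproducibility. Kruskal and Prim coincide for distinct weights; the
  MST is invariant under strictly monotone transforms of `D`, so the
  exact functional form of the similarity-to-distance map does not affect
  the edge set (property-tested). Default 4 layers (`k_avg ≈ 8`). A
  residual-graph disconnection aborts with the completed layer count.
- *Geometric reference*: connect pairs within a Euclidean distance
  threshold, or bisect that threshold to a target `k_avg` (default 8 so
  functional and structural networks are compared at matched density).
- *Interval carry-over*: calibrate the variable threshold on interval 1,
  re-apply it as a fixed threshold on interval 2, so changes in
  coordinated activity appear as density changes instead of being
  normalized away.

Negative correlations get no special treatment: anticorrelated pairs
simply fall below any practically used threshold.

## Metrics

Degrees, triangle-based clustering, greedy modularity-maximization
partition and its Newman–Girvan `Q` (the partition is returned, so `Q` is
recomputable from it), global efficiency with `1/∞ = 0`, `L_avg` on the
largest component (it is undefined on disconnected graphs; efficiency
covers disconnection), `S_max`, and `SW = (C/⟨C_rand⟩)/(L/⟨L_rand⟩)` with
20 seeded random reference graphs matched in node and edge count
(density-matched; a degree-preserving configuration-model reference is
available via `sw_reference="degree"`). Edge lengths can be normalized by
the mean distance to the 8 nearest neighbors (fewer when N < 9), making
islets of different cell density comparable. Hubs are the top 1/6 of the
degree ranking, ties broken by cell id; degree–activity relations use
per-islet degree normalization `k/k_max` by default (`k/k_avg` by flag)
and optionally activity normalized by the islet mean for pooling.

## Synthetic islet simulator

The simulator emulates what the pipeline measures, at desk scale, with a
geometric wave model rather than a biophysical coupled-oscillator system:

- Cells are dart-thrown into a disc (default 100 cells, radius 100 μm,
  minimum spacing 9 μm). Wave initiators (default 3) are drawn from the
  outer 20% radius band; bursts rotate among them.
- Fast component: bursts with period 12 s (5 min⁻¹, the fast end of the
  1–5 min⁻¹ bursting range; chosen so the burst-train fundamental
  0.083 Hz lies above the slow band's 0.07 Hz edge — a slower default
  would leak fast-wave structure into the slow component), ±1 s period
  jitter. Each cell activates at the burst time plus its distance to the
  initiator divided by the wave speed (80 μm/s), for `duty × period`
  seconds; duty cycles are per-cell, Normal(0.3, 0.1) clipped to
  [0.1, 0.9]. A per-burst, spatially smooth conduction-delay field
  (squared-exponential, correlation length 40 μm, SD 1.5 s) models
  conduction variability: neighbors stay tightly coordinated while
  distant cells — including pairs equidistant from the initiator, which a
  purely geometric wave would leave perfectly synchronous — accumulate
  independent delays. This is what makes fast-component similarity decay
  with pair distance.
- Slow component: a sinusoid (period 400 s ≈ 0.15 min⁻¹) whose per-cell
  phase is a long-range smooth field (correlation length 300 μm, SD
  0.3 rad) plus an independent per-cell offset (SD 0.3 rad): the slow
  rhythm is coherent across the islet but not spatially organized at cell
  scale. Per-cell Ornstein–Uhlenbeck fluctuations (SD 0.3, τ = 60 s) add
  the finite-sample scatter that real slow-band correlation estimates
  have over a 20-minute recording. Without the offset and OU terms the
  slow similarity ranking degenerates (either distance-monotone or
  phase-clique structured) and the slow networks spuriously mimic the
  fast ones.
- Readout: events are passed through first-order indicator kinetics
  (rise/decay τ = 0.2 s, plateau 1 during sustained activity — modelling
  dye reporting lag; the calcium burst plateau itself is the event), the
  slow component is added with amplitude 0.5 versus 1.0 for fast, plus a
  baseline of 1 and Gaussian photon noise (SD 0.05). Asynchronous
  contaminant cells (e.g. non-beta cells) burst at independent random
  times. All randomness derives from one seed through per-stage
  substreams; identical configs give bit-identical output.

Defaults (1200 s at 5 Hz) are sized so a recording holds ~100 fast bursts
and 3 slow periods. With zero photon noise the pipeline recovers the
ground-truth rasters with per-cell Jaccard ≥ 0.8 and duty cycles within
0.02; the strict activation-order-by-distance property holds when the
conduction-jitter SD is set to 0 (it is a noise source distinct from
photon noise).

**What the simulator does not capture**: electrophysiology (channel and
gap-junction dynamics), 3D islet geometry, partial/colliding waves,
bleaching and motion artifacts, heterogeneous indicator expression, and
cell-type mixtures beyond the binary synchronous/asynchronous split.
Passing tests demonstrate that the pipeline detects the structures it is
designed to detect when those structures are present — not that real
islets have them.

## Numerical conventions

- Undefined similarity entries (diagonal, degenerate cells) are NaN and
  excluded from all edge logic; in distance space they map to +∞.
- Both-empty NSI is defined as 1 (identical empty edge sets) with a
  warning; hub overlap divides by the hub-set size, which both networks
  share by construction.
- Bisection problem sizes and the test-suite simulation sizes (100-cell
  islets, 5 seeds for the stochastic contrasts) are chosen to keep the
  full validation suite in the tens of seconds while leaving the
  stochastic assertions comfortably away from their majority thresholds.

## Known limitations

- The fixed-`k_avg` and multilayer-MST constructions enforce density, so
  they mask genuine changes in coordinated activity between conditions
  (the interval carry-over helper exists for exactly that case) and the
  MST forces connections to asynchronous cells — both behaviors are
  reproduced and tested as failure modes, not hidden.
- Greedy modularity maximization is deterministic but not optimal; `Q` is
  reported for the partition found.
- Coordinates are 2D; no correction for out-of-plane neighbors.
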