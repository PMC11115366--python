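# isletnet

Functional connectivity analysis of multicellular calcium imaging in
pancreatic islets.

Beta cells in an islet act as an electrically and metabolically coupled
collective. Confocal calcium imaging yields one fluorescence trace per
cell, superimposing two rhythms: fast bursting oscillations (~1–5 min⁻¹)
that propagate across the tissue as intercellular waves, and slow
metabolic oscillations (~0.1–0.2 min⁻¹) that are coherent over long
ranges. `isletnet` turns such recordings into functional networks — graphs
whose nodes are cells at their physical positions and whose edges denote
statistically similar activity — and quantifies their topology. It is
aimed at researchers analyzing islet (or other multicellular) calcium
recordings who need a reproducible, scriptable pipeline, and it ships a
synthetic islet simulator with known ground truth so every stage can be
validated without experimental data.

## Pipeline

1. **Preprocess** (`isletnet.preprocess`): zero-phase Butterworth band-pass
   into the fast (0.05–2.0 Hz), slow (0.001–0.07 Hz), or oscillatory
   (0.005–0.25 Hz) component; optional adjacency-averaging smoothing;
   hysteresis binarization into active/inactive states; relative active
   time (duty cycle) per cell.
2. **Similarity** (`isletnet.similarity`): for cells *i*, *j* with traces
   *x‌ᵢ*, *x‌ⱼ* and binarized rasters *x_b,i*, *x_b,j*:
   - Pearson correlation `PC_ij = corr(x_i, x_j)`;
   - coactivity `CA_ij = Σ_t x_b,i x_b,j / √(Σ_t x_b,i · Σ_t x_b,j)`
     (cosine of the binary activity vectors);
   - normalized mutual information
     `MĨ_ij = [H_i + H_j − H_ij] / √(H_i H_j)` in bits.
3. **Construct** (`isletnet.construct`): connect pairs with `SC_ij > SC_th`
   (fixed threshold); bisect the threshold to a target average degree
   `k_avg` (default 8); or build a **multilayer minimum spanning tree** —
   edge-disjoint MSTs computed sequentially on the abstract distance
   `D_ij = 2(1 − SC_ij)`, each layer adding `N − 1` edges (4 layers ⇒
   `k_avg ≈ 8`). A geometric network on the cell coordinates serves as the
   structural reference, and a threshold calibrated on one protocol
   interval can be carried over to another.
4. **Metrics** (`isletnet.metrics`): `k_avg`, average clustering `C_avg`,
   modularity `Q`, global efficiency `E`, average shortest path `L_avg`,
   relative largest component `S_max`, small-world coefficient `SW`, edge
   length distributions (optionally normalized by the mean 8-nearest-
   neighbor distance), hub cells (top 1/6 by degree), and the
   degree–activity relation.
5. **Compare** (`isletnet.compare`): network similarity index
   `NSI = |A∩A′| / |A∪A′|` (Jaccard overlap of edge sets), hub overlap,
   and per-cell degree pairing with R².

## Worked example

```python
import isletnet as isn

islet = isn.generate_islet(isn.IsletSimConfig(seed=1))   # 100 cells, 1200 s at 5 Hz
rec = islet.recording

fast = isn.bandpass_filter(rec, isn.FilterSpec.named("fast"))
S = isn.pearson_matrix(fast)
net = isn.fixed_kavg_network(S, target_kavg=8.0, coords=rec.coords)
m = isn.compute_metrics(net, sw_randomizations=20, seed=1)
geo = isn.reference_geometric_truth(islet, 8.0)

print(f"k_avg = {m.k_avg:.2f}  threshold = {net.construction['threshold_used']:.3f}")
print(f"C_avg = {m.C_avg:.3f}  Q = {m.Q:.3f}  E = {m.E:.3f}  L_avg = {m.L_avg:.3f}")
print(f"NSI(fast, geometric) = {isn.nsi(net, geo):.3f}")
```

prints

```
k_avg = 7.94  threshold = 0.661
C_avg = 0.466  Q = 0.502  E = 0.338  L_avg = 3.356
NSI(fast, geometric) = 0.401
```

The bisected correlation threshold 0.661 yields a network within the 0.1
degree tolerance of the target `k_avg = 8`. High clustering and modularity
with moderate efficiency reflect the wave-like, spatially local fast
component, and the NSI of 0.40 against the geometric reference shows the
fast functional network recovering a large share of the physical
neighborhood structure. Building the 4-layer multilayer MST on the same
matrix instead gives exactly `4 × 99 = 396` edges (`k_avg = 7.92`).

There is also a CLI:

```bash
isletnet simulate --n-cells 100 --seed 1 --out rec.csv --coords-out coords.csv
isletnet similarity rec.csv --band fast --method correlation --out sim.csv
isletnet network sim.csv --method multilayer_mst --coords coords.csv --out edges.csv
isletnet run config.yaml          # full YAML-configured pipeline
```

## Layout

- `src/isletnet/` — library modules (`recording`, `preprocess`,
  `similarity`, `construct`, `metrics`, `compare`, `simulate`, `io`,
  `pipeline`, `cli`).
- `tests/` — unit, property, and acceptance suites (all synthetic data is
  generated at test time).
- `docs/methods.md` — model and algorithm notes, parameter defaults, and
  known limitations.
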