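# combfish

Combinatorial in-situ transcript decoding for multiplexed FISH experiments.

In combinatorial in-situ sequencing, every mRNA of interest is amplified
into a rolling-circle product (RCP) — a bright, diffraction-limited dot —
and re-labelled over several rounds of hybridization so that each gene
traces a characteristic *sequence of dye colours* across rounds. `combfish`
turns the resulting image stacks back into a table of transcript calls:

* **Codebook** — each gene `g` is written in base-7 digits `(g2, g1, g0)`
  and shown, on round `r`, the dye
  `D(g, r) = (g2·r² + g1·r + g0) mod 7` — a Reed–Solomon codeword over
  GF(7). Any two codewords differ in at least 5 of the 7 rounds, and the
  seven constant codes are never used (they look like fixed background).
* **Filtering & detection** — every tile is band-pass filtered with a
  difference of Hannings (sum-one kernels of radius 0.5 µm and 1 µm);
  spots are strict local maxima above a robust (MAD-based) threshold.
* **Stitching & registration** — overlapping tiles are aligned by
  exhaustive shift search maximizing `Σ_s exp(−D_s²/8)` over nearest-spot
  distances, tile origins solved by least squares, and every
  (round, channel) image is fine-aligned to the anchor round with an
  affine fitted by iterative closest point (3 px match cutoff).
* **Cross-talk** — dye signatures `c_d` are estimated from well-isolated
  spots by *scaled k-means*, clustering colour vectors onto rays
  `λ·c_d` rather than centroids.
* **Gene calling** — each pixel's 49-dimensional (round × channel) vector
  is decomposed by orthogonal matching pursuit over unit-norm gene codes
  `a_g = [ε_{g,1}c_{d_{g,1}}; …; ε_{g,7}c_{d_{g,7}}]` plus per-channel
  background codes; per-gene weight images are peak-picked into calls.
  The per-gene/round efficiencies `ε_{g,r}` are learned from unambiguous
  detections of a first pursuit pass.

A synthetic-experiment simulator (`combfish.simulate`) generates multi-tile,
multi-round image sets with planted spots, cross-talk, efficiencies,
per-round shifts, chromatic affines, background and noise — with full
ground truth — so the entire pipeline is testable without microscopy data.

## Worked example

```bash
combfish simulate exp --seed 3 --grid 2 --tile-size 128 --spots-per-tile 40
combfish run exp --out exp/out
combfish score exp/out/calls.csv exp/truth.csv
```

prints

```
wrote 224 tiles, 176 planted RCPs -> exp
176 transcript calls -> exp/out/calls.csv
precision=0.9886 recall=0.9886 gene_accuracy=1.0000
```

i.e. the simulator planted 176 RCPs across a 2×2 grid of 128-pixel tiles
(224 TIFFs = 4 tiles × 8 rounds × 7 channels); the pipeline emitted 176
calls of which 98.9% sit within 2 px of a planted RCP, 98.9% of planted
RCPs were recovered, and every matched call carries the correct gene.
`exp/out/` also holds every intermediate: per-tile spot tables, stitched
tile origins, per-(tile, round, channel) affine transforms, the estimated
cross-talk matrix, the ε table, and the calls CSV
(`call_id,gene_name,global_row,global_col,weight,tile`) with a provenance
sidecar. Re-running `combfish run` resumes from these files and reproduces
the calls byte for byte.

The same flow is available as a library:

```python
from combfish import SimulationConfig, TileImageSet, run_pipeline, score_calls, simulate_experiment

exp = simulate_experiment(SimulationConfig(seed=3))
result = run_pipeline(TileImageSet.from_simulation(exp), exp.codebook, out_dir="out")
precision, recall, gene_acc = score_calls(result["calls"], exp.truth)
```

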