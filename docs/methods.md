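# Methods

This note records the models, conventions and numerical choices behind
`combfish`, and what the synthetic experiments do and do not demonstrate.

## Image model

An experiment consists of images `I_{R,C,T}(x)`: sequencing round `R`
(seven combinatorial rounds, indices 0–6, plus one anchor round, index 7),
colour channel `C` (seven dyes, one channel each), tile `T` (a square grid
with 10% nominal overlap), pixel coordinates `x = (row, col)`, zero-based,
half-open tile extents. Every RCP of gene `g` appears in round `r` in
channel profile `amplitude · ε_{g,r} · c_{d_{g,r}}`, where `d_{g,r}` is the
dye the codebook assigns, `c_d` is the dye's unit-norm channel signature
(cross-talk), and `ε_{g,r}` a per-gene/round efficiency reflecting unequal
bridge-probe concentrations. The anchor round labels every RCP in one
channel and drives all geometry.

## Codebook

Gene integers are expanded in base `n_dyes` and the dye for round `r` is
the modular polynomial `D(g, r) = g2·r² + g1·r + g0 (mod n_dyes)`.
`n_dyes` must be prime (so that the evaluation points form a field and the
degree-≤2 agreement bound holds) and `n_rounds ≤ n_dyes` (distinct
evaluation points); any such prime is accepted, enabling exhaustive tests
on 3-dye toy schemes. Two distinct polynomials of degree ≤ 2 agree at no
more than 2 points, giving minimum Hamming distance `n_rounds − 2`
(5 for the 7×7 default, verified by brute force over all 336 usable
codewords). Constant codewords (`g < n_dyes`) are skipped because they
cannot be told apart from static background fluorescence; genes receive
ascending usable integers in input order — the mapping is a convention
(no published per-gene assignment exists) and does not affect decoding.

## Filtering and spot detection

RCP images are convolved with a difference of Hannings: separable
outer-product Hanning kernels of half-width `round(r/pixel)` pixels
(defaults 0.5 µm and 1.0 µm at 0.1625 µm/px → 3 and 6 px), each normalized
to sum 1, subtracted. The difference sums to zero, so constant offsets
vanish exactly. Boundary handling is edge-repeating reflection, which
avoids the spurious edge maxima zero-padding would create. Nuclear-stain
images use a disk white top-hat of radius 8 µm instead. Spots are strict
8-neighbourhood maxima at or above `k·MAD` of the filtered tile
(`k = 6` by default; the acquisition-specific absolute threshold of the
original instrument is not published, so a robust relative rule is used).
Equal-valued plateaus are reported once, at their lexicographically
smallest pixel; a plateau with no strictly lower neighbour (a constant
image) is not a maximum.

## Stitching

For each neighbouring tile pair, spots from the two nominal overlap bands
(±10 px margin) are aligned by exhaustive integer-shift search within
±50 px of the stage-predicted offset, maximizing `Σ_s exp(−D_s²/8)` with
`D_s` the distance to the nearest counterpart spot; ties break toward the
expected shift, then lexicographically. Restricting to the overlap band
matters: scoring whole tiles lets coincidental alignments of non-shared
spots win when tiles are small. Tile origins minimize
`Σ_pairs |X_{T2} − X_{T1} − Δ|²` (Δ = measured offset of T2 relative to
T1); the system is under-determined up to a global translation, fixed by
pinning tile 0 at the origin. Duplicate spots in overlaps are resolved by
keeping each spot only on the tile whose centre it is nearest (ties keep).

## Fine registration

Each (tile, round, channel) image is mapped from the anchor frame by an
affine `y = xM + b`. The initial shift per (tile, round) is found by the
same exp(−D²/8) search (±30 px) against the channel-pooled spot cloud —
pooling is a robustness/runtime choice: per-channel clouds are ~1/7 the
density, and channel-specific chromatic terms are sub-pixel at tile scale.
ICP then alternates nearest-neighbour matching (matches > 3 px discarded)
with a joint least-squares affine refit per channel, stopping when the
match set repeats or after 50 iterations; fewer than 3 matches raises an
error (the pipeline falls back to the shift-only transform and counts the
event). Intensities are read at the nearest pixel — detection and ICP
operate on integer pixels, and no interpolation convention is published.

## Intensity normalization

All filtered images are divided by one global factor, the median detected
anchor-spot peak, before colour extraction and decomposition. This puts a
typical spot at intensity ≈ 1 so the absolute constants of the pursuit
gate (below) are meaningful, while leaving all cross-channel and
cross-round ratios — the quantities cross-talk and ε estimation rely on —
untouched.

## Cross-talk

Well-isolated spots (mean anchor intensity over a 4–14 px annulus below
20% of the median spot peak; the original threshold value is unpublished)
contribute one channel vector per round. Scaled k-means minimizes
`Σ_{s,r} min_{d,λ} |V_{s,r} − λ c_d|²` with `λ = max(0, V·c_d)`
(fluorescence is non-negative) and unit-norm columns (the model is scale
degenerate between λ and c). Assignment/update alternation starts from
argmax-channel group means — dyes are channel-dominant by design, so this
starts each ray in its basin — stops when assignments repeat, and re-seeds
empty clusters from the worst-fit vector; the objective is non-increasing
by construction. Clusters carry no dye labels, so columns are permuted to
maximize the matrix diagonal (linear assignment), identifying dye `d` with
its dominant channel `d`. A single matrix serves all rounds (cross-talk is
stable within an experiment for hybridization chemistry).

## Gene calling

Gene codes concatenate `ε_{g,r} c_{d_{g,r}}` over rounds and are
L2-normalized; background codes are flat across rounds within one channel
(`1/√7` entries), modelling autofluorescence that affects all rounds
equally. Orthogonal matching pursuit keeps the background codes always
active; at each step every candidate gene's decrease of the residual L2
norm under a joint refit of all active coefficients is evaluated, and the
best gene is added iff its decrease exceeds
`0.0612 × clip(second-largest |v_p| component, 0.01, 3.0)`, up to 6 genes
per pixel. "Decrease" is of the norm (not squared norm) under joint refit,
and the clamp applies to the second-largest component before the multiply
— both readings are configurable. The dense decomposition is a vectorized
implementation verified pixel-for-pixel against the reference single-pixel
routine.

Nearly every pixel passes this gate (its floor is far below noise-driven
decreases), as intended: rejection happens at the *call* stage. A call is
an 8-neighbourhood local maximum of a gene's weight image with weight
above a threshold (default 0.75 on the normalized scale) and at least 6
positive-weight pixels within radius 2. On simulated data, noise-driven
weights plateau below ~0.7 while true spots score 1–6, and the
neighbourhood-support rule removes single-pixel flickers. Both are
configurable; the original pipeline's final criterion lives only in its
source code, so ours is a documented replacement. Calls in overlap strips
are deduplicated by the same nearest-tile-centre rule as spots.

Aligned per-pixel vectors are built by nearest-neighbour affine resampling
into the anchor frame. Reads falling outside a round's image are
zero-filled for the dense decomposition: a spot near an outer mosaic edge
that loses a minority of rounds can still be decoded, since codes differ
in ≥ 5 of 7 rounds. (Per-spot colour extraction, used for cross-talk,
instead falls back to a neighbouring tile's transform and otherwise flags
the read invalid and excludes the spot.)

## Efficiency (ε) estimation

One pursuit pass runs with all ε = 1 and a stringent weight threshold
(2× the call threshold). A candidate detection is kept as *unambiguous*
only if its pixel vector lies along the gene's dye signature in every
round, allowing a free per-round scale (that scale is exactly what is
being estimated): the off-signature residual fraction must fall below an
adaptive cutoff, twice the median fraction over all candidates, floored at
0.05. Clean data therefore rejects any pixel contaminated by an
overlapping spot of another gene, while noisy data — where every genuine
detection carries an off-signature noise floor — keeps the bulk. Then
`ε_{g,r} = v̄_{g,r} · c_{d_{g,r}}` (the least-squares slope; signatures are
unit norm) from the mean vector of surviving detections; genes with no
detections keep ε = 1 and non-positive estimates are floored at 0.01.
ε is identifiable only up to a per-gene scale (it trades off against
amplitude, and codes are re-normalized), so recovery is assessed on
per-gene mean-normalized profiles.

## The simulator

`SimulationConfig` defaults define the study condition used throughout the
tests: a 2×2 grid of 256² tiles (2048² supported) with 10% overlap and
±3 px stage jitter on tile origins; a 49-gene panel over 7 rounds × 7
dyes; Poisson(150) spots per tile, uniform positions, isotropic Gaussian
PSF (σ = 1.5 px), lognormal amplitudes (median 1000, σ = 0.25); planted
channel-dominant cross-talk (adjacent-channel bleed ~0.15); planted ε
log-uniform in [0.5, 2]; smooth background fields (Gaussian-filtered
noise, 30 px scale, amplitude 300) constant across rounds per channel —
exactly the structure the background codes assume, so their subtraction is
testable; Gaussian read noise σ = 100 (spot SNR ≈ 10); per-(tile, round)
integer shifts from a clipped normal (σ = 6 px, support ±20 px, the stage
repositioning model) plus subpixel U(−0.5, 0.5); per-channel chromatic
rotations ≤ 1° and isotropic scale jitter ≤ 0.5% about the tile centre.
Images are clipped non-negative; one seed drives everything and identical
configs are bit-identical.

What the simulator does **not** emulate: optical aberrations beyond
affine, photobleaching kinetics, textured tissue autofluorescence, z-depth
effects (images are 2D), and RCP size variability. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under the stated image model, not performance on real tissue.

Scoring matches calls to planted RCPs greedily, closest pair first, within
2 px, each side used once — simple, deterministic and adequate at the
tested densities (optimal bipartite matching changes nothing there). An
empty call table scores precision 1 by convention.

## Problem sizes and runtimes

The end-to-end test condition (4 tiles of 256², ~600 planted RCPs)
decodes in about a minute on one CPU; the full test suite and the
acceptance script each run in a few minutes. Tile size, grid and density
scale up transparently; memory stays bounded by a handful of tiles because
no stitched mega-image is ever materialized.

## Known limitations

* The detection threshold, isolation threshold, call criterion and k-means
  initialization are documented conventions where the original values are
  unpublished; absolute numbers (e.g. call counts) therefore depend on
  these defaults even though the algorithms match the published
  descriptions.
* ICP needs ≥ 3 well-spread matches per (tile, round, channel); very
  sparse channels fall back to shift-only alignment.
* Cross-tile reads reuse the neighbouring tile's transforms rather than
  re-running a dedicated cross-tile registration.
* The stitch assumes a connected tile grid; disconnected mosaics fail
  loudly rather than being solved per component.
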