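"""End-to-end orchestration: filter -> detect -> stitch -> fine-register ->
cross-talk -> epsilon -> OMP -> calls.

Processing is strictly per tile — no stitched mega-image is ever built; the
stitch only solves tile *origins* so that spot and call coordinates can be
reported in one global frame.  Every stage persists its result (CSV/JSON)
into the output directory and is resumed from disk when re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from . import __version__
from .codebook import Codebook, read_codebook_csv, write_codebook_csv
from .crosstalk import (
    CrosstalkMatrix,
    match_columns_to_dyes,
    scaled_kmeans,
    select_isolated_spots,
)
from .genecall import (
    EpsilonTable,
    build_gene_codes,
    call_genes,
    estimate_epsilon_from_stack,
    gene_weight_maps,
)
from .imgproc import (
    SpotCloud,
    detect_spots,
    difference_of_hannings,
    filter_image,
    mad_threshold,
)
from .registration import (
    AffineTransform,
    RegistrationError,
    TileLayout,
    TileOrigins,
    deduplicate_spots,
    extract_spot_colors,
    icp_affine,
    pair_shift,
    solve_tile_origins,
    tile_center,
)

logger = logging.getLogger("combfish")

__all__ = [
    "PipelineConfig",
    "TileImageSet",
    "read_tileset",
    "write_tileset",
    "write_calls",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; defaults are the published values where one
    exists (filter radii, exp(-D^2/8) score, 3 px ICP cutoff, 4-14 px
    annulus, OMP constants) and documented conventions elsewhere."""

    pixel_size_um: float = 0.1625
    hanning_small_um: float = 0.5
    hanning_large_um: float = 1.0
    tophat_radius_um: float = 8.0
    detect_k_mad: float = 6.0
    stitch_search_radius: int = 50
    round_search_radius: int = 30
    icp_cutoff_px: float = 3.0
    icp_max_iter: int = 50
    annulus_inner_px: float = 4.0
    annulus_outer_px: float = 14.0
    annulus_threshold_fraction: float = 0.2
    omp_alpha: float = 0.0612
    omp_clamp: tuple[float, float] = (0.01, 3.0)
    max_genes_per_pixel: int = 6
    min_weight: float = 0.75
    min_neighbourhood: int = 6
    epsilon_stringency: float = 2.0  # stringent threshold = this x min_weight


class TileImageSet:
    """Accessor for the raw images I_{R,C,T} plus layout metadata.

    ``get(round, channel, tile)`` returns one 2D image; the anchor round
    index equals ``n_rounds`` (combinatorial rounds are 0..n_rounds-1).
    """

    def __init__(
        self,
        getter,
        layout: TileLayout,
        n_rounds: int,
        n_channels: int,
        anchor_channel: int = 0,
        pixel_size_um: float = 0.1625,
    ):
        self._getter = getter
        self.layout = layout
        self.n_rounds = n_rounds
        self.n_channels = n_channels
        self.anchor_channel = anchor_channel
        self.pixel_size_um = pixel_size_um

    @property
    def n_tiles(self) -> int:
        return self.layout.n_tiles

    @property
    def anchor_round(self) -> int:
        return self.n_rounds

    def get(self, round: int, channel: int, tile: int) -> np.ndarray:
        return np.asarray(self._getter(round, channel, tile), dtype=float)

    @classmethod
    def from_simulation(cls, experiment) -> "TileImageSet":
        cfg = experiment.config
        return cls(
            getter=experiment.get,
            layout=experiment.layout,
            n_rounds=cfg.n_rounds,
            n_channels=cfg.n_channels,
            anchor_channel=cfg.anchor_channel,
        )


def write_tileset(experiment, directory: str | Path) -> Path:
    """Persist a simulated experiment in the on-disk layout the pipeline
    reads: one TIFF per (round, channel, tile) plus a YAML manifest,
    the codebook and the ground-truth/planted-parameter CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = experiment.config
    for (r, c, t), img in experiment.images.items():
        tifffile.imwrite(directory / f"r{r}_c{c}_t{t}.tif", img.astype(np.float32))
    manifest = {
        "template": "r{round}_c{channel}_t{tile}.tif",
        "n_rounds": cfg.n_rounds,
        "n_channels": cfg.n_channels,
        "anchor_channel": cfg.anchor_channel,
        "tile_shape": list(cfg.tile_shape),
        "overlap_fraction": cfg.overlap_fraction,
        "pixel_size_um": 0.1625,
        "grid_positions": experiment.layout.grid_positions.tolist(),
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    experiment.truth.to_csv(directory / "truth.csv", index=False)
    write_codebook_csv(experiment.codebook, directory / "codebook.csv")
    pd.DataFrame(experiment.true_crosstalk).to_csv(
        directory / "planted_crosstalk.csv", index=False
    )
    pd.DataFrame(experiment.true_epsilon).to_csv(
        directory / "planted_epsilon.csv", index=False
    )
    return directory


def read_tileset(directory: str | Path) -> TileImageSet:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    grid = np.asarray(manifest["grid_positions"], dtype=int)
    if len(grid) == 0:
        raise ValueError("manifest lists zero tiles")
    layout = TileLayout(
        grid_positions=grid,
        tile_shape=tuple(manifest["tile_shape"]),
        overlap_fraction=float(manifest["overlap_fraction"]),
    )
    template = manifest["template"]
    shape = tuple(manifest["tile_shape"])

    def getter(r: int, c: int, t: int) -> np.ndarray:
        path = directory / template.format(round=r, channel=c, tile=t)
        if not path.exists():
            raise FileNotFoundError(f"missing tile image {path}")
        img = tifffile.imread(path)
        if img.shape != shape:
            raise ValueError(f"{path}: shape {img.shape} != manifest {shape}")
        return img

    return TileImageSet(
        getter=getter,
        layout=layout,
        n_rounds=int(manifest["n_rounds"]),
        n_channels=int(manifest["n_channels"]),
        anchor_channel=int(manifest["anchor_channel"]),
        pixel_size_um=float(manifest["pixel_size_um"]),
    )


class _FilteredCache:
    """Difference-of-Hannings filtered (and globally normalized) images,
    cached per tile so memory stays bounded by a handful of tiles."""

    def __init__(self, images: TileImageSet, config: PipelineConfig, max_entries: int = 128):
        self.images = images
        self.kernel = difference_of_hannings(
            config.pixel_size_um, config.hanning_small_um, config.hanning_large_um
        )
        self.scale = 1.0
        self._cache: dict[tuple[int, int, int], np.ndarray] = {}
        self._max = max_entries

    def get(self, round: int, channel: int, tile: int) -> np.ndarray:
        key = (round, channel, tile)
        if key not in self._cache:
            if len(self._cache) >= self._max:
                self._cache.pop(next(iter(self._cache)))
            filtered = filter_image(self.images.get(round, channel, tile), self.kernel)
            self._cache[key] = filtered.astype(np.float32)
        return self._cache[key] * self.scale


def write_calls(calls: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    cols = ["call_id", "gene_name", "global_row", "global_col", "weight", "tile"]
    out = calls.copy()
    if "call_id" not in out.columns:
        out.insert(0, "call_id", np.arange(len(out)))
    out[cols].to_csv(path, index=False, float_format="%.4f")
    if provenance is not None:
        path.with_suffix(".provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True)
        )
    return path


def _transforms_to_json(transforms: dict[tuple[int, int, int], AffineTransform]) -> str:
    payload = {
        f"{t},{r},{c}": {
            "matrix": tf.matrix.tolist(),
            "offset": tf.offset.tolist(),
            "n_matched": tf.n_matched,
            "mean_residual": tf.mean_residual,
        }
        for (t, r, c), tf in transforms.items()
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def _transforms_from_json(text: str) -> dict[tuple[int, int, int], AffineTransform]:
    out = {}
    for key, val in json.loads(text).items():
        t, r, c = (int(x) for x in key.split(","))
        out[(t, r, c)] = AffineTransform(
            matrix=np.asarray(val["matrix"]),
            offset=np.asarray(val["offset"]),
            n_matched=val["n_matched"],
            mean_residual=val["mean_residual"],
        )
    return out


def _aligned_stack(
    filtered: _FilteredCache,
    transforms: dict[tuple[int, int, int], AffineTransform],
    tile: int,
    n_rounds: int,
    n_channels: int,
    tile_shape: tuple[int, int],
) -> np.ndarray:
    """Resample every (round, channel) image of one tile into the reference
    frame with nearest-neighbour affine warping.  Reads that land outside
    the image are zero-filled; a spot near an outer edge that loses a
    minority of rounds can still be decoded (codes differ in >= 5 rounds)."""
    stack = np.zeros((*tile_shape, n_rounds, n_channels), dtype=np.float32)
    for r in range(n_rounds):
        for c in range(n_channels):
            tf = transforms[(tile, r, c)]
            stack[:, :, r, c] = ndimage.affine_transform(
                filtered.get(r, c, tile),
                matrix=tf.matrix.T,
                offset=tf.offset,
                order=0,
                mode="constant",
                cval=0.0,
                prefilter=False,
            )
    return stack


def run_pipeline(
    images: TileImageSet,
    codebook: Codebook,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path = "combfish_out",
) -> dict:
    """Execute all stages; returns a dict of results and persists each
    intermediate under ``out_dir`` (stages resume from persisted files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = images.layout
    n_tiles = layout.n_tiles
    n_rounds, n_channels = images.n_rounds, images.n_channels
    filtered = _FilteredCache(images, config)

    # -- reference spot detection -----------------------------------------
    ref_spots: dict[int, SpotCloud] = {}
    for t in range(n_tiles):
        path = out / f"ref_spots_t{t}.csv"
        ref = filtered.get(images.anchor_round, images.anchor_channel, t)
        if path.exists():
            df = pd.read_csv(path)
            ref_spots[t] = SpotCloud(
                coordinates=df[["row", "col"]].to_numpy(int),
                intensities=df["intensity"].to_numpy(),
                tile=t,
            )
        else:
            thr = mad_threshold(ref, config.detect_k_mad)
            cloud = detect_spots(ref, thr)
            cloud.tile = t
            ref_spots[t] = cloud
            pd.DataFrame(
                {
                    "row": cloud.coordinates[:, 0],
                    "col": cloud.coordinates[:, 1],
                    "intensity": cloud.intensities,
                }
            ).to_csv(path, index=False)
        logger.info("tile %d: %d reference spots", t, len(ref_spots[t]))

    # global intensity normalization: median reference spot peak -> 1
    peaks = np.concatenate([ref_spots[t].intensities for t in range(n_tiles)])
    if len(peaks) == 0:
        raise RuntimeError("no reference spots detected in any tile")
    filtered.scale = 1.0 / float(np.median(peaks))

    # -- stitch ------------------------------------------------------------
    origins_path = out / "tile_origins.csv"
    if origins_path.exists():
        origins = TileOrigins(
            origins=pd.read_csv(origins_path)[["row", "col"]].to_numpy(float)
        )
    else:
        shifts = []
        margin = 10.0  # tolerance on the nominal overlap band, px
        shape_arr = np.asarray(layout.tile_shape, float)
        for t1, t2 in layout.neighbor_pairs():
            expected = layout.expected_shift(t1, t2)
            # register only the overlapping regions: keep T2 spots whose
            # nominal position on T1 is inside T1 (and vice versa)
            c2 = ref_spots[t2].coordinates
            in_t1 = ((c2 + expected >= -margin) & (c2 + expected < shape_arr + margin)).all(axis=1)
            c1 = ref_spots[t1].coordinates
            in_t2 = ((c1 - expected >= -margin) & (c1 - expected < shape_arr + margin)).all(axis=1)
            # a point at local p on T2 sits at p + (X_T2 - X_T1) on T1, so
            # matching T2's cloud onto T1's measures Delta_{T1,T2} directly
            ps = pair_shift(
                c2[in_t1],
                c1[in_t2],
                expected=expected,
                search_radius=config.stitch_search_radius,
            )
            ps.tiles = (t1, t2)
            shifts.append(ps)
            logger.info(
                "pair (%d,%d): shift %s score %.1f", t1, t2, ps.shift, ps.score
            )
        origins = solve_tile_origins(shifts, layout)
        pd.DataFrame(origins.origins, columns=["row", "col"]).to_csv(
            origins_path, index=False
        )

    global_pos, home_tiles, _ = deduplicate_spots(ref_spots, origins, layout)
    logger.info("global reference spots after dedup: %d", len(global_pos))

    # -- fine registration -------------------------------------------------
    tf_path = out / "transforms.json"
    if tf_path.exists():
        transforms = _transforms_from_json(tf_path.read_text())
    else:
        transforms = {}
        n_fallback = 0
        for t in range(n_tiles):
            ref_cloud = ref_spots[t]
            for r in range(n_rounds):
                clouds = []
                for c in range(n_channels):
                    img = filtered.get(r, c, t)
                    thr = mad_threshold(img, config.detect_k_mad)
                    clouds.append(detect_spots(img, thr))
                pooled = np.vstack(
                    [cl.coordinates for cl in clouds if len(cl)]
                    or [np.empty((0, 2), int)]
                )
                if len(pooled) == 0 or len(ref_cloud) == 0:
                    raise RegistrationError(f"no spots for tile {t} round {r}")
                init = pair_shift(
                    ref_cloud,
                    pooled,
                    expected=np.zeros(2),
                    search_radius=config.round_search_radius,
                ).shift
                for c in range(n_channels):
                    try:
                        tf = icp_affine(
                            ref_cloud,
                            clouds[c],
                            init_shift=init,
                            cutoff_px=config.icp_cutoff_px,
                            max_iter=config.icp_max_iter,
                        )
                    except RegistrationError:
                        tf = AffineTransform.from_shift(init)
                        n_fallback += 1
                    transforms[(t, r, c)] = tf
        logger.info(
            "fine registration done (%d shift-only fallbacks of %d transforms)",
            n_fallback,
            len(transforms),
        )
        tf_path.write_text(_transforms_to_json(transforms))

    # -- cross-talk --------------------------------------------------------
    crosstalk_path = out / "crosstalk.csv"
    if crosstalk_path.exists():
        crosstalk = CrosstalkMatrix(pd.read_csv(crosstalk_path).to_numpy(float))
    else:
        vectors = []
        n_isolated = 0
        for t in range(n_tiles):
            ref = filtered.get(images.anchor_round, images.anchor_channel, t)
            isolated = select_isolated_spots(
                ref,
                ref_spots[t],
                r_inner_px=config.annulus_inner_px,
                r_outer_px=config.annulus_outer_px,
                threshold_fraction=config.annulus_threshold_fraction,
            )
            n_isolated += len(isolated)
            if len(isolated) == 0:
                continue
            iso_global = isolated.coordinates.astype(float) + origins[t]
            colors = extract_spot_colors(
                iso_global,
                np.full(len(isolated), t),
                transforms,
                filtered,
                origins,
                layout,
                n_rounds,
                n_channels,
            )
            ok = colors.valid.all(axis=2)  # (spot, round): all channels read
            for s in range(len(isolated)):
                for r in range(n_rounds):
                    if ok[s, r]:
                        vectors.append(colors.colors[s, r])
        logger.info("isolated spots: %d -> %d colour vectors", n_isolated, len(vectors))
        raw = scaled_kmeans(np.asarray(vectors), n_dyes=n_channels)
        crosstalk = match_columns_to_dyes(raw)
        pd.DataFrame(crosstalk.columns).to_csv(crosstalk_path, index=False)

    # -- epsilon -----------------------------------------------------------
    stacks = {
        t: _aligned_stack(filtered, transforms, t, n_rounds, n_channels, layout.tile_shape)
        for t in range(n_tiles)
    }
    eps_path = out / "epsilon.csv"
    if eps_path.exists():
        eps_df = pd.read_csv(eps_path)
        epsilon = EpsilonTable(
            values=eps_df[[f"r{r}" for r in range(n_rounds)]].to_numpy(float)
        )
    else:
        epsilon = estimate_epsilon_from_stack(
            stacks,
            codebook,
            crosstalk,
            stringent_weight=config.epsilon_stringency * config.min_weight,
        )
        epsilon.to_frame(codebook.gene_names).to_csv(eps_path, index=False)
    logger.info(
        "epsilon estimated for %d/%d genes",
        int((epsilon.values != 1.0).any(axis=1).sum()),
        codebook.n_genes,
    )

    # -- OMP + calls -------------------------------------------------------
    calls_path = out / "calls.csv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path)
    else:
        codes = build_gene_codes(codebook, crosstalk, epsilon)
        per_tile = []
        for t in range(n_tiles):
            maps = gene_weight_maps(
                stacks[t],
                codes,
                max_genes=config.max_genes_per_pixel,
                alpha=config.omp_alpha,
                clamp=config.omp_clamp,
            )
            tile_calls = call_genes(
                maps,
                codebook.gene_names,
                min_weight=config.min_weight,
                min_neighbourhood=config.min_neighbourhood,
                origin=origins[t],
                tile=t,
            )
            logger.info("tile %d: %d calls", t, len(tile_calls))
            per_tile.append(tile_calls)
        calls = pd.concat(per_tile, ignore_index=True)
        # overlap strips are decoded on both tiles; keep the owner's call
        if len(calls):
            centers = np.array(
                [tile_center(layout, origins, t) for t in range(n_tiles)]
            )
            pos = calls[["global_row", "global_col"]].to_numpy(float)
            d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            own = d2[np.arange(len(calls)), calls["tile"].to_numpy(int)]
            calls = calls[own <= d2.min(axis=1) + 1e-9].reset_index(drop=True)
        calls.insert(0, "call_id", np.arange(len(calls)))
        provenance = {
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "version": __version__,
            "n_calls": int(len(calls)),
        }
        write_calls(calls, calls_path, provenance)
    logger.info("total calls: %d", len(calls))

    return {
        "ref_spots": ref_spots,
        "origins": origins,
        "transforms": transforms,
        "crosstalk": crosstalk,
        "epsilon": epsilon,
        "calls": calls,
        "out_dir": out,
    }
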