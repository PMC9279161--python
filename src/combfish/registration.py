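"""Tile stitching and fine per-round/channel registration.

The anchor (reference) round labels every RCP, so its spot clouds drive all
geometry.  Stitching proceeds in two steps: (i) for every pair of
overlapping tiles an integer offset is found by exhaustive search,
maximizing the soft match score ``sum_s exp(-D_s**2 / 8)`` where ``D_s`` is
the distance from each spot on the first tile to its nearest neighbour on
the second; (ii) tile origins ``X_T`` are obtained by least squares on the
overdetermined system ``X_T1 - X_T2 = Delta_T1T2``, gauge-fixed by pinning
the first tile at the origin.

Within a tile, each (round, channel) image is aligned to the reference
image by an affine transform fitted with iterative closest point (ICP),
discarding matches beyond a 3 px cutoff.  Finally a colour vector is read
for every reference spot from each aligned filtered image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .imgproc import SpotCloud

__all__ = [
    "TileLayout",
    "PairShift",
    "TileOrigins",
    "AffineTransform",
    "SpotColorMatrix",
    "RegistrationError",
    "pair_shift",
    "solve_tile_origins",
    "deduplicate_spots",
    "icp_affine",
    "extract_spot_colors",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TileLayout:
    """Square tiling metadata: grid index per tile and nominal geometry."""

    grid_positions: np.ndarray  # (n_tiles, 2) int: (grid_row, grid_col)
    tile_shape: tuple[int, int]
    overlap_fraction: float = 0.10

    @property
    def n_tiles(self) -> int:
        return len(self.grid_positions)

    def nominal_origin(self, tile: int) -> np.ndarray:
        """Expected global origin from the stage grid (pixels)."""
        step = (1.0 - self.overlap_fraction) * np.asarray(self.tile_shape, float)
        return self.grid_positions[tile] * step

    def neighbor_pairs(self) -> list[tuple[int, int]]:
        """Pairs of tiles adjacent on the grid (up to four neighbours each)."""
        index = {tuple(p): t for t, p in enumerate(self.grid_positions.tolist())}
        pairs = []
        for t, (gr, gc) in enumerate(self.grid_positions.tolist()):
            for dr, dc in ((0, 1), (1, 0)):
                other = index.get((gr + dr, gc + dc))
                if other is not None:
                    pairs.append((t, other))
        return pairs

    def expected_shift(self, t1: int, t2: int) -> np.ndarray:
        """Nominal stage offset of tile t2 relative to tile t1
        (``X_t2 - X_t1``), as the position sensor would report it."""
        return self.nominal_origin(t2) - self.nominal_origin(t1)


@dataclass
class PairShift:
    tiles: tuple[int, int]
    shift: np.ndarray  # local_t1 + shift ~ local_t2
    score: float
    n_matches: int


@dataclass
class TileOrigins:
    origins: np.ndarray  # (n_tiles, 2) float, first tile pinned at (0, 0)

    def __getitem__(self, tile: int) -> np.ndarray:
        return self.origins[tile]


@dataclass
class AffineTransform:
    """Maps reference-image coordinates to a (round, channel) image.

    ``y = x @ matrix + offset`` for row vectors ``x = (row, col)``.
    """

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    n_matched: int = 0
    mean_residual: float = float("nan")
    residual_path: list | None = None  # mean matched residual per ICP iteration

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.atleast_2d(coords) @ self.matrix + self.offset

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(matrix=np.eye(2), offset=np.zeros(2))

    @classmethod
    def from_shift(cls, shift: np.ndarray) -> "AffineTransform":
        return cls(matrix=np.eye(2), offset=np.asarray(shift, float))


@dataclass
class SpotColorMatrix:
    """Per-spot colour readout: (n_spots, n_rounds, n_channels) intensities
    plus a validity flag per (spot, round, channel) read."""

    global_positions: np.ndarray  # (n_spots, 2)
    colors: np.ndarray  # (n_spots, n_rounds, n_channels)
    valid: np.ndarray  # same shape, bool
    tiles: np.ndarray  # (n_spots,) home tile

    @property
    def fully_valid(self) -> np.ndarray:
        return self.valid.all(axis=(1, 2))


def pair_shift(
    spots_a: SpotCloud | np.ndarray,
    spots_b: SpotCloud | np.ndarray,
    expected: np.ndarray,
    search_radius: int = 50,
) -> PairShift:
    """Exhaustive integer-shift search maximizing ``sum exp(-D**2/8)``.

    ``D`` is the distance from each shifted ``spots_a`` point to the nearest
    ``spots_b`` point.  Ties are broken toward the expected shift, then
    lexicographically.
    """
    pts_a = spots_a.coordinates if isinstance(spots_a, SpotCloud) else np.asarray(spots_a)
    pts_b = spots_b.coordinates if isinstance(spots_b, SpotCloud) else np.asarray(spots_b)
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise RegistrationError("empty spot cloud in overlap region")
    pts_a = np.asarray(pts_a, dtype=float)
    expected = np.asarray(expected, dtype=float)
    base = np.round(expected).astype(int)
    tree_b = cKDTree(np.asarray(pts_b, dtype=float))

    offsets = np.arange(-search_radius, search_radius + 1)
    dr, dc = np.meshgrid(offsets, offsets, indexing="ij")
    shifts = base + np.column_stack([dr.ravel(), dc.ravel()])  # (k, 2)
    # one batched nearest-neighbour query over all shifts at once
    queries = (pts_a[None, :, :] + shifts[:, None, :]).reshape(-1, 2)
    d, _ = tree_b.query(queries)
    scores = np.exp(-(d.reshape(len(shifts), -1) ** 2) / 8.0).sum(axis=1)
    # ties broken toward the expected shift, then lexicographically
    dist_to_expected = np.hypot(*(shifts - expected).T)
    order = np.lexsort((shifts[:, 1], shifts[:, 0], dist_to_expected, -scores))
    best = order[0]
    shift, score = shifts[best].astype(float), float(scores[best])
    d, _ = tree_b.query(pts_a + shift)
    return PairShift(
        tiles=(getattr(spots_a, "tile", None), getattr(spots_b, "tile", None)),
        shift=shift.astype(float),
        score=score,
        n_matches=int((d <= 2.0).sum()),
    )


def solve_tile_origins(
    pair_shifts: list[PairShift], layout: TileLayout
) -> TileOrigins:
    """Least-squares stitch of the pairwise offsets.

    ``Delta_{T1,T2}`` is the measured offset of tile T2's origin relative to
    T1's, so each pair contributes ``|X_T2 - X_T1 - Delta|**2`` to the loss.
    Tile 0 is pinned at (0, 0) to fix the translational gauge; the rest is
    the least-squares solution of the overdetermined linear system.
    """
    n = layout.n_tiles
    adjacency = np.zeros((n, n))
    for ps in pair_shifts:
        t1, t2 = ps.tiles
        adjacency[t1, t2] = adjacency[t2, t1] = 1
    n_comp, comp = connected_components(adjacency, directed=False)
    if n_comp > 1:
        groups = [list(np.nonzero(comp == k)[0]) for k in range(n_comp)]
        raise RegistrationError(f"tile graph disconnected: components {groups}")

    # unknowns: origins of tiles 1..n-1 (tile 0 pinned at (0, 0))
    rows = []
    rhs = []
    for ps in pair_shifts:
        t1, t2 = ps.tiles
        row = np.zeros(n - 1)
        if t2 > 0:
            row[t2 - 1] = 1.0
        if t1 > 0:
            row[t1 - 1] = -1.0
        rows.append(row)
        rhs.append(ps.shift)
    A = np.array(rows)
    b = np.array(rhs)  # (n_pairs, 2) -- solve both axes at once
    solution, *_ = np.linalg.lstsq(A, b, rcond=None)
    origins = np.vstack([np.zeros(2), solution])
    return TileOrigins(origins=origins)


def tile_center(layout: TileLayout, origins: TileOrigins, tile: int) -> np.ndarray:
    return origins[tile] + (np.asarray(layout.tile_shape, float) - 1.0) / 2.0


def deduplicate_spots(
    spots_per_tile: dict[int, SpotCloud],
    origins: TileOrigins,
    layout: TileLayout,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge per-tile clouds into global coordinates, dropping duplicates.

    A spot is kept iff it is at least as close to its own tile's centre as
    to any other tile's centre, so each physical RCP in an overlap strip
    survives exactly once (on the tile that owns it).

    Returns (global_positions, home_tiles, local_positions).
    """
    centers = np.array(
        [tile_center(layout, origins, t) for t in range(layout.n_tiles)]
    )
    out_pos, out_tile, out_local = [], [], []
    for t, cloud in spots_per_tile.items():
        if len(cloud) == 0:
            continue
        global_pos = cloud.coordinates.astype(float) + origins[t]
        d2 = ((global_pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        keep = d2[:, t] <= d2.min(axis=1) + 1e-9
        out_pos.append(global_pos[keep])
        out_tile.append(np.full(keep.sum(), t, dtype=int))
        out_local.append(cloud.coordinates[keep].astype(float))
    if not out_pos:
        return np.empty((0, 2)), np.empty(0, dtype=int), np.empty((0, 2))
    return np.vstack(out_pos), np.concatenate(out_tile), np.vstack(out_local)


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine src -> dst for matched point rows."""
    n = len(src)
    design = np.column_stack([src, np.ones(n)])
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    return AffineTransform(matrix=params[:2], offset=params[2])


def icp_affine(
    ref_spots: SpotCloud | np.ndarray,
    target_spots: SpotCloud | np.ndarray,
    init_shift: np.ndarray,
    cutoff_px: float = 3.0,
    max_iter: int = 50,
) -> AffineTransform:
    """Iterative closest point fit of an affine map reference -> target.

    Alternates nearest-neighbour matching (matches beyond ``cutoff_px``
    discarded) with a joint least-squares affine refit, starting from a pure
    shift.  Stops when the match assignment repeats or at ``max_iter``.
    """
    ref = np.asarray(
        ref_spots.coordinates if isinstance(ref_spots, SpotCloud) else ref_spots,
        dtype=float,
    )
    target = np.asarray(
        target_spots.coordinates
        if isinstance(target_spots, SpotCloud)
        else target_spots,
        dtype=float,
    )
    if len(target) == 0:
        raise RegistrationError("no target spots for ICP")
    tree = cKDTree(target)
    transform = AffineTransform.from_shift(init_shift)
    prev_assignment = None
    path: list[float] = []
    for _ in range(max_iter):
        mapped = transform.apply(ref)
        dist, idx = tree.query(mapped)
        matched = dist <= cutoff_px
        if matched.sum() < 3:
            raise RegistrationError(
                f"ICP collapsed to {int(matched.sum())} matches (<3)"
            )
        path.append(float(dist[matched].mean()))
        assignment = (tuple(np.nonzero(matched)[0]), tuple(idx[matched]))
        transform = _fit_affine(ref[matched], target[idx[matched]])
        if assignment == prev_assignment:
            break
        prev_assignment = assignment
    mapped = transform.apply(ref)
    dist, idx = tree.query(mapped)
    matched = dist <= cutoff_px
    transform.n_matched = int(matched.sum())
    transform.mean_residual = float(dist[matched].mean()) if matched.any() else float("nan")
    transform.residual_path = path
    return transform


def extract_spot_colors(
    global_positions: np.ndarray,
    home_tiles: np.ndarray,
    transforms: dict[tuple[int, int, int], AffineTransform],
    images: "object",
    origins: TileOrigins,
    layout: TileLayout,
    n_rounds: int,
    n_channels: int,
) -> SpotColorMatrix:
    """Read each spot's filtered intensity in every (round, channel).

    The spot's reference-tile coordinate is pushed through that tile's
    (round, channel) affine and the image is read at the nearest pixel.
    Coordinates landing outside the tile fall back to a neighbouring tile's
    transform when one covers them; otherwise the read is flagged invalid.

    ``images`` must support ``images.get(round, channel, tile) -> 2D array``
    (filtered intensities).
    """
    n_spots = len(global_positions)
    colors = np.zeros((n_spots, n_rounds, n_channels))
    valid = np.zeros((n_spots, n_rounds, n_channels), dtype=bool)
    shape = np.asarray(layout.tile_shape)
    neighbor_map: dict[int, list[int]] = {t: [] for t in range(layout.n_tiles)}
    for t1, t2 in layout.neighbor_pairs():
        neighbor_map[t1].append(t2)
        neighbor_map[t2].append(t1)

    # group by home tile so each image is loaded once
    for t in np.unique(home_tiles):
        sel = np.nonzero(home_tiles == t)[0]
        local = global_positions[sel] - origins[int(t)]
        for r in range(n_rounds):
            for c in range(n_channels):
                candidates = [int(t)] + neighbor_map[int(t)]
                remaining = np.arange(len(sel))
                for cand in candidates:
                    if len(remaining) == 0:
                        break
                    key = (cand, r, c)
                    if key not in transforms:
                        if cand == int(t):
                            raise KeyError(f"missing transform for {key}")
                        continue
                    cand_local = global_positions[sel[remaining]] - origins[cand]
                    mapped = transforms[key].apply(cand_local)
                    px = np.round(mapped).astype(int)
                    inside = ((px >= 0) & (px < shape)).all(axis=1)
                    if inside.any():
                        img = images.get(r, c, cand)
                        hit = remaining[inside]
                        colors[sel[hit], r, c] = img[px[inside, 0], px[inside, 1]]
                        valid[sel[hit], r, c] = True
                        remaining = remaining[~inside]
    return SpotColorMatrix(
        global_positions=np.asarray(global_positions, float),
        colors=colors,
        valid=valid,
        tiles=np.asarray(home_tiles, int),
    )
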