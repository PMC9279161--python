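"""Gene calling by orthogonal matching pursuit (OMP) on pixel vectors.

Every aligned pixel carries an ``n_rounds * n_channels`` fluorescence
vector ``v_p`` (49-dimensional in the default scheme).  It is modelled as a
sparse non-negative combination of *gene codes* plus *background codes*:

    v_p  ~=  sum_i alpha_{g_i} a_{g_i}  +  sum_c beta_c a_c^B

A gene code concatenates, over rounds, the cross-talk signature of the dye
the gene shows in that round, scaled by a learned per-gene/round efficiency
``eps_{g,r}``, then L2-normalized.  A background code is flat across rounds
within a single channel, modelling autofluorescence that hits every round
equally.  OMP keeps the background codes always active, and greedily adds
the gene whose inclusion (with a joint least-squares refit of all active
coefficients) most decreases the residual norm, while that decrease exceeds
``alpha * clip(second-largest |v_p| component, clamp)`` — up to 6 genes per
pixel.  Per-gene weight images of the fitted coefficients are then peak-
picked to produce transcript calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .codebook import Codebook
from .crosstalk import CrosstalkMatrix

__all__ = [
    "GeneCodeMatrix",
    "EpsilonTable",
    "PixelDecomposition",
    "build_gene_codes",
    "omp_decompose",
    "omp_batch",
    "gene_weight_maps",
    "estimate_epsilon_from_stack",
    "call_genes",
]

OMP_ALPHA = 0.0612
OMP_CLAMP = (0.01, 3.0)
MAX_GENES_PER_PIXEL = 6


@dataclass
class EpsilonTable:
    """Per-gene, per-round intensity scale factors (bridge-probe efficiency)."""

    values: np.ndarray  # (n_genes, n_rounds), > 0
    n_spots: np.ndarray | None = None  # confident detections per gene
    mean_vectors: np.ndarray | None = None  # (n_genes, n_rounds, n_channels)

    @classmethod
    def ones(cls, n_genes: int, n_rounds: int) -> "EpsilonTable":
        return cls(values=np.ones((n_genes, n_rounds)))

    def to_frame(self, gene_names: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"r{r}" for r in range(self.values.shape[1])]
        )
        df.insert(0, "gene_name", gene_names)
        return df


@dataclass
class GeneCodeMatrix:
    """Unit-norm gene codes and background codes, flattened (round, channel)."""

    gene_codes: np.ndarray  # (n_genes, n_rounds * n_channels)
    background_codes: np.ndarray  # (n_channels, n_rounds * n_channels)
    gene_names: list[str]
    n_rounds: int
    n_channels: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_codes)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"r{r}_c{c}"
            for r in range(self.n_rounds)
            for c in range(self.n_channels)
        ]
        df = pd.DataFrame(self.gene_codes, columns=cols)
        df.insert(0, "gene_name", self.gene_names)
        return df


def build_gene_codes(
    codebook: Codebook,
    crosstalk: CrosstalkMatrix,
    epsilon: EpsilonTable | None = None,
) -> GeneCodeMatrix:
    """Assemble a_g = [eps_{g,0} c_{d_{g,0}}; ...; eps_{g,R-1} c_{d_{g,R-1}}],
    L2-normalized, plus one flat background code per channel."""
    n_rounds = codebook.n_rounds
    n_channels = crosstalk.n_channels
    if epsilon is None:
        epsilon = EpsilonTable.ones(codebook.n_genes, n_rounds)
    if epsilon.values.shape != (codebook.n_genes, n_rounds):
        raise ValueError("epsilon table shape does not match codebook")

    seqs = codebook.dye_sequences()
    codes = np.zeros((codebook.n_genes, n_rounds, n_channels))
    for r in range(n_rounds):
        codes[:, r, :] = epsilon.values[:, r, None] * crosstalk.columns[:, seqs[:, r]].T
    flat = codes.reshape(codebook.n_genes, -1)
    norms = np.linalg.norm(flat, axis=1)
    bad = np.nonzero(norms <= 0)[0]
    if len(bad):
        raise ValueError(
            f"zero-norm gene code for {[codebook.gene_names[i] for i in bad]}"
        )
    flat = flat / norms[:, None]

    bg = np.zeros((n_channels, n_rounds, n_channels))
    for c in range(n_channels):
        bg[c, :, c] = 1.0 / np.sqrt(n_rounds)
    return GeneCodeMatrix(
        gene_codes=flat,
        background_codes=bg.reshape(n_channels, -1),
        gene_names=codebook.gene_names,
        n_rounds=n_rounds,
        n_channels=n_channels,
    )


@dataclass
class PixelDecomposition:
    genes: list[int]
    coefficients: np.ndarray  # alpha per selected gene
    background_coefficients: np.ndarray  # beta per channel
    residual_norms: np.ndarray  # after each stage, starting at background-only
    fitted: np.ndarray


def _threshold_for(v: np.ndarray, alpha: float, clamp: tuple[float, float]) -> float:
    """alpha * (second largest |v| component, clamped to [clamp_lo, clamp_hi])."""
    a = np.abs(v)
    if len(a) < 2:
        return alpha * clamp[0]
    second = np.partition(a, -2)[-2]
    return alpha * float(np.clip(second, *clamp))


def _refit(v: np.ndarray, active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint least squares of v on the active code rows; returns (coef, residual)."""
    coef, *_ = np.linalg.lstsq(active.T, v, rcond=None)
    return coef, v - active.T @ coef


def omp_decompose(
    v_p: np.ndarray,
    codes: GeneCodeMatrix,
    max_genes: int = MAX_GENES_PER_PIXEL,
    alpha: float = OMP_ALPHA,
    clamp: tuple[float, float] = OMP_CLAMP,
) -> PixelDecomposition:
    """Greedy sparse decomposition of one pixel vector.

    The background codes are always in the active set.  At each step every
    candidate gene's decrease of the residual L2 norm (after a joint refit
    of all active coefficients) is evaluated; the best gene joins the set
    iff its decrease beats the pixel's threshold.
    """
    v = np.asarray(v_p, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite pixel vector")
    if v.shape != (codes.gene_codes.shape[1],):
        raise ValueError("pixel vector dimension does not match the codes")

    threshold = _threshold_for(v, alpha, clamp)
    A = codes.gene_codes
    bg = codes.background_codes

    selected: list[int] = []
    active = bg.copy()
    coef, resid = _refit(v, active)
    norms = [float(np.linalg.norm(resid))]

    # orthonormal basis of the active span, grown incrementally
    Q = np.linalg.qr(bg.T)[0]
    for _ in range(max_genes):
        candidates = np.setdiff1d(np.arange(codes.n_genes), selected, assume_unique=False)
        if len(candidates) == 0:
            break
        A_perp = A[candidates].T - Q @ (Q.T @ A[candidates].T)  # (dim, k)
        pn = np.linalg.norm(A_perp, axis=0)
        usable = pn > 1e-12
        if not usable.any():
            break
        u = A_perp[:, usable] / pn[usable]
        proj = resid @ u
        r_norm = norms[-1]
        decreases = r_norm - np.sqrt(np.maximum(r_norm**2 - proj**2, 0.0))
        best = int(np.argmax(decreases))
        if decreases[best] <= threshold:
            break
        g = int(candidates[usable][best])
        selected.append(g)
        # grow the basis and refit everything jointly
        new_dir = u[:, best]
        Q = np.column_stack([Q, new_dir])
        active = np.vstack([bg, A[selected]])
        coef, resid = _refit(v, active)
        norms.append(float(np.linalg.norm(resid)))

    beta = coef[: len(bg)]
    alpha_coef = coef[len(bg):] if selected else np.empty(0)
    fitted = active.T @ coef
    return PixelDecomposition(
        genes=selected,
        coefficients=np.asarray(alpha_coef, dtype=float),
        background_coefficients=np.asarray(beta, dtype=float),
        residual_norms=np.asarray(norms),
        fitted=fitted,
    )


def omp_batch(
    pixel_vectors: np.ndarray,
    codes: GeneCodeMatrix,
    max_genes: int = MAX_GENES_PER_PIXEL,
    alpha: float = OMP_ALPHA,
    clamp: tuple[float, float] = OMP_CLAMP,
) -> np.ndarray:
    """OMP over many pixels at once; returns (n_pixels, n_genes) gene weights.

    Vectorized counterpart of :func:`omp_decompose` (same selection rule,
    same joint refit).  Per-pixel state is the residual (kept orthogonal to
    the active span by deflation) plus the Gram-Schmidt directions of the
    genes selected so far; candidate decreases are evaluated for all pixels
    of a pursuit step in batched matrix products.
    """
    V = np.asarray(pixel_vectors, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite pixel vectors")
    n_pixels, dim = V.shape
    n_genes = codes.n_genes
    weights = np.zeros((n_pixels, n_genes))

    bg = codes.background_codes
    Q0 = np.linalg.qr(bg.T)[0]
    # residual after the always-active background fit
    R = V - (V @ Q0) @ Q0.T
    A_perp = codes.gene_codes.T - Q0 @ (Q0.T @ codes.gene_codes.T)
    pn = np.linalg.norm(A_perp, axis=0)
    usable0 = pn > 1e-12
    U0 = A_perp / np.maximum(pn, 1e-12)  # (dim, n_genes), unit columns

    a = np.abs(V)
    second = np.partition(a, -2, axis=1)[:, -2] if dim >= 2 else a[:, 0]
    thresholds = alpha * np.clip(second, *clamp)

    rn = np.linalg.norm(R, axis=1)
    selected = np.full((n_pixels, max_genes), -1, dtype=int)
    n_sel = np.zeros(n_pixels, dtype=int)
    basis = np.zeros((n_pixels, max_genes, dim))  # Gram-Schmidt gene directions
    active = np.arange(n_pixels)
    # per active pixel: residual/basis projections on every candidate,
    # maintained incrementally across pursuit steps
    P = R @ U0  # residual . u0_g
    S = np.zeros_like(P)  # sum_j (basis_j . u0_g)^2

    for step in range(max_genes):
        if len(active) == 0:
            break
        # candidate norm after orthogonalization against the pixel's own
        # selected directions; the residual projection P is unaffected
        # because the residual is already orthogonal to those directions
        nperp2 = 1.0 - S
        bad = (nperp2 <= 1e-9) | ~usable0[None, :]
        proj2 = np.where(bad, 0.0, P**2 / np.maximum(nperp2, 1e-12))
        if step > 0:
            np.put_along_axis(proj2, selected[active, :step], 0.0, axis=1)
        rna = rn[active]
        dec = rna[:, None] - np.sqrt(np.maximum(rna[:, None] ** 2 - proj2, 0.0))
        dec[bad] = -np.inf
        best = dec.argmax(axis=1)
        accept = dec[np.arange(len(active)), best] > thresholds[active]
        if not accept.any():
            break
        idx = active[accept]
        g = best[accept]
        u = U0[:, g].T.copy()  # (m_acc, dim)
        if step > 0:
            Ba = basis[idx, :step]
            coef = np.einsum("msd,md->ms", Ba, u)
            u -= np.einsum("ms,msd->md", coef, Ba)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pr = np.einsum("md,md->m", R[idx], u)
        R[idx] -= pr[:, None] * u
        rn[idx] = np.sqrt(np.maximum(rn[idx] ** 2 - pr**2, 0.0))
        basis[idx, step] = u
        selected[idx, step] = g
        n_sel[idx] += 1
        active = idx
        row = u @ U0  # new direction . u0_g, drives both updates
        P = P[accept] - pr[:, None] * row
        S = S[accept] + row**2

    # joint least-squares refit of [background; selected genes] per pixel,
    # batched over pixels with the same active-set size
    for kk in range(1, max_genes + 1):
        pix = np.nonzero(n_sel == kk)[0]
        if len(pix) == 0:
            continue
        genes = selected[pix, :kk]
        A = np.concatenate(
            [
                np.broadcast_to(bg, (len(pix), *bg.shape)),
                codes.gene_codes[genes],
            ],
            axis=1,
        )  # (m, n_bg + kk, dim)
        gram = A @ A.transpose(0, 2, 1)
        rhs = np.einsum("mqd,md->mq", A, V[pix])
        coef = np.linalg.solve(gram, rhs[..., None])[..., 0]
        block = weights[pix]
        np.put_along_axis(block, genes, coef[:, len(bg):], axis=1)
        weights[pix] = block
    return weights


def gene_weight_maps(
    aligned_stack: np.ndarray,
    codes: GeneCodeMatrix,
    max_genes: int = MAX_GENES_PER_PIXEL,
    alpha: float = OMP_ALPHA,
    clamp: tuple[float, float] = OMP_CLAMP,
) -> np.ndarray:
    """Per-gene weight rasters from an (H, W, n_rounds, n_channels) stack."""
    H, W = aligned_stack.shape[:2]
    expected = (codes.n_rounds, codes.n_channels)
    if aligned_stack.shape[2:] != expected:
        raise ValueError(
            f"aligned stack trailing shape {aligned_stack.shape[2:]} != {expected}"
        )
    V = aligned_stack.reshape(H * W, -1)
    weights = omp_batch(V, codes, max_genes=max_genes, alpha=alpha, clamp=clamp)
    return weights.T.reshape(codes.n_genes, H, W)


def estimate_epsilon_from_stack(
    aligned_stacks: dict[int, np.ndarray],
    codebook: Codebook,
    crosstalk: CrosstalkMatrix,
    stringent_weight: float,
    epsilon_floor: float = 0.01,
    impurity_floor: float = 0.05,
    impurity_factor: float = 2.0,
) -> EpsilonTable:
    """Learn eps_{g,r} from unambiguous detections of a first OMP pass.

    One OMP iteration runs with all eps = 1; weight-map local maxima above
    ``stringent_weight`` (conventionally twice the standard call threshold)
    count as candidate detections.  A detection is *unambiguous* only if,
    in every round, the pixel's channel vector lies along the gene's dye
    signature (with a free per-round scale, since that scale is what is
    being estimated).  The off-signature residual fraction is compared to
    an adaptive cutoff -- ``impurity_factor`` times the median fraction over
    all candidates, floored at ``impurity_floor`` -- so clean data rejects
    any contaminated pixel while noisy data keeps the bulk of genuine
    detections, whose residual fraction is set by the noise level.  The
    mean channel vector of a gene's surviving detections in round r is
    regressed on the dye signature: ``eps_{g,r} = vbar_{g,r} . c_{d_{g,r}}``
    (signatures are unit norm).  Genes without detections keep eps = 1;
    non-positive estimates are floored at ``epsilon_floor``.
    """
    codes = build_gene_codes(codebook, crosstalk, None)
    n_genes, n_rounds = codebook.n_genes, codebook.n_rounds
    n_channels = crosstalk.n_channels
    seqs = codebook.dye_sequences()

    # pass 1: candidate detections and their off-signature residual fraction
    candidates: list[tuple[int, np.ndarray, np.ndarray]] = []  # (gene, vectors, ratio)
    for tile, stack in aligned_stacks.items():
        maps = gene_weight_maps(stack, codes, max_genes=1)
        for g in range(n_genes):
            m = maps[g]
            if not (m > 0).any():
                continue
            peaks = (m == ndimage.maximum_filter(m, size=3, mode="reflect")) & (
                m >= stringent_weight
            )
            rr, cc = np.nonzero(peaks)
            if len(rr) == 0:
                continue
            v = stack[rr, cc].astype(float)  # (n_det, n_rounds, n_channels)
            resid2 = np.zeros(len(rr))
            for r in range(n_rounds):
                c = crosstalk.column(seqs[g, r])
                along = v[:, r] @ c
                resid2 += ((v[:, r] - along[:, None] * c[None, :]) ** 2).sum(axis=1)
            norm = np.maximum(np.linalg.norm(v.reshape(len(rr), -1), axis=1), 1e-12)
            candidates.append((g, v, np.sqrt(resid2) / norm))

    sums = np.zeros((n_genes, n_rounds, n_channels))
    counts = np.zeros(n_genes, dtype=int)
    if candidates:
        cutoff = max(
            impurity_floor,
            impurity_factor * float(np.median(np.concatenate([c[2] for c in candidates]))),
        )
        for g, v, ratio in candidates:
            pure = ratio <= cutoff
            if pure.any():
                sums[g] += v[pure].sum(axis=0)
                counts[g] += int(pure.sum())

    values = np.ones((n_genes, n_rounds))
    mean_vectors = np.full((n_genes, n_rounds, n_channels), np.nan)
    for g in range(n_genes):
        if counts[g] == 0:
            continue
        vbar = sums[g] / counts[g]
        mean_vectors[g] = vbar
        for r in range(n_rounds):
            c = crosstalk.column(seqs[g, r])
            eps = float(vbar[r] @ c)  # c is unit norm, so this is the LS slope
            values[g, r] = max(eps, epsilon_floor)
    return EpsilonTable(values=values, n_spots=counts, mean_vectors=mean_vectors)


def call_genes(
    weight_maps: np.ndarray,
    gene_names: list[str],
    min_weight: float,
    min_neighbourhood: int = 6,
    origin: np.ndarray | None = None,
    tile: int | None = None,
) -> pd.DataFrame:
    """Peak-pick the gene weight maps into a transcript call table.

    A call is an 8-neighbourhood local maximum of a gene's weight raster
    with weight >= ``min_weight`` and at least ``min_neighbourhood``
    positive-weight pixels within radius 2 (suppressing single-pixel noise).
    ``origin`` shifts (row, col) into global coordinates.
    """
    if origin is None:
        origin = np.zeros(2)
    yy, xx = np.mgrid[-2:3, -2:3]
    support_fp = (np.hypot(yy, xx) <= 2.0).astype(float)
    rows = []
    for g, m in enumerate(weight_maps):
        if not (m > 0).any():
            continue
        support = ndimage.convolve((m > 0).astype(float), support_fp, mode="constant")
        peaks = (
            (m == ndimage.maximum_filter(m, size=3, mode="reflect"))
            & (m >= min_weight)
            & (support >= min_neighbourhood)
        )
        rr, cc = np.nonzero(peaks)
        for r, c in zip(rr.tolist(), cc.tolist()):
            rows.append(
                (
                    gene_names[g],
                    g,
                    float(r + origin[0]),
                    float(c + origin[1]),
                    float(m[r, c]),
                    tile if tile is not None else -1,
                    r,
                    c,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_name",
            "gene_index",
            "global_row",
            "global_col",
            "weight",
            "tile",
            "local_row",
            "local_col",
        ],
    )
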