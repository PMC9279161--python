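"""Gene/background code construction, OMP pixel decomposition, epsilon
scale-factor estimation, weight maps and transcript calling."""

import itertools

import numpy as np
import pytest

from combfish.codebook import assign_dye_sequences
from combfish.crosstalk import CrosstalkMatrix
from combfish.genecall import (
    EpsilonTable,
    build_gene_codes,
    call_genes,
    estimate_epsilon_from_stack,
    gene_weight_maps,
    omp_batch,
    omp_decompose,
)

from conftest import bleed_matrix


def exhaustive_subset_fit(v, codes, max_size=2, tol=1e-8):
    """Independent oracle: joint least squares of v on background plus every
    gene subset of size <= max_size; returns the smallest subset whose
    residual is within tol of the best achievable."""
    bg = codes.background_codes
    best = []
    for size in range(0, max_size + 1):
        for subset in itertools.combinations(range(codes.n_genes), size):
            A = np.vstack([bg, codes.gene_codes[list(subset)]])
            coef, *_ = np.linalg.lstsq(A.T, v, rcond=None)
            resid = np.linalg.norm(v - A.T @ coef)
            best.append((resid, size, subset, coef[len(bg):]))
    best.sort(key=lambda t: (t[0], t[1], t[2]))
    min_resid = best[0][0]
    for resid, size, subset, coef in sorted(best, key=lambda t: (t[1], t[0])):
        if resid <= min_resid + tol:
            return set(subset), coef
    raise AssertionError


class TestBuildGeneCodes:
    def test_identity_crosstalk_unit_epsilon(self, small_codebook):
        codes = build_gene_codes(small_codebook, CrosstalkMatrix.identity(7))
        seqs = small_codebook.dye_sequences()
        for g in range(5):
            code = codes.gene_codes[g].reshape(7, 7)
            for r in range(7):
                expect = np.zeros(7)
                expect[seqs[g, r]] = 1 / np.sqrt(7)
                np.testing.assert_allclose(code[r], expect, atol=1e-12)

    def test_background_code_structure(self, small_codebook):
        codes = build_gene_codes(small_codebook, CrosstalkMatrix.identity(7))
        bg2 = codes.background_codes[2].reshape(7, 7)
        np.testing.assert_allclose(bg2[:, 2], 1 / np.sqrt(7), atol=1e-12)
        assert np.abs(np.delete(bg2, 2, axis=1)).max() == 0

    def test_epsilon_scales_rounds_before_normalization(self, small_codebook):
        eps = EpsilonTable.ones(small_codebook.n_genes, 7)
        eps.values[0, 0] = 2.0
        codes = build_gene_codes(small_codebook, CrosstalkMatrix.identity(7), eps)
        code = codes.gene_codes[0].reshape(7, 7)
        # round 0 entry twice the others (up to the common normalization)
        peak = code.max(axis=1)
        assert peak[0] == pytest.approx(2 * peak[1], rel=1e-12)
        assert np.linalg.norm(code) == pytest.approx(1.0)

    def test_zero_epsilon_gene_raises(self, small_codebook):
        eps = EpsilonTable.ones(small_codebook.n_genes, 7)
        eps.values[3] = 0.0
        with pytest.raises(ValueError, match="g03"):
            build_gene_codes(small_codebook, CrosstalkMatrix.identity(7), eps)


class TestOmpDecompose:
    def test_single_gene_pixel(self, small_codes):
        v = 1.7 * small_codes.gene_codes[4]
        dec = omp_decompose(v, small_codes)
        assert dec.genes == [4]
        # the gene code is not orthogonal to the background, so the joint
        # fit splits the vector; the gene still carries most of the weight
        assert dec.residual_norms[-1] < 1e-10
        assert dec.coefficients[0] > 0

    def test_zero_pixel_selects_nothing(self, small_codes):
        dec = omp_decompose(np.zeros(49), small_codes)
        assert dec.genes == []
        assert np.all(dec.background_coefficients == 0)

    def test_two_gene_pixel_matches_exhaustive_subset_oracle(self, small_codes):
        v = 0.8 * small_codes.gene_codes[3] + 0.5 * small_codes.gene_codes[17]
        dec = omp_decompose(v, small_codes)
        oracle_genes, oracle_coef = exhaustive_subset_fit(v, small_codes)
        assert set(dec.genes) == oracle_genes == {3, 17}
        np.testing.assert_allclose(sorted(dec.coefficients), sorted(oracle_coef), atol=1e-8)

    def test_oracle_agreement_on_random_pixels(self, small_codes):
        """Noiseless pixels with <= 2 planted genes: OMP must recover the
        planted set (and thus agree with best-subset least squares)."""
        rng = np.random.default_rng(5)
        agree = 0
        n = 200
        for _ in range(n):
            k = rng.integers(0, 3)
            genes = rng.choice(small_codes.n_genes, k, replace=False)
            v = np.zeros(49)
            for g in genes:
                v += rng.uniform(0.3, 1.5) * small_codes.gene_codes[g]
            v += small_codes.background_codes.T @ rng.uniform(0, 0.5, 7)
            dec = omp_decompose(v, small_codes)
            agree += set(dec.genes) == set(genes.tolist())
        assert agree / n >= 0.99

    def test_residual_non_increasing_and_active_set_capped(self, small_codes):
        rng = np.random.default_rng(6)
        for _ in range(20):
            v = rng.normal(size=49)
            dec = omp_decompose(v, small_codes)
            assert len(dec.genes) <= 6
            assert np.all(np.diff(dec.residual_norms) <= 1e-10)

    def test_non_finite_input_raises(self, small_codes):
        v = np.zeros(49)
        v[0] = np.nan
        with pytest.raises(ValueError):
            omp_decompose(v, small_codes)


class TestOmpBatch:
    def test_batch_matches_per_pixel(self, small_codes):
        rng = np.random.default_rng(7)
        V = []
        for _ in range(300):
            v = 0.05 * rng.standard_normal(49)
            for g in rng.choice(small_codes.n_genes, rng.integers(0, 3), replace=False):
                v += rng.uniform(0.3, 2.0) * small_codes.gene_codes[g]
            V.append(v)
        V = np.asarray(V)
        W = omp_batch(V, small_codes)
        for i in range(len(V)):
            dec = omp_decompose(V[i], small_codes)
            assert set(np.nonzero(W[i])[0]) == set(dec.genes)
            if dec.genes:
                np.testing.assert_allclose(W[i][dec.genes], dec.coefficients, atol=1e-8)


class TestWeightMapsAndCalls:
    def _stack_with_spots(self, codes, spots, shape=(48, 48), sigma=1.5):
        """Render (pos, gene, amplitude) spots into an aligned pixel stack."""
        stack = np.zeros((*shape, 7, 7))
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for (r0, c0), g, a in spots:
            bump = a * np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma**2))
            stack += bump[:, :, None, None] * codes.gene_codes[g].reshape(7, 7)
        return stack

    def test_single_spot_peaks_in_its_own_map_only(self, small_codes):
        stack = self._stack_with_spots(small_codes, [((24, 24), 5, 3.0)])
        maps = gene_weight_maps(stack, small_codes)
        assert maps[5].argmax() == 24 * 48 + 24
        others = np.delete(maps, 5, axis=0)
        assert others[:, 22:27, 22:27].max() < 0.1 * maps[5].max()

    def test_overlapping_spots_of_different_genes_both_peak(self, small_codes):
        spots = [((24, 24), 2, 3.0), ((24, 27), 9, 3.0)]  # 3 px apart
        maps = gene_weight_maps(self._stack_with_spots(small_codes, spots), small_codes)
        for (r0, c0), g, _ in spots:
            peak = np.unravel_index(maps[g].argmax(), maps[g].shape)
            assert abs(peak[0] - r0) <= 1 and abs(peak[1] - c0) <= 1

    def test_pure_background_pixels_give_empty_maps(self, small_codes):
        stack = np.zeros((16, 16, 7, 7))
        stack[:, :, :, 3] = 2.0  # constant across rounds in one channel
        maps = gene_weight_maps(stack, small_codes)
        assert np.abs(maps).max() == 0

    def test_calls_shift_with_translated_input(self, small_codes):
        stack = self._stack_with_spots(small_codes, [((20, 22), 7, 3.0)])
        maps = gene_weight_maps(stack, small_codes)
        rolled = gene_weight_maps(np.roll(stack, (5, -3), axis=(0, 1)), small_codes)
        a = call_genes(maps, small_codes.gene_names, min_weight=0.5)
        b = call_genes(rolled, small_codes.gene_names, min_weight=0.5)
        assert len(a) == len(b) == 1
        assert b.loc[0, "global_row"] == a.loc[0, "global_row"] + 5
        assert b.loc[0, "global_col"] == a.loc[0, "global_col"] - 3

    def test_empty_maps_give_empty_table(self, small_codes):
        calls = call_genes(np.zeros((30, 16, 16)), small_codes.gene_names, min_weight=0.5)
        assert len(calls) == 0


class TestEstimateEpsilon:
    def test_parallel_mean_vector_gives_exact_scale(self):
        # vbar = 2 c_d -> least squares slope 2 (signatures are unit norm)
        C = CrosstalkMatrix(bleed_matrix())
        vbar = 2.0 * C.column(3)
        assert vbar @ C.column(3) == pytest.approx(2.0)

    def test_orthogonal_mean_vector_floored(self, small_codebook):
        """A mean vector orthogonal to the dye signature yields epsilon 0,
        which is floored to a small positive constant."""
        C = CrosstalkMatrix(np.eye(7))
        seqs = small_codebook.dye_sequences()
        g = 0
        stack = np.zeros((32, 32, 7, 7))
        # plant a strong detection for gene 0 but zero out one round's channel
        code = build_gene_codes(small_codebook, C).gene_codes[g].reshape(7, 7)
        stack[16, 16] = 5.0 * code
        stack[16, 16, 2, :] = 0.0
        stack[16, 16, 2, (seqs[g, 2] + 1) % 7] = 5.0  # energy in the wrong channel
        eps = estimate_epsilon_from_stack({0: stack}, small_codebook, C, stringent_weight=0.5)
        if eps.n_spots[g] > 0:
            assert eps.values[g, 2] == pytest.approx(0.01)

    def test_planted_epsilon_recovered_noiseless(self, small_codebook):
        """Spots rendered with planted per-gene/round scales: the estimated
        table matches the planted one (up to the per-gene overall scale that
        is absorbed by code normalization) within 5%."""
        rng = np.random.default_rng(8)
        C = CrosstalkMatrix(bleed_matrix())
        n_genes = small_codebook.n_genes
        planted = np.exp(rng.uniform(np.log(0.5), np.log(2.0), (n_genes, 7)))
        seqs = small_codebook.dye_sequences()
        stack = np.zeros((128, 128, 7, 7))
        coords = [(8 + 16 * i, 8 + 16 * j) for i in range(8) for j in range(8)]
        yy, xx = np.mgrid[:128, :128]
        for k, (r0, c0) in enumerate(coords[:n_genes]):
            g = k
            bump = 3.0 * np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * 1.5**2))
            for r in range(7):
                stack[:, :, r, :] += (
                    bump[:, :, None] * planted[g, r] * C.column(seqs[g, r])[None, None, :]
                )
        est = estimate_epsilon_from_stack({0: stack}, small_codebook, C, stringent_weight=1.0)
        assert (est.n_spots > 0).all()
        est_n = est.values / est.values.mean(axis=1, keepdims=True)
        planted_n = planted / planted.mean(axis=1, keepdims=True)
        rel = np.abs(est_n - planted_n) / planted_n
        assert rel.max() < 0.05
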