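import numpy as np
import pytest

from dsbnorm import (
    CountMatrix,
    ambient_correct,
    cell_background_means,
    dsb_normalize,
    estimate_ambient,
    remove_technical,
    technical_component,
)
from dsbnorm.dsb_core import TechnicalComponent


def _bg(counts, ids=None):
    counts = np.atleast_2d(np.asarray(counts))
    ids = ids or [f"p{i}" for i in range(counts.shape[0])]
    return CountMatrix(counts, ids, [f"e{j}" for j in range(counts.shape[1])])


class TestEstimateAmbient:
    def test_worked_example_mean_and_sample_sd(self):
        # independent arithmetic oracle on ln(count + 10)
        logs = np.log(np.array([0, 10, 20, 30]) + 10.0)
        prof = estimate_ambient(_bg([[0, 10, 20, 30]]), P=10)
        assert np.isclose(prof.mu_n[0], logs.mean(), atol=1e-12)
        assert np.isclose(prof.mu_n[0], 3.097098, atol=1e-6)
        assert np.isclose(prof.sigma_n[0], logs.std(ddof=1), atol=1e-12)
        assert np.isclose(prof.sigma_n[0], 0.601167, atol=1e-6)

    def test_all_zero_protein_is_dropped(self, caplog):
        prof = estimate_ambient(_bg([[0, 10, 20, 30], [0, 0, 0, 0]]), P=10)
        assert prof.dropped_proteins == ["p1"]
        assert list(prof.protein_ids) == ["p0"]

    def test_too_few_droplets_and_all_degenerate_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_ambient(_bg([[5]]))
        with pytest.raises(ValueError, match="zero variance"):
            estimate_ambient(_bg([[3, 3, 3]]))


class TestAmbientCorrect:
    def test_worked_example_value(self):
        prof = estimate_ambient(_bg([[0, 10, 20, 30]]), P=10)
        cell = CountMatrix(np.array([[90]]), ["p0"], ["c0"])
        y = ambient_correct(cell, prof)[0, 0]
        logs = np.log(np.array([0, 10, 20, 30]) + 10.0)
        expected = (np.log(100.0) - logs.mean()) / logs.std(ddof=1)
        assert np.isclose(y, expected, atol=1e-12)
        assert np.isclose(y, 2.5086, atol=1e-4)

    def test_count_at_profile_mean_gives_zero(self):
        prof = estimate_ambient(_bg([[0, 10, 20, 30]]), P=10)
        x = np.exp(prof.mu_n[0]) - 10.0  # ln(x+P) == mu_n
        logc = np.log(x + 10.0)
        assert np.isclose((logc - prof.mu_n[0]) / prof.sigma_n[0], 0.0, atol=1e-12)

    def test_background_self_standardizes(self, small_sim):
        _, empties, _ = small_sim
        prof = estimate_ambient(empties)
        Y = ambient_correct(empties, prof)
        assert np.abs(Y.mean(axis=1)).max() < 1e-12
        assert np.abs(Y.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_unknown_protein_named_in_error(self):
        prof = estimate_ambient(_bg([[0, 10, 20, 30]]), P=10)
        cell = CountMatrix(np.array([[1]]), ["mystery"], ["c0"])
        with pytest.raises(KeyError, match="mystery"):
            ambient_correct(cell, prof)

    def test_strictly_increasing_in_raw_count(self):
        prof = estimate_ambient(_bg([[0, 10, 20, 30]]), P=10)
        counts = np.arange(0, 200)[None, :]
        cells = CountMatrix(counts, ["p0"], [f"c{j}" for j in range(200)])
        y = ambient_correct(cells, prof)[0]
        assert np.all(np.diff(y) > 0)


class TestCellBackgroundMeans:
    def test_bimodal_cell_mu1_near_zero(self):
        rng = np.random.default_rng(0)
        col = np.concatenate([rng.normal(0, 1, 40), rng.normal(8, 1, 10)])
        Y = np.tile(col[:, None], (1, 3))
        mu1, fits = cell_background_means(Y, seed=0)
        assert np.all(np.abs(mu1) < 0.3)
        assert not fits.fallback_used.any()

    def test_constant_cell_takes_fallback_path(self):
        Y = np.column_stack([np.full(6, 1.5), np.arange(6.0)])
        with pytest.warns(RuntimeWarning):
            mu1, fits = cell_background_means(Y, seed=0)
        assert fits.fallback_used[0] and not fits.fallback_used[1]
        assert np.isclose(mu1[0], 1.5)

    def test_fewer_than_four_proteins_rejected(self):
        with pytest.raises(ValueError, match="4 proteins"):
            cell_background_means(np.ones((3, 5)))

    def test_mu1_concordant_between_k2_and_k3(self, small_sim):
        cells, empties, _ = small_sim
        prof = estimate_ambient(empties)
        Y = ambient_correct(cells, prof)
        mu1_2, _ = cell_background_means(Y, seed=1, k=2)
        mu1_3, _ = cell_background_means(Y, seed=1, k=3)
        assert np.corrcoef(mu1_2, mu1_3)[0, 1] >= 0.95


class TestTechnicalComponent:
    def test_single_column_lambda_is_zscored_mu1(self):
        rng = np.random.default_rng(0)
        mu1 = rng.normal(size=50)
        tc = technical_component(mu1, None)
        z = (mu1 - mu1.mean()) / mu1.std(ddof=1)
        assert np.allclose(tc.lam, z, atol=1e-9)

    def test_perfectly_correlated_columns_share_loadings(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=40)
        tc = technical_component(v, (2.0 * v + 5.0)[:, None])
        assert np.isclose(abs(tc.loadings[0]), abs(tc.loadings[1]), atol=1e-9)
        z = (v - v.mean()) / v.std(ddof=1)
        ratio = tc.lam / z
        assert np.allclose(ratio, ratio[0], atol=1e-9)

    def test_lambda_zero_mean_and_sign_convention(self, small_sim):
        cells, empties, _ = small_sim
        prof = estimate_ambient(empties)
        Y = ambient_correct(cells, prof)
        mu1, _ = cell_background_means(Y, seed=1)
        tc = technical_component(mu1, Y[cells.isotype_flags].T)
        assert abs(tc.lam.mean()) < 1e-10
        noise = np.column_stack([mu1, Y[cells.isotype_flags].T])
        z = (noise - noise.mean(0)) / noise.std(0, ddof=1)
        assert np.corrcoef(tc.lam, z.mean(axis=1))[0, 1] >= 0

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            tc = technical_component(v, np.full((30, 1), 3.0))
        assert tc.noise_columns == ["mu1"]
        with pytest.raises(ValueError, match="zero variance"):
            technical_component(np.full(30, 1.0), np.full((30, 1), 3.0))


class TestRemoveTechnical:
    def _tc(self, lam):
        lam = np.asarray(lam, dtype=float)
        return TechnicalComponent(
            cell_ids=np.arange(lam.size), mu1=lam, isotype_values=np.empty((lam.size, 0)),
            lam=lam - lam.mean(), loadings=np.ones(1), sign_fixed=False,
        )

    def test_perfect_linear_dependence_collapses_to_intercept(self):
        lam = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        Y = (2.0 + 0.5 * lam)[None, :]
        out = remove_technical(Y, self._tc(lam))
        assert np.allclose(out, 2.0, atol=1e-12)

    def test_constant_lambda_returns_input_with_warning(self):
        Y = np.arange(8.0).reshape(2, 4)
        with pytest.warns(RuntimeWarning, match="constant"):
            out = remove_technical(Y, self._tc(np.full(4, 3.0)))
        assert np.array_equal(out, Y)

    def test_orthogonality_and_mean_preservation_match_ols_oracle(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(10, 200))
        lam = rng.normal(size=200)
        out = remove_technical(Y, self._tc(lam))
        lam_c = lam - lam.mean()
        for p in range(10):
            beta, alpha = np.polyfit(lam_c, Y[p], 1)  # closed-form OLS oracle
            assert np.allclose(out[p], Y[p] - beta * lam_c, atol=1e-10)
            assert abs(out[p].mean() - Y[p].mean()) < 1e-9
            assert abs(np.corrcoef(out[p], lam)[0, 1]) < 1e-8


class TestDsbNormalize:
    def test_denoise_false_returns_step_one_values(self, small_sim):
        cells, empties, _ = small_sim
        norm = dsb_normalize(cells, empties, denoise=False)
        prof = estimate_ambient(empties)
        assert np.array_equal(norm.values, ambient_correct(cells, prof))

    def test_same_seed_runs_are_bit_identical(self, small_sim):
        cells, empties, _ = small_sim
        a = dsb_normalize(cells, empties, seed=4)
        b = dsb_normalize(cells, empties, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_overlapping_barcodes_rejected(self, small_sim):
        cells, _, _ = small_sim
        with pytest.raises(ValueError, match="both cells and background"):
            dsb_normalize(cells, cells)

    def test_missing_isotypes_instructs_alternative_mode(self, small_sim):
        cells, empties, _ = small_sim
        keep = ~cells.isotype_flags
        with pytest.raises(ValueError, match="use_isotype=False"):
            dsb_normalize(cells.subset_proteins(keep), empties.subset_proteins(keep))

    def test_denoise_without_isotypes_uses_mu1_alone(self, small_sim):
        cells, empties, _ = small_sim
        keep = ~cells.isotype_flags
        norm = dsb_normalize(
            cells.subset_proteins(keep), empties.subset_proteins(keep),
            use_isotype=False, seed=1,
        )
        assert norm.provenance["noise_columns"] == ["mu1"]
        assert np.all(np.isfinite(norm.values))

    def test_isotypes_are_returned_but_flagged(self, small_sim):
        cells, empties, _ = small_sim
        norm = dsb_normalize(cells, empties, seed=1)
        assert norm.values.shape[0] == cells.n_proteins
        assert norm.isotype_flags.sum() == cells.isotype_flags.sum()
        assert set(norm.provenance["isotype_proteins"]) == set(
            map(str, cells.protein_ids[cells.isotype_flags])
        )
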