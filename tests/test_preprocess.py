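"""Outlier truncation, PCA, batch adjustment, deconvolution, surrogate
variables, and design construction."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dualtissue as dt
from dualtissue.preprocess import (
    _cell_pcs,
    tukey_fences,
    truncate_outliers_rows,
)


class TestTruncateOutliers:
    def test_hand_oracle_five_values(self):
        # fences from (0.50, 0.51, 0.52, 0.53, 0.99): Q1=0.51, Q3=0.53,
        # IQR=0.02 -> upper fence 0.56, so 0.99 -> 0.53 (in-fence max)
        out = dt.truncate_outliers([0.50, 0.51, 0.52, 0.53, 0.99])
        np.testing.assert_allclose(out, [0.50, 0.51, 0.52, 0.53, 0.53])

    def test_no_outliers_is_fixed_point(self, rng):
        x = rng.uniform(0.4, 0.6, 50)
        np.testing.assert_array_equal(dt.truncate_outliers(x), x)

    def test_too_few_values(self):
        with pytest.raises(dt.DegenerateInputError):
            dt.truncate_outliers([0.1, 0.2, 0.3])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=4, max_size=40))
    def test_within_observed_range_and_rank_preserving(self, values):
        x = np.asarray(values)
        once = dt.truncate_outliers(x)
        assert once.min() >= x.min() and once.max() <= x.max()
        # rank order of non-outlier values unchanged
        lo, hi = tukey_fences(x)
        inside = (x >= lo) & (x <= hi)
        np.testing.assert_array_equal(
            np.argsort(x[inside], kind="stable"),
            np.argsort(once[inside], kind="stable"),
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_idempotent_on_bulk_plus_sparse_outliers(self, seed):
        """A second truncation pass changes nothing when outliers are sparse
        (the quartiles, hence the fences, are untouched by boundary
        replacement of a small tail)."""
        r = np.random.default_rng(seed)
        x = np.concatenate([r.normal(0.5, 0.05, 95), r.uniform(0.9, 1.0, 5)])
        once = dt.truncate_outliers(x)
        np.testing.assert_array_equal(dt.truncate_outliers(once), once)

    def test_rowwise_matches_vector_version(self, rng):
        m = rng.uniform(0, 1, size=(20, 30))
        m[:, 0] = 0.999  # force outliers on some rows
        rows = truncate_outliers_rows(m)
        for i in range(m.shape[0]):
            np.testing.assert_allclose(rows[i], dt.truncate_outliers(m[i]))


class TestPca:
    def test_rank_one_matrix_explains_everything(self, rng):
        direction = rng.normal(size=50)
        weights = rng.normal(size=12)
        X = pd.DataFrame(np.outer(direction, weights))  # CpG x sample
        scores, varexp = dt.run_pca(X, n_components=3)
        assert varexp[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_orthogonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 15)))
        scores, _ = dt.run_pca(X)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_full_rank_reconstruction(self, rng):
        """Loadings recovered by least squares reproduce the centered matrix
        (direct multiplication oracle)."""
        X = pd.DataFrame(rng.normal(size=(40, 10)))
        scores, _ = dt.run_pca(X)
        Xc = X.to_numpy().T - X.to_numpy().T.mean(axis=0, keepdims=True)
        loadings, *_ = np.linalg.lstsq(scores.to_numpy(), Xc, rcond=None)
        np.testing.assert_allclose(scores.to_numpy() @ loadings, Xc, atol=1e-8)

    def test_constant_matrix_rejected(self):
        X = pd.DataFrame(np.full((10, 5), 0.3))
        with pytest.raises(dt.DegenerateInputError):
            dt.run_pca(X)


class TestAssociatePcs:
    def test_pc_equal_to_batch_indicator(self):
        idx = [f"s{i}" for i in range(40)]
        batch = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        scores = pd.DataFrame({"PC1": (batch == "a").astype(float)}, index=idx)
        diag = dt.associate_pcs(scores, batch.to_frame("batch"))
        assert diag["p_value"].iloc[0] < 1e-10

    def test_constant_pc_p_one(self):
        idx = [f"s{i}" for i in range(10)]
        scores = pd.DataFrame({"PC1": np.ones(10)}, index=idx)
        md = pd.DataFrame({"batch": ["a"] * 5 + ["b"] * 5,
                           "age": np.arange(10.0)}, index=idx)
        diag = dt.associate_pcs(scores, md)
        assert (diag["p_value"] == 1.0).all()

    def test_single_level_variable_skipped(self):
        idx = [f"s{i}" for i in range(10)]
        scores = pd.DataFrame({"PC1": np.arange(10.0)}, index=idx)
        md = pd.DataFrame({"batch": ["only"] * 10}, index=idx)
        assert len(dt.associate_pcs(scores, md)) == 0

    def test_null_calibration(self, rng):
        """P values under a permuted batch label are uniform: the rejection
        rate at 0.05 stays within its Monte-Carlo band over 1,000 replicates."""
        idx = [f"s{i}" for i in range(60)]
        base = np.array(["a"] * 30 + ["b"] * 30)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            scores = pd.DataFrame({"PC1": rng.normal(size=60)}, index=idx)
            md = pd.DataFrame({"batch": rng.permutation(base)}, index=idx)
            p = dt.associate_pcs(scores, md)["p_value"].iloc[0]
            hits += p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


def _toy_m(values, samples=None):
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return dt.MValueMatrix(pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples
    ))


class TestCombat:
    def test_noiseless_shift_equalizes_batch_means(self, rng):
        base = rng.normal(0, 2, size=(30, 1))
        X = np.tile(base, (1, 20))
        X[:, 10:] += 0.8
        batch = pd.Series(["a"] * 10 + ["b"] * 10,
                          index=[f"s{i}" for i in range(20)])
        adj = dt.combat_adjust(_toy_m(X), batch).values.to_numpy()
        diff = adj[:, :10].mean(axis=1) - adj[:, 10:].mean(axis=1)
        assert np.abs(diff).max() < 1e-6

    def test_single_batch_is_noop(self, rng):
        X = rng.normal(size=(15, 12))
        batch = pd.Series(["only"] * 12, index=[f"s{i}" for i in range(12)])
        adj = dt.combat_adjust(_toy_m(X), batch).values.to_numpy()
        np.testing.assert_allclose(adj, X, atol=1e-8)

    def test_singleton_batch_rejected(self, rng):
        X = rng.normal(size=(5, 5))
        batch = pd.Series(["a", "a", "a", "a", "lonely"],
                          index=[f"s{i}" for i in range(5)])
        with pytest.raises(dt.IntegrityError, match="lonely"):
            dt.combat_adjust(_toy_m(X), batch)

    def test_reduces_between_batch_f_on_every_cpg(self, rng):
        n = 60
        X = rng.normal(size=(40, n))
        shifts = rng.normal(0, 1.0, size=(40, 3))
        labels = np.repeat(["a", "b", "c"], n // 3)
        for k, lab in enumerate(["a", "b", "c"]):
            X[:, labels == lab] += shifts[:, [k]]
        batch = pd.Series(labels, index=[f"s{i}" for i in range(n)])
        adj = dt.combat_adjust(_toy_m(X), batch).values.to_numpy()

        def fstats(mat):
            return np.array([
                stats.f_oneway(*[row[labels == g] for g in "abc"]).statistic
                for row in mat
            ])

        assert (fstats(adj) < fstats(X)).all()

    def test_preserves_covariate_signal(self, rng):
        n = 80
        x = rng.normal(size=n)
        slopes = rng.normal(0, 1, size=25)
        X = rng.normal(0, 0.1, size=(25, n)) + np.outer(slopes, x)
        labels = np.array(["a"] * 40 + ["b"] * 40)
        X[:, labels == "b"] += rng.normal(0, 1, size=(25, 1))
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"intercept": 1.0, "x": x}, index=idx)
        adj = dt.combat_adjust(_toy_m(X, idx), pd.Series(labels, index=idx), cov)
        est = [np.polyfit(x, row, 1)[0] for row in adj.values.to_numpy()]
        np.testing.assert_allclose(est, slopes, rtol=0.1, atol=0.05)

    def test_matches_bioconductor_sva_combat(self, rng, tmp_path):
        """Independent oracle: the classical-convention adjustment reproduces
        Bioconductor sva's parametric ComBat on a shared fixture."""
        G, n = 60, 24
        X = rng.normal(0, 1, (G, n)) + rng.normal(0, 2, (G, 1))
        labels = np.array(["b1"] * 8 + ["b2"] * 10 + ["b3"] * 6)
        shift = {"b1": 0.0, "b2": 0.8, "b3": -0.5}
        X += np.array([shift[b] for b in labels])[None, :] * rng.uniform(0.5, 1.5, (G, 1))
        idx = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        X += np.outer(rng.normal(0, 0.5, G), x)
        cov = pd.DataFrame({"intercept": 1.0, "x": x}, index=idx)
        mine = dt.combat_adjust(_toy_m(X, idx), pd.Series(labels, index=idx), cov,
                                df_corrected_variance=False)
        dat = tmp_path / "dat.csv"
        pd.DataFrame(X, index=[f"g{i}" for i in range(G)], columns=idx).to_csv(dat)
        pd.DataFrame({"batch": labels, "x": x}, index=idx).to_csv(tmp_path / "pheno.csv")
        script = tmp_path / "combat.R"
        script.write_text(
            "suppressMessages(library(sva))\n"
            f'dat <- as.matrix(read.csv("{dat}", row.names=1))\n'
            f'ph <- read.csv("{tmp_path / "pheno.csv"}", row.names=1)\n'
            "mod <- model.matrix(~x, data=ph)\n"
            "adj <- ComBat(dat=dat, batch=ph$batch, mod=mod, par.prior=TRUE)\n"
            f'write.csv(adj, "{tmp_path / "r_adj.csv"}")\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_adj = pd.read_csv(tmp_path / "r_adj.csv", index_col=0)
        np.testing.assert_allclose(
            mine.values.to_numpy(), r_adj.to_numpy(), atol=1e-4
        )


class TestCellDeconvolution:
    def _panel(self, rng, k=2, n_cpgs=50):
        return pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(n_cpgs, k)),
            index=[f"cg{i:03d}" for i in range(n_cpgs)],
            columns=[f"type{j}" for j in range(k)],
        )

    def _matrix(self, panel, W, noise=0.0, rng=None):
        mix = panel.to_numpy() @ W.T
        if noise and rng is not None:
            mix = np.clip(mix + rng.normal(0, noise, mix.shape), 0, 1)
        return dt.BetaMatrix(pd.DataFrame(
            mix, index=panel.index, columns=[f"s{i}" for i in range(W.shape[0])]
        ))

    def test_exact_two_component_recovery(self, rng):
        panel = self._panel(rng)
        est = dt.estimate_cell_proportions(
            self._matrix(panel, np.array([[0.3, 0.7]])), panel
        )
        np.testing.assert_allclose(
            est.proportions.to_numpy()[0], [0.3, 0.7], atol=1e-6
        )
        assert est.residual_norm.iloc[0] < 1e-6

    def test_pure_profile_recovery(self, rng):
        panel = self._panel(rng, k=3)
        est = dt.estimate_cell_proportions(
            self._matrix(panel, np.array([[0.0, 1.0, 0.0]])), panel
        )
        np.testing.assert_allclose(est.proportions.to_numpy()[0], [0, 1, 0], atol=1e-6)

    def test_noisy_recovery_rmse(self, rng):
        panel = self._panel(rng, k=3, n_cpgs=120)
        W = rng.dirichlet([2.0, 2.0, 2.0], size=100)
        est = dt.estimate_cell_proportions(
            self._matrix(panel, W, noise=0.02, rng=rng), panel
        )
        rmse = np.sqrt(((est.proportions.to_numpy() - W) ** 2).mean(axis=0))
        assert (rmse < 0.03).all()

    def test_output_on_simplex(self, rng):
        panel = self._panel(rng, k=4, n_cpgs=80)
        W = rng.dirichlet(np.ones(4), size=30)
        est = dt.estimate_cell_proportions(
            self._matrix(panel, W, noise=0.05, rng=rng), panel
        )
        arr = est.proportions.to_numpy()
        assert (arr >= 0).all()
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-8)

    def test_missing_panel_cpgs_listed(self, rng, small_beta):
        panel = pd.DataFrame(
            {"a": [0.1, 0.9], "b": [0.9, 0.1]}, index=["absent1", "absent2"]
        )
        with pytest.raises(dt.IntegrityError, match="absent"):
            dt.estimate_cell_proportions(small_beta, panel)


class TestSurrogateVariables:
    def test_zero_residual_gives_zero_scores(self, rng):
        idx = [f"s{i}" for i in range(20)]
        x = rng.normal(size=20)
        design = pd.DataFrame({"intercept": 1.0, "x": x}, index=idx)
        X = np.outer(rng.normal(size=30), x)  # pure design signal
        sv = dt.estimate_surrogate_variables(_toy_m(X, idx), design, 2)
        assert np.abs(sv.to_numpy()).max() < 1e-8

    def test_recovers_hidden_batch(self, rng):
        idx = [f"s{i}" for i in range(60)]
        hidden = np.array([1.0] * 30 + [0.0] * 30)
        X = rng.normal(0, 0.3, size=(100, 60)) + np.outer(
            rng.normal(0, 1, 100), hidden
        )
        design = pd.DataFrame({"intercept": np.ones(60)}, index=idx)
        sv = dt.estimate_surrogate_variables(_toy_m(X, idx), design, 1)
        r = np.corrcoef(sv["SV1"], hidden)[0, 1]
        assert abs(r) > 0.9

    def test_columns_orthogonal(self, rng):
        idx = [f"s{i}" for i in range(25)]
        X = rng.normal(size=(60, 25))
        design = pd.DataFrame({"intercept": np.ones(25)}, index=idx)
        sv = dt.estimate_surrogate_variables(_toy_m(X, idx), design, 4).to_numpy()
        gram = sv.T @ sv
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_n_sv_too_large_rejected(self, rng):
        idx = [f"s{i}" for i in range(10)]
        design = pd.DataFrame({"intercept": np.ones(10)}, index=idx)
        with pytest.raises(dt.ConfigError):
            dt.estimate_surrogate_variables(
                _toy_m(rng.normal(size=(20, 10)), idx), design, 9
            )


class TestBuildDesign:
    def _metadata(self, rng, n=60, ethnicities=("chinese", "malay", "indian")):
        idx = [f"s{i}" for i in range(n)]
        return pd.DataFrame({
            "sex": rng.choice(["male", "female"], n),
            "gestational_age": rng.normal(38.5, 1, n).round(2),
            "ethnicity": rng.choice(ethnicities, n),
            "hospital": rng.choice(["KKH", "NUH"], n),
            "bisulfite_batch": rng.choice(["bs0", "bs1"], n),
            "chip_position": rng.choice([f"pos{i}" for i in range(4)], n),
            "dna_extraction_batch": rng.choice(["ex0", "ex1"], n),
            "chip_set": rng.choice(["set0", "set1"], n),
        }, index=idx)

    def _props(self, rng, idx, k=3):
        W = rng.dirichlet(np.ones(k), size=len(idx))
        return pd.DataFrame(W, index=idx, columns=[f"t{j}" for j in range(k)])

    def test_cell_pc_and_interaction_dimensions(self, rng):
        md = self._metadata(rng)
        props = self._props(rng, md.index, k=3)
        design = dt.build_design(md, props, tissue="cord_tissue")
        pcs = [c for c in design.frame.columns
               if c.startswith("cellPC") and ":" not in c]
        inter = [c for c in design.frame.columns if ":" in c]
        assert 1 <= len(pcs) <= 2           # 3 cell types -> at most 2 PCs
        assert len(inter) <= 2 * len(pcs)   # 2 non-reference ethnicity dummies

    @pytest.mark.parametrize("tissue, present, absent", [
        ("cord_tissue", "dna_extraction_batch", "chip_set"),
        ("cord_blood", "chip_set", "dna_extraction_batch"),
    ])
    def test_tissue_specific_covariate(self, rng, tissue, present, absent):
        md = self._metadata(rng)
        design = dt.build_design(md, self._props(rng, md.index), tissue=tissue)
        cols = " ".join(design.frame.columns)
        assert present in cols
        assert absent not in cols

    def test_single_ethnicity_degenerate(self, rng):
        md = self._metadata(rng, ethnicities=("chinese",))
        design = dt.build_design(md, self._props(rng, md.index), tissue="cord_blood")
        assert not any("ethnicity" in c for c in design.frame.columns)
        assert not any(":" in c for c in design.frame.columns)

    def test_full_rank_and_deterministic(self, rng):
        md = self._metadata(rng)
        props = self._props(rng, md.index)
        d1 = dt.build_design(md, props, tissue="cord_tissue")
        d2 = dt.build_design(md, props, tissue="cord_tissue")
        assert d1.rank == len(d1.frame.columns)
        pd.testing.assert_frame_equal(d1.frame, d2.frame)
        assert d1.dropped == d2.dropped

    def test_redundant_column_dropped_and_logged(self, rng):
        md = self._metadata(rng)
        props = self._props(rng, md.index)
        extra = pd.DataFrame({"ga_copy": md["gestational_age"]}, index=md.index)
        design = dt.build_design(md, props, tissue="cord_tissue", extra=extra)
        assert "ga_copy" in design.dropped
        assert design.rank == len(design.frame.columns)

    def test_cell_pc_count_respects_variance_target(self, rng):
        idx = [f"s{i}" for i in range(50)]
        W = rng.dirichlet(np.ones(5), size=50)
        pcs, var = _cell_pcs(pd.DataFrame(W, index=idx))
        assert pcs.shape[1] <= 4
        assert var.sum() >= 0.90 or pcs.shape[1] == 4
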