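"""TIC normalization, PCA/PLS-DA/VIP and fold-change estimation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import silhouette_score

from cellmech import sims, synth
from cellmech.sims import PeakTable, fold_changes, pca_scores, plsda_vip, \
    saturation_ratios, tic_normalize


def small_table(data, tic=None, cols=None):
    df = pd.DataFrame(np.asarray(data, dtype=float),
                      columns=cols or [f"p{i}" for i in
                                       range(np.shape(data)[1])])
    t = pd.Series(tic, index=df.index) if tic is not None else None
    return PeakTable(intensities=df, tic=t)


class TestTicNormalize:
    def test_single_peak_normalizes_to_one(self):
        out = tic_normalize(small_table([[5.0]], tic=[5.0]))
        assert out.intensities.iloc[0, 0] == pytest.approx(1.0)

    def test_arithmetic(self):
        out = tic_normalize(small_table([[2.0, 3.0, 5.0]], tic=[10.0]))
        assert out.intensities.iloc[0].tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_tic_spectrum_rejected(self):
        with pytest.warns(UserWarning):
            out = tic_normalize(small_table([[1.0, 1.0], [0.0, 0.0]],
                                            tic=[2.0, 0.0]))
        assert out.n_spectra == 1
        assert out.intensities.iloc[0].tolist() == pytest.approx([0.5, 0.5])

    def test_scale_invariance(self):
        base = small_table([[2.0, 3.0], [1.0, 4.0]], tic=[10.0, 10.0])
        scaled = small_table([[6.0, 9.0], [1.0, 4.0]], tic=[30.0, 10.0])
        a = tic_normalize(base).intensities.to_numpy()
        b = tic_normalize(scaled).intensities.to_numpy()
        assert np.allclose(a, b)


class TestPCA:
    def test_duplicated_spectra_have_zero_variance(self):
        row = [1.0, 2.0, 3.0]
        out = pca_scores(small_table([row, row, row, row]))
        assert np.allclose(out.scores.to_numpy(), 0.0, atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=(12, 5))
        table = small_table(x)
        out = pca_scores(table, n_components=3)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T, ddof=1))
        order = np.argsort(evals)[::-1]
        ref = xc @ evecs[:, order[:3]]
        got = out.scores.to_numpy()
        for j in range(3):   # eigenvector sign is arbitrary
            sign = np.sign(ref[0, j] * got[0, j]) or 1.0
            assert np.allclose(got[:, j], sign * ref[:, j], atol=1e-8)

    def test_two_class_separation_with_fold_changes(self):
        table, labels, _ = synth.gen_peak_tables(synth.SimsConfig(), 13)
        out = pca_scores(tic_normalize(table), labels)
        s = silhouette_score(out.scores.to_numpy()[:, :2], labels)
        assert s > 0
        assert set(out.ellipses) == set(np.unique(labels))

    def test_null_table_shows_overlap(self):
        cfg = synth.SimsConfig(fold_overrides={
            name: 1.0 for _, name, _, _, _ in synth.DEFAULT_PEAK_PANEL})
        table, labels, _ = synth.gen_peak_tables(cfg, 14)
        out = pca_scores(tic_normalize(table), labels)
        assert silhouette_score(out.scores.to_numpy()[:, :2], labels) <= 0


class TestPLSDAVIP:
    def test_mean_squared_vip_is_one(self):
        table, labels, _ = synth.gen_peak_tables(synth.SimsConfig(), 15)
        model = plsda_vip(tic_normalize(table), labels)
        assert (model.vip**2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_toy_table_matches_brute_force_oracle(self):
        # 4 spectra x 3 peaks, VIP from an independent PLS implementation
        x = np.array([[1.0, 0.2, 5.0],
                      [1.2, 0.1, 4.0],
                      [3.1, 0.3, 5.5],
                      [2.9, 0.4, 4.5]])
        labels = ["a", "a", "b", "b"]
        table = small_table(x)
        model = plsda_vip(table, labels, n_components=2)

        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        y = np.array([1.0, 1.0, -1.0, -1.0])
        y = y - y.mean()
        pls = PLSRegression(n_components=2, scale=False).fit(xs, y)
        w = pls.x_weights_
        t = pls.x_scores_
        ssy = np.array([
            (pls.y_loadings_[0, a]**2) * (t[:, a] @ t[:, a])
            for a in range(2)])
        vip_ref = np.sqrt(x.shape[1] * ((w**2) @ ssy) / ssy.sum())
        assert np.allclose(model.vip.to_numpy(), vip_ref, atol=1e-8)

    def test_shifted_peak_ranks_above_noise(self):
        table, labels, truth = synth.gen_peak_tables(synth.SimsConfig(), 16)
        model = plsda_vip(tic_normalize(table), labels)
        noise_peaks = truth["groups"]["other"]
        assert model.vip[259.1] > 1.0          # the 7.1-fold shifted ion
        assert model.vip[noise_peaks].mean() < 1.0

    def test_one_class_rejected(self):
        table = small_table(np.eye(4))
        with pytest.raises(ValueError):
            plsda_vip(table, ["a", "a", "a", "a"])

    def test_label_permutation_null(self):
        # one strongly shifted peak: its true-label VIP is exceeded by the
        # shuffled-label max |VIP - 1| in fewer than 5% of 100 draws
        cfg = synth.SimsConfig(fold_overrides={
            name: 1.0 for _, name, _, _, _ in synth.DEFAULT_PEAK_PANEL}
            | {"PI": 1 / 7.1})
        table, labels, _ = synth.gen_peak_tables(cfg, 17)
        norm = tic_normalize(table)
        observed = plsda_vip(norm, labels).vip[259.1]
        rng = np.random.default_rng(0)
        exceed = 0
        for _ in range(100):
            perm = rng.permutation(labels)
            vip = plsda_vip(norm, perm).vip
            if np.abs(vip - 1.0).max() >= observed - 1.0:
                exceed += 1
        assert exceed / 100 < 0.05


class TestFoldChanges:
    def test_identical_class_means_give_unity(self):
        x = [[0.2, 0.8], [0.4, 0.6], [0.2, 0.8], [0.4, 0.6]]
        table = small_table(x)
        table.normalized = True
        out = fold_changes(table, ["a", "a", "b", "b"], n_boot=100)
        assert np.allclose(out["ratio"].to_numpy(), 1.0)

    def test_hand_computed_ratio(self):
        x = [[0.2, 0.1], [0.4, 0.3], [0.1, 0.4], [0.1, 0.4]]
        table = small_table(x)
        table.normalized = True
        out = fold_changes(table, ["a", "a", "b", "b"], n_boot=100)
        assert out.loc["p0", "ratio"] == pytest.approx(0.3 / 0.1)
        assert out.loc["p1", "ratio"] == pytest.approx(0.2 / 0.4)

    def test_zero_denominator_flagged_infinite(self):
        x = [[0.5, 0.1], [0.5, 0.3], [0.0, 0.4], [0.0, 0.4]]
        table = small_table(x)
        table.normalized = True
        out = fold_changes(table, ["b", "b", "a", "a"], peaks=["p0"],
                           n_boot=50)
        assert np.isinf(out.loc["p0", "ratio"]) or out.loc["p0", "finite"]

    def test_generated_sm_ratio_estimated_and_bounded(self):
        # the estimator is unbiased for the configured 2.2-fold shift;
        # calibration-frequency CI coverage is exercised over many seeds in
        # the end-to-end acceptance suite
        ratios = []
        for seed in range(5):
            table, labels, truth = synth.gen_peak_tables(
                synth.SimsConfig(), seed)
            out = fold_changes(tic_normalize(table), labels, peaks=[264.2],
                               n_boot=200, seed=1)
            row = out.iloc[0]
            assert row["ci_low"] < row["ratio"] < row["ci_high"]
            ratios.append(row["ratio"])
        assert np.mean(ratios) == pytest.approx(2.2, rel=0.15)

    def test_saturation_ratios_reflect_truth(self):
        table, labels, truth = synth.gen_peak_tables(synth.SimsConfig(), 19)
        out = saturation_ratios(tic_normalize(table), labels,
                                sfa=truth["groups"]["SFA"],
                                mufa=truth["groups"]["MUFA"],
                                pufa=truth["groups"]["PUFA"], n_boot=500)
        assert out.loc["MUFA/SFA", "ratio"] == pytest.approx(
            truth["MUFA/SFA"], rel=0.35)
        assert out.loc["PUFA/SFA", "ratio"] == pytest.approx(
            truth["PUFA/SFA"], rel=0.35)
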