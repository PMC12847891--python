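"""PCA/ICA decomposition, orientation, pattern grouping, projection."""

import numpy as np
import pytest

from somnipeak.decompose import (FeatureMatrix, build_matrix, fit_ica,
                                 fit_pca, group_patterns, orient_components,
                                 project)
from somnipeak.socoupling import CoupledHistogram, default_freq_edges


def make_hist(values, subject):
    values = np.asarray(values, dtype=float)
    edges = default_freq_edges()
    return CoupledHistogram("power", edges, np.array([0, 25, 50, 75, 100.0]),
                            values, np.ones(4), subject=subject)


def random_hists(n_sub, seed=0, shape=(21, 4)):
    rng = np.random.default_rng(seed)
    return [make_hist(rng.random(shape), f"s{i}") for i in range(n_sub)]


class TestBuildMatrix:
    def test_shape_and_standardization(self):
        fm = build_matrix(random_hists(5))
        assert fm.data.shape == (5, 84)
        assert np.abs(fm.data.mean(axis=0)).max() < 1e-8
        assert np.abs(fm.data.std(axis=0) - 1.0).max() < 1e-6

    def test_constant_column_flagged(self):
        hists = random_hists(4, seed=1)
        for h in hists:
            h.values[0, 0] = 0.0
        fm = build_matrix(hists)
        assert fm.constant_cols[0]
        assert np.all(fm.data[:, 0] == 0.0)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            build_matrix(random_hists(2))


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(2)
        direction = rng.standard_normal(84)
        hists = [make_hist((w * direction + 1e-4 * rng.standard_normal(84)
                            ).reshape(21, 4), f"s{i}")
                 for i, w in enumerate(rng.standard_normal(10))]
        cs = fit_pca(build_matrix(hists), 5)
        assert cs.explained_var_ratio[0] > 0.99

    def test_matches_eigendecomposition(self):
        fm = build_matrix(random_hists(20, seed=3))
        cs = fit_pca(fm, 5)
        cov = np.cov(fm.data, rowvar=False)
        w, v = np.linalg.eigh(cov)
        top = v[:, np.argsort(w)[::-1][:5]].T
        dots = np.abs(np.sum(cs.loadings * top, axis=1))
        assert np.all(dots > 1 - 1e-6)

    def test_orthonormal_loadings_and_projection(self):
        fm = build_matrix(random_hists(12, seed=4))
        cs = fit_pca(fm, 6)
        gram = cs.loadings @ cs.loadings.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert np.allclose(cs.scores, fm.data @ cs.loadings.T, atol=1e-8)

    def test_explained_variance_sums_to_one(self):
        fm = build_matrix(random_hists(6, seed=5))
        with pytest.warns(UserWarning):
            cs = fit_pca(fm, 10)         # only n-1 = 5 available
        assert cs.n_components == 5
        assert cs.explained_var_ratio.sum() == pytest.approx(1.0, abs=1e-6)


class TestICA:
    def test_two_source_unmixing(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(-1, 1, size=(2, 2000))
        mix = np.array([[1.0, 0.6], [0.4, 1.0]])
        x = (mix @ s).T
        fm = FeatureMatrix((x - x.mean(0)) / x.std(0),
                           [str(i) for i in range(2000)],
                           x.mean(0), x.std(0), np.zeros(2, bool))
        cs = fit_ica(fm, 2, seed=0)
        assert cs.converged
        corr = np.corrcoef(np.c_[cs.scores, s.T], rowvar=False)[:2, 2:]
        best = np.abs(corr).max(axis=1)
        assert np.all(best > 0.95)

    def test_seeded_determinism(self):
        fm = build_matrix(random_hists(15, seed=7))
        a = fit_ica(fm, 3, seed=42)
        b = fit_ica(fm, 3, seed=42)
        assert np.array_equal(a.loadings, b.loadings)


class TestOrientation:
    @staticmethod
    def _setup():
        rng = np.random.default_rng(8)
        fm = build_matrix(random_hists(20, seed=8))
        cs = fit_pca(fm, 4)
        labels = ["control"] * 10 + ["p1"] * 5 + ["p2"] * 5
        return cs, labels

    def test_flip_rule(self):
        cs, labels = self._setup()
        # force component 0 so patients score below controls
        cs.scores[:, 0] = np.r_[np.ones(10), -np.ones(10)]
        out = orient_components(cs, labels)
        assert out.orientation_signs[0] == -1.0
        assert np.median(out.scores[10:, 0]) >= np.median(out.scores[:10, 0])

    def test_double_flip_identity(self):
        cs, labels = self._setup()
        once = orient_components(cs, labels)
        twice = orient_components(once, labels)
        assert np.array_equal(once.loadings, twice.loadings)

    def test_reconstruction_preserved(self):
        cs, labels = self._setup()
        out = orient_components(cs, labels)
        rec_before = cs.scores @ cs.loadings
        rec_after = out.scores @ out.loadings
        assert np.allclose(rec_before, rec_after, atol=1e-10)

    def test_pvalues_sign_invariant(self):
        from scipy.stats import mannwhitneyu

        cs, labels = self._setup()
        out = orient_components(cs, labels)
        labels = np.array(labels)
        for k in range(cs.n_components):
            p0 = mannwhitneyu(cs.scores[labels == "control", k],
                              cs.scores[labels == "p1", k],
                              alternative="two-sided").pvalue
            p1 = mannwhitneyu(out.scores[labels == "control", k],
                              out.scores[labels == "p1", k],
                              alternative="two-sided").pvalue
            assert p0 == pytest.approx(p1)


class TestPatternGrouping:
    @staticmethod
    def _sets_from_loadings(loadings_per_channel):
        sets = []
        for ch, L in loadings_per_channel.items():
            sets.append(type("CS", (), {})())
            cs = sets[-1]
            cs.channel, cs.condition, cs.method = ch, "NREM+REM", "PCA"
            cs.loadings = np.asarray(L)
            cs.n_components = cs.loadings.shape[0]
        return sets

    def test_identical_loadings_one_pattern(self):
        rng = np.random.default_rng(9)
        motif = rng.standard_normal(84)
        sets = self._sets_from_loadings({f"ch{i}": motif[None, :] for i in range(6)})
        cat = group_patterns(sets, threshold=0.7, prefix="Pow")
        assert cat.names[0] == "Pow1" and len(cat.members["Pow1"]) == 6

    def test_known_motifs_recovered(self):
        rng = np.random.default_rng(10)
        motifs = rng.standard_normal((3, 84))
        sets = self._sets_from_loadings({
            f"ch{i}": motifs + 0.05 * rng.standard_normal((3, 84))
            for i in range(6)})
        cat = group_patterns(sets, threshold=0.7, prefix="Pow")
        big = [n for n in cat.names if len(cat.members[n]) >= 5]
        assert len(big) == 3
        assert sum(len(cat.members[n]) for n in big) == 18

    def test_member_centroid_guarantee(self):
        rng = np.random.default_rng(11)
        sets = self._sets_from_loadings({
            f"ch{i}": rng.standard_normal((4, 40)) for i in range(4)})
        cat = group_patterns(sets, threshold=0.7)
        pooled = {(cs.channel, cs.condition, cs.method, k): cs.loadings[k]
                  for cs in sets for k in range(4)}
        for name in cat.names:
            c = cat.centroids[name]
            for key in cat.members[name]:
                r = np.corrcoef(pooled[key], c)[0, 1]
                assert abs(r) >= 0.7 - 1e-9


class TestProject:
    def test_training_subject_idempotent(self):
        hists = random_hists(8, seed=12)
        fm = build_matrix(hists)
        cs = fit_pca(fm, 4)
        score = project(hists[2], cs, fm)
        assert np.allclose(score, cs.scores[2], atol=1e-8)

    def test_zero_histogram_finite(self):
        hists = random_hists(8, seed=13)
        fm = build_matrix(hists)
        cs = fit_pca(fm, 4)
        zero = make_hist(np.zeros((21, 4)), "z")
        assert np.all(np.isfinite(project(zero, cs, fm)))

    def test_linearity_in_single_cell(self):
        hists = random_hists(8, seed=14)
        fm = build_matrix(hists)
        cs = fit_pca(fm, 4)
        base = make_hist(np.zeros((21, 4)), "t")
        bumped = make_hist(np.zeros((21, 4)), "t")
        bumped.values[3, 2] = 1.0
        delta = project(bumped, cs, fm) - project(base, cs, fm)
        cell = 3 * 4 + 2
        expected = cs.loadings[:, cell] / fm.col_sds[cell]
        assert np.allclose(delta, expected, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        hists = random_hists(8, seed=15)
        fm = build_matrix(hists)
        cs = fit_pca(fm, 4)
        bad = CoupledHistogram("power", default_freq_edges(2.0),
                               np.array([0, 50, 100.0]), np.zeros((10, 2)))
        with pytest.raises(ValueError):
            project(bad, cs, fm)
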