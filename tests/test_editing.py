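import numpy as np
import pytest
from sklearn.linear_model import Ridge

from epiedit import editing, models
from epiedit.editing import EditSpec, EditingError, GuideRNA
from epiedit.features import FeatureWindow
from epiedit.tracks_io import GeneRecord, HISTONE_MARKS

from conftest import make_track


def make_window(values=None, W=401, scale="normalized"):
    if values is None:
        values = np.zeros((6, W))
    return FeatureWindow("gX", "ctA", HISTONE_MARKS, values, scale=scale)


def monotone_model(weight=0.05, shape=(6, 401)):
    """Positive linear weight on every H3K27ac bin: monotone in H3K27ac."""
    coef = np.zeros(shape)
    coef[0] = weight
    ridge = Ridge(alpha=1.0)
    ridge.coef_ = coef.reshape(-1)
    ridge.intercept_ = 0.0
    ridge.n_features_in_ = coef.size
    return models.ExpressionModel("ridge", models.ModelConfig(), shape,
                                  frozenset(), _ridge=ridge)


GENE = GeneRecord("gX", "chr1", 100_000, "+", 110_000)


class TestScaleMnase:
    def test_all_zero_passes_through(self):
        t = make_track({"chr1": np.zeros(6)}, assay="MNase", scale="coverage")
        assert np.all(editing.scale_mnase(t).values["chr1"] == 0.0)

    def test_quantile_and_clip(self):
        t = make_track({"chr1": [1.0, 2.0, 3.0, 100.0]}, assay="MNase", scale="coverage")
        out = editing.scale_mnase(t, quantile=0.5)  # q over positives = 2.5
        assert np.allclose(out.values["chr1"], [0.4, 0.8, 1.0, 1.0])

    def test_value_at_quantile_maps_to_one(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 10, 500)
        t = make_track({"chr1": v}, assay="MNase", scale="coverage")
        out = editing.scale_mnase(t, quantile=0.99)
        q = np.quantile(v, 0.99)
        i = int(np.argmin(np.abs(v - q)))
        assert out.values["chr1"][i] == pytest.approx(min(v[i] / q, 1.0))
        assert out.values["chr1"].max() == 1.0

    def test_invalid_quantile(self):
        t = make_track({"chr1": np.ones(3)}, assay="MNase", scale="coverage")
        for q in (0.0, 1.5, -0.1):
            with pytest.raises(EditingError):
                editing.scale_mnase(t, quantile=q)


class TestDepositionProfile:
    def test_no_histones_no_deposition(self):
        add = editing.deposition_profile(np.zeros(9), 4, EditSpec(lam=1000.0))
        assert np.all(add == 0.0)

    def test_value_at_guide_site(self):
        # at i=j: lam * exp(-5*m_j) * 1 * m_i = 1000 * e^-1 * 0.2
        m = np.full(9, 0.2)
        add = editing.deposition_profile(m, 4, EditSpec(lam=1000.0, sigma_bp=500.0))
        assert add[4] == pytest.approx(1000.0 * np.exp(-1.0) * 0.2)

    def test_symmetry(self):
        m = np.array([0.1, 0.3, 0.5, 0.3, 0.1])
        add = editing.deposition_profile(m, 2, EditSpec(lam=100.0, sigma_bp=100.0))
        assert np.allclose(add, add[::-1])

    def test_sigma_limits(self):
        """Kernel collapses onto the guide bin as sigma -> 0 and flattens to
        lam * exp(-c*m_j) * m as sigma -> infinity."""
        rng = np.random.default_rng(1)
        m = rng.uniform(0.1, 1.0, 21)
        j = 10
        tiny = editing.deposition_profile(m, j, EditSpec(lam=50.0, sigma_bp=1e-3))
        assert tiny[j] == pytest.approx(50.0 * np.exp(-5 * m[j]) * m[j])
        assert np.all(tiny[np.arange(21) != j] < 1e-10)
        flat = editing.deposition_profile(m, j, EditSpec(lam=50.0, sigma_bp=1e9))
        assert np.allclose(flat, 50.0 * np.exp(-5 * m[j]) * m, rtol=1e-6)

    def test_guide_outside_window(self):
        with pytest.raises(EditingError, match="outside"):
            editing.deposition_profile(np.ones(5), 7, EditSpec())

    def test_invalid_sigma(self):
        with pytest.raises(EditingError, match="sigma"):
            EditSpec(sigma_bp=0.0)


class TestApplyEdit:
    def test_lambda_zero_is_identity(self):
        rng = np.random.default_rng(2)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        out = editing.apply_edit(win, np.full(401, 0.5), 200, EditSpec(lam=0.0))
        assert np.array_equal(out.values, win.values)

    def test_deposition_nonnegative(self):
        rng = np.random.default_rng(3)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        m = rng.uniform(0, 1, 401)
        out = editing.apply_edit(win, m, 123, EditSpec(lam=700.0))
        assert np.all(out.values >= win.values - 1e-12)
        assert np.all(out.values[1:] == win.values[1:])  # only H3K27ac changes

    def test_matches_hand_computed_nine_bin_window(self):
        """Independent oracle: direct elementwise evaluation of the model
        lam * exp(-c*m_j) * exp(-(d_bp)^2/(2 sigma^2)) * m_i on 9 bins."""
        m = np.array([0.0, 0.2, 0.5, 1.0, 0.8, 0.4, 0.1, 0.0, 0.3])
        vals = np.tile(np.arange(9.0), (6, 1))
        win = FeatureWindow("gX", "ctA", HISTONE_MARKS, vals, scale="normalized")
        spec = EditSpec(sigma_bp=50.0, lam=200.0, steric_coefficient=5.0)
        j = 3
        out = editing.apply_edit(win, m, j, spec)
        expected = vals[0].copy()
        for i in range(9):
            d_bp = (i - j) * 25.0
            expected[i] += (200.0 * np.exp(-5.0 * m[j])
                            * np.exp(-d_bp ** 2 / (2 * 50.0 ** 2)) * m[i])
        assert np.allclose(out.values[0], expected)

    def test_misaligned_mnase_window(self):
        win = make_window()
        with pytest.raises(EditingError, match="misaligned"):
            editing.apply_edit(win, np.ones(100), 50, EditSpec())


class TestGuideWindowBin:
    def test_plus_strand_offset(self):
        g = GuideRNA("q", "gX", GENE.tss + 250)
        assert editing.guide_window_bin(GENE, g, 401) == 200 + 10

    def test_minus_strand_flips(self):
        gene = GeneRecord("gY", "chr1", 100_000, "-", 90_000)
        g = GuideRNA("q", "gY", gene.tss - 250)  # downstream for minus strand
        assert editing.guide_window_bin(gene, g, 401) == 200 + 10

    def test_outside_window_rejected(self):
        g = GuideRNA("q", "gX", GENE.tss + 10_000)
        with pytest.raises(EditingError, match="outside"):
            editing.guide_window_bin(GENE, g, 401)


class TestPredictFoldChange:
    def test_lambda_zero_fc_exactly_one(self):
        m = monotone_model()
        rng = np.random.default_rng(4)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        res = editing.predict_edit_fold_change(
            [m], GENE, win, np.full(401, 0.5), GuideRNA("q", "gX", GENE.tss),
            EditSpec(lam=0.0))
        assert res.predicted_fc == 1.0

    def test_no_histones_fc_exactly_one(self):
        m = monotone_model()
        rng = np.random.default_rng(5)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        res = editing.predict_edit_fold_change(
            [m], GENE, win, np.zeros(401), GuideRNA("q", "gX", GENE.tss),
            EditSpec(lam=1000.0))
        assert res.predicted_fc == 1.0

    def test_monotone_model_fc_above_one(self):
        m = monotone_model()
        rng = np.random.default_rng(6)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        res = editing.predict_edit_fold_change(
            [m], GENE, win, np.full(401, 0.5), GuideRNA("q", "gX", GENE.tss),
            EditSpec(lam=1000.0))
        assert res.predicted_fc > 1.0

    def test_occluded_guide_smaller_fc(self):
        m = monotone_model()
        rng = np.random.default_rng(7)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        base = np.full(401, 0.5)
        m_occ, m_acc = base.copy(), base.copy()
        m_occ[200], m_acc[200] = 1.0, 0.0
        guide = GuideRNA("q", "gX", GENE.tss)
        spec = EditSpec(lam=1000.0)
        fc_occ = editing.predict_edit_fold_change([m], GENE, win, m_occ, guide, spec).predicted_fc
        fc_acc = editing.predict_edit_fold_change([m], GENE, win, m_acc, guide, spec).predicted_fc
        assert fc_occ < fc_acc

    def test_fc_monotone_in_lambda(self):
        m = monotone_model()
        rng = np.random.default_rng(8)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        guide = GuideRNA("q", "gX", GENE.tss)
        fcs = [editing.predict_edit_fold_change(
            [m], GENE, win, np.full(401, 0.5), guide, EditSpec(lam=lam)).predicted_fc
            for lam in (0.0, 10.0, 100.0, 1000.0)]
        assert all(a <= b for a, b in zip(fcs, fcs[1:]))

    def test_fc_invariant_to_prediction_offset(self):
        rng = np.random.default_rng(9)
        win = make_window(rng.uniform(0, 5, (6, 401)))
        guide = GuideRNA("q", "gX", GENE.tss)
        spec = EditSpec(lam=500.0)
        mvec = np.full(401, 0.5)
        fc0 = editing.predict_edit_fold_change(
            [monotone_model()], GENE, win, mvec, guide, spec).predicted_fc
        shifted = monotone_model()
        shifted._ridge.intercept_ = 12.5
        fc1 = editing.predict_edit_fold_change(
            [shifted], GENE, win, mvec, guide, spec).predicted_fc
        assert fc0 == pytest.approx(fc1, rel=1e-12)

    def test_training_gene_rejected(self):
        m = monotone_model()
        m.training_genes = frozenset({"gX"})
        win = make_window()
        with pytest.raises(EditingError, match="training"):
            editing.predict_edit_fold_change(
                [m], GENE, win, np.zeros(401), GuideRNA("q", "gX", GENE.tss), EditSpec())


class TestRankConcordance:
    def res(self, gid, pred, meas):
        return editing.EditResult(f"q{gid}{pred}", gid, pred, EditSpec(), measured_fc=meas)

    def test_perfect_agreement(self):
        rs = [self.res("a", 1.1, 3.0), self.res("b", 1.5, 10.0), self.res("c", 9.0, 6500.0)]
        assert editing.rank_concordance(rs, "inter_gene") == 1.0

    def test_anti_ordered(self):
        rs = [self.res("a", 9.0, 3.0), self.res("b", 1.5, 10.0), self.res("c", 1.1, 6500.0)]
        assert editing.rank_concordance(rs, "inter_gene") == -1.0

    def test_inter_gene_uses_max_per_gene(self):
        rs = [self.res("a", 1.1, 2.0), self.res("a", 5.0, 100.0),
              self.res("b", 2.0, 50.0), self.res("b", 1.0, 3.0),
              self.res("c", 9.0, 600.0)]
        # per-gene maxima: a (5, 100), b (2, 50), c (9, 600) -> rho = 1
        assert editing.rank_concordance(rs, "inter_gene") == 1.0

    def test_intra_gene_per_gene_rhos(self):
        rs = [self.res("a", 1.0, 2.0), self.res("a", 2.0, 5.0), self.res("a", 3.0, 9.0),
              self.res("b", 3.0, 2.0), self.res("b", 2.0, 5.0), self.res("b", 1.0, 9.0)]
        out = editing.rank_concordance(rs, "intra_gene")
        assert out == {"a": 1.0, "b": -1.0}

    def test_too_few_points(self):
        rs = [self.res("a", 1.0, 2.0), self.res("b", 2.0, 3.0)]
        with pytest.raises(EditingError, match="3"):
            editing.rank_concordance(rs, "inter_gene")
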