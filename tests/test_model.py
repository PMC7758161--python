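"""Joint fitting, standard errors, the self-renewal statistic, F test, AICc."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

import memokin as mk
from memokin.exceptions import ConvergenceWarning, DomainError
from memokin.model import TurnoverResults


def _fake_result(rss, n, k):
    """Minimal results object for testing the comparison statistics."""
    import pandas as pd

    return TurnoverResults(
        model=None, variant="full",
        params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        cov_params=pd.DataFrame(), rss=rss, nobs=n, k_params=k,
        success=True, pinned=[], telomere_used=True,
    )


class TestFitConfig:
    def test_from_yaml_merges_partial_bounds(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "bw: 4.0\nn_global: 100\n"
            "telomere: {epsilon: 30.0, K: 2.0}\n"
            "bounds: {mR: [0.0, 0.1]}\n"
        )
        cfg = mk.FitConfig.from_yaml(path)
        assert cfg.bw == 4.0 and cfg.n_global == 100
        assert cfg.telomere.epsilon == 30.0 and cfg.telomere.K == 2.0
        assert cfg.bounds["mR"] == (0.0, 0.1)
        assert cfg.bounds["p1"] == (0.0, 0.20)  # untouched default

    def test_invalid_bounds_rejected(self):
        with pytest.raises(DomainError):
            mk.FitConfig(bounds={"p1": (0.2, 0.1)})


class TestJointResiduals:
    def test_zero_at_generating_parameters(self, cd4_truth, noisefree_fit):
        model, _ = noisefree_fit
        res = model.joint_residuals(cd4_truth.kinetics)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_length_is_label_points_plus_one(self, noisefree_fit):
        model, _ = noisefree_fit
        res = model.joint_residuals(
            mk.KineticParameters(p1=0.01, z1s=0.01, p2=0.01, z2s=0.01, mR=0.01)
        )
        assert res.size == 2 * 8 + 1

    def test_label_part_invariant_to_joint_rescaling(self, cd4_truth,
                                                     noisefree_dataset):
        """Doubling observed enrichments together with the predictions
        (via the amplification factor) leaves normalized residuals as-is."""
        curve = cd4_truth.curve
        params = dataclasses.replace(cd4_truth.kinetics, p2=0.004)  # off-truth
        model1 = mk.TurnoverModel(noisefree_dataset, curve)
        doubled = dataclasses.replace(
            noisefree_dataset,
            labels={
                s: mk.LabelSeries(s, ls.days, 2.0 * ls.enrichment)
                for s, ls in noisefree_dataset.labels.items()
            },
        )
        model2 = mk.TurnoverModel(doubled, curve)
        r1 = model1.joint_residuals(params)[:-1]
        r2 = model2.joint_residuals(
            dataclasses.replace(params, bw=2 * params.bw)
        )[:-1]
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_label_only_when_telomere_missing(self, cd4_truth, noisefree_dataset):
        bare = dataclasses.replace(noisefree_dataset, telomeres=None)
        model = mk.TurnoverModel(bare, cd4_truth.curve)
        assert not model.telomere_used
        assert model.joint_residuals(cd4_truth.kinetics).size == 16


class TestFit:
    def test_same_seed_is_bit_identical(self, noisefree_fit):
        model, first = noisefree_fit
        second = model.fit()
        assert (first.params == second.params).all()
        assert first.rss == second.rss

    def test_true_p2_zero_recovered_as_zero(self, cd4_truth, noisefree_design):
        truth0 = mk.default_true_parameters("CD4", p2=0.0)
        ds = mk.generate_volunteer(truth0, noisefree_design, seed=2)
        model = mk.TurnoverModel(ds, truth0.curve)
        res = model.fit()
        assert res.params["p2"] < 1e-4

    def test_label_only_fit_flagged(self, cd4_truth, noisefree_dataset):
        bare = dataclasses.replace(noisefree_dataset, telomeres=None)
        res = mk.TurnoverModel(bare, cd4_truth.curve).fit()
        assert not res.telomere_used
        assert res.nobs == 16

    def test_summary_reports_percent_per_day(self, noisefree_fit):
        _, res = noisefree_fit
        text = res.summary()
        assert "%/day" in text and "Self-renewal" in text
        assert "0.53" in text  # p1 median truth in % per day

    def test_predict_returns_trajectories(self, noisefree_fit):
        _, res = noisefree_fit
        pred = res.predict(np.array([7.0, 49.0, 126.0]))
        assert list(pred.columns) == ["day", "L1", "L2"]
        assert (pred[["L1", "L2"]] >= 0).all().all()


class TestStandardErrors:
    def test_zero_residual_data_gives_near_zero_ses(self, noisefree_fit):
        _, res = noisefree_fit
        assert (res.bse.dropna() < 1e-6).all()

    @pytest.mark.parametrize("method", ["pooled", "robust"])
    def test_duplicating_observations_shrinks_ses_about_root_two(
        self, method, cd4_truth
    ):
        design = mk.StudyDesign()
        ds = mk.generate_volunteer(cd4_truth, design, seed=5)
        dup = dataclasses.replace(
            ds,
            labels={
                s: mk.LabelSeries(
                    s, np.repeat(ls.days, 2) + np.tile([0.0, 1e-9], len(ls)),
                    np.repeat(ls.enrichment, 2),
                )
                for s, ls in ds.labels.items()
            },
            telomeres={
                s: mk.TelomereObservation(s, lengths=np.repeat(t.lengths, 2))
                for s, t in ds.telomeres.items()
            },
        )
        m1 = mk.TurnoverModel(ds, cd4_truth.curve)
        m2 = mk.TurnoverModel(dup, cd4_truth.curve)
        at = m1.fit().kinetic_parameters  # evaluate both at the optimum
        se1 = m1.asymptotic_standard_errors(at, method=method)
        se2 = m2.asymptotic_standard_errors(at, method=method)
        ratio = (se1 / se2).median()
        assert 1.2 < ratio < 1.8

    def test_deficient_design_not_determined(self, cd4_truth):
        days = np.array([7.0, 49.0])
        traj = mk.label_fraction_trajectories(
            cd4_truth.kinetics, cd4_truth.curve, days
        )
        ds = mk.VolunteerDataset(
            "V1", "CD4", saliva=None,
            labels={
                "CD57neg": mk.LabelSeries("CD57neg", days, traj.L1),
                "CD57pos": mk.LabelSeries("CD57pos", days, traj.L2),
            },
            telomeres={
                "CD57neg": mk.TelomereObservation("CD57neg", lengths=[5000.0]),
                "CD57pos": mk.TelomereObservation("CD57pos", lengths=[4700.0]),
            },
        )
        model = mk.TurnoverModel(ds, cd4_truth.curve)
        se = model.asymptotic_standard_errors(cd4_truth.kinetics)
        assert se.isna().all()  # n = 5 observations <= k = 5 parameters


class TestSelfRenewal:
    def test_published_row_rounds_to_97(self):
        assert round(mk.self_renewal_percentage(0.59, 0.02)) == 97

    def test_no_conversion_means_all_self_renewal(self):
        assert mk.self_renewal_percentage(0.53, 0.0) == 100.0

    def test_no_proliferation_means_none(self):
        assert mk.self_renewal_percentage(0.0, 0.02) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(DomainError):
            mk.self_renewal_percentage(0.0, 0.0)


class TestFTest:
    def test_equal_rss_gives_f_zero_p_one(self):
        comp = mk.f_test_nested(_fake_result(1.0, 17, 4), _fake_result(1.0, 17, 5))
        assert comp.F == 0.0 and comp.p_value == 1.0

    def test_reference_distribution_value(self):
        comp = mk.f_test_nested(_fake_result(2.0, 17, 4), _fake_result(1.0, 17, 5))
        assert comp.F == pytest.approx(12.0)
        assert comp.p_value == pytest.approx(
            float(scipy.stats.f.sf(12.0, 1, 12)), rel=1e-12
        )
        assert comp.p_value == pytest.approx(0.0047, abs=5e-4)

    def test_rss_inversion_clipped_with_warning(self):
        with pytest.warns(ConvergenceWarning):
            comp = mk.f_test_nested(
                _fake_result(0.9, 17, 4), _fake_result(1.0, 17, 5)
            )
        assert comp.F == 0.0 and comp.p_value == 1.0

    def test_requires_single_parameter_difference(self):
        with pytest.raises(DomainError):
            mk.f_test_nested(_fake_result(2.0, 17, 3), _fake_result(1.0, 17, 5))


class TestAicc:
    def test_formula_against_direct_evaluation(self):
        rss, n, k = 1.7, 17, 5
        direct = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert mk.aicc(rss, n, k) == pytest.approx(direct, rel=1e-12)

    def test_equal_fits_prefer_simpler_model(self):
        delta = mk.compare_aicc(_fake_result(1.0, 17, 4), _fake_result(1.0, 17, 5))
        expected = (8 + 40 / 12) - (10 + 60 / 11)
        assert delta == pytest.approx(expected, rel=1e-12)
        assert delta < 0

    def test_headline_difference_from_rss_ratio(self):
        """With equal k the AICc difference is n ln(RSS0/RSS1): an RSS
        ratio of exp(106/n) reproduces a difference of 106."""
        n = 17
        rss1 = 1.0
        rss0 = rss1 * np.exp(106.0 / n)
        delta = mk.aicc(rss0, n, 5) - mk.aicc(rss1, n, 5)
        assert delta == pytest.approx(106.0, rel=1e-12)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(DomainError):
            mk.aicc(1.0, 6, 5)

    def test_equal_rss_equal_k_gives_zero(self):
        assert mk.compare_aicc(
            _fake_result(2.0, 17, 5), _fake_result(2.0, 17, 5)
        ) == 0.0
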