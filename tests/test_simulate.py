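import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from cindexlab.roc import auc_rank_oracle, compute_roc
from cindexlab.simulate import (
    FitDomainError,
    GROUPS,
    default_config,
    fit_lognormal_moments,
    fit_lognormal_quantiles,
    fit_report,
    lognormal_auc,
    sample_cohort,
    sample_group_values,
    dump_config,
    load_config,
)
from cindexlab.cohort import BIOMARKERS


class TestMomentFit:
    def test_standard_lognormal_recovered(self):
        # analytic mean/SD of a (mu=0, sigma=1) lognormal
        mean = math.exp(0.5)
        sd = math.sqrt((math.e - 1) * math.e)
        p = fit_lognormal_moments(mean, sd)
        assert p.mu == pytest.approx(0.0, abs=1e-12)
        assert p.sigma == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_against_numerical_integration(self):
        p = fit_lognormal_moments(1.21, 2.15)
        assert p.mu == pytest.approx(-0.5219, abs=5e-4)
        assert p.sigma == pytest.approx(1.1937, abs=5e-4)
        # independent check: integrate the fitted density's moments
        m1, _ = integrate.quad(lambda x: x * p.pdf(x), 0, np.inf)
        m2, _ = integrate.quad(lambda x: x * x * p.pdf(x), 0, np.inf)
        assert m1 == pytest.approx(1.21, rel=1e-8)
        assert math.sqrt(m2 - m1**2) == pytest.approx(2.15, rel=1e-6)

    @pytest.mark.parametrize("mean,sd", [(1.0, 0.0), (0.0, 1.0), (-2.0, 1.0)])
    def test_degenerate_targets_rejected(self, mean, sd):
        with pytest.raises(FitDomainError):
            fit_lognormal_moments(mean, sd)

    @settings(max_examples=200, deadline=None)
    @given(
        mean=st.floats(min_value=1e-3, max_value=1e6),
        ratio=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_round_trip(self, mean, ratio):
        """Fitted params reproduce the target mean and SD to 1e-9 relative."""
        sd = mean * ratio
        p = fit_lognormal_moments(mean, sd)
        assert p.mean == pytest.approx(mean, rel=1e-9)
        assert p.sd == pytest.approx(sd, rel=1e-9)


class TestQuantileFit:
    def test_q3_fit_closed_form(self):
        p = fit_lognormal_quantiles(189.0, 384.0, "Q3")
        assert p.mu == pytest.approx(5.2417, abs=5e-4)
        assert p.sigma == pytest.approx(1.0511, abs=5e-4)
        # independent check via the fitted quantile function
        assert p.quantile(0.5) == pytest.approx(189.0, rel=1e-9)
        assert p.quantile(0.75) == pytest.approx(384.0, rel=1e-9)

    def test_log_symmetric_q1_gives_same_sigma(self):
        q3 = fit_lognormal_quantiles(189.0, 384.0, "Q3")
        q1 = fit_lognormal_quantiles(189.0, 189.0**2 / 384.0, "Q1")
        assert q1.sigma == pytest.approx(q3.sigma, rel=1e-12)
        assert q1.quantile(0.25) == pytest.approx(189.0**2 / 384.0, rel=1e-9)

    @pytest.mark.parametrize(
        "median,quartile,which",
        [(189.0, 189.0, "Q3"), (189.0, 90.0, "Q3"), (189.0, 200.0, "Q1")],
    )
    def test_degenerate_or_wrong_side_rejected(self, median, quartile, which):
        with pytest.raises(FitDomainError):
            fit_lognormal_quantiles(median, quartile, which)

    @settings(max_examples=200, deadline=None)
    @given(
        median=st.floats(min_value=1e-3, max_value=1e6),
        ratio=st.floats(min_value=1.001, max_value=100.0),
    )
    def test_round_trip(self, median, ratio):
        p = fit_lognormal_quantiles(median, median * ratio, "Q3")
        assert p.quantile(0.5) == pytest.approx(median, rel=1e-9)
        assert p.quantile(0.75) == pytest.approx(median * ratio, rel=1e-9)


class TestDefaultConfig:
    def test_group_sizes_and_spec_coverage(self):
        cfg = default_config(seed=7)
        assert cfg.n_infection == 11
        assert cfg.n_no_infection == 40
        assert len(cfg.specs) == 6
        assert {(s.biomarker, s.group) for s in cfg.specs} == {
            (b, g) for b in BIOMARKERS for g in GROUPS
        }

    def test_fit_methods(self):
        cfg = default_config(seed=0)
        for s in cfg.specs:
            expected = (
                "quantiles"
                if (s.biomarker, s.group) == ("il6", "infection")
                else "moments"
            )
            assert s.fit_method == expected

    def test_moment_cells_match_their_targets(self):
        cfg = default_config(seed=0)
        for s in cfg.specs:
            if s.fit_method == "moments":
                assert s.params.mean == pytest.approx(s.target_summary.mean, rel=1e-9)
                assert s.params.sd == pytest.approx(s.target_summary.sd, rel=1e-9)

    def test_il6_infection_quantile_fit_implies_printed_mean(self):
        """The (median, Q1) fit's analytic mean lands within 2% of the
        printed mean — evidence the corrupted SD cell is the typo."""
        cfg = default_config(seed=0)
        spec = cfg.spec("il6", "infection")
        assert spec.params.median == pytest.approx(189.0, rel=1e-9)
        assert spec.params.quantile(0.25) == pytest.approx(93.45, rel=1e-9)
        assert spec.params.mean == pytest.approx(325.81, rel=0.02)

    def test_config_round_trips_through_json(self, tmp_path):
        cfg = default_config(seed=11)
        path = tmp_path / "config.json"
        dump_config(cfg, path)
        back = load_config(path)
        assert back == cfg


class TestSampling:
    def test_cohort_structure_and_determinism(self):
        cfg = default_config(seed=42)
        a = sample_cohort(cfg)
        b = sample_cohort(cfg)
        assert len(a) == 51
        assert a.n_infection() == 11
        assert a.episodes == b.episodes
        assert [ep.episode_id for ep in a][:2] == ["sim-0001", "sim-0002"]

    def test_different_seeds_differ(self):
        a = sample_cohort(default_config(seed=1))
        b = sample_cohort(default_config(seed=2))
        assert a.episodes != b.episodes

    def test_empirical_means_within_three_standard_errors(self):
        cfg = default_config(seed=2024)
        n = 100_000
        for s in cfg.specs:
            draws = sample_group_values(cfg, s.biomarker, s.group, n=n)
            se = s.params.sd / math.sqrt(n)
            assert abs(draws.mean() - s.params.mean) < 3 * se, (
                s.biomarker, s.group,
            )

    def test_large_sample_auc_matches_lognormal_closed_form(self):
        """Empirical AUC at n=1e5/group agrees with
        Phi((mu1-mu0)/sqrt(s0^2+s1^2)) within 0.01 for every marker."""
        cfg = default_config(seed=99)
        n = 100_000
        for b in BIOMARKERS:
            neg = sample_group_values(cfg, b, "no_infection", n=n)
            pos = sample_group_values(cfg, b, "infection", n=n)
            scores = np.concatenate([neg, pos])
            labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])
            emp = compute_roc(scores, labels).auc
            closed = lognormal_auc(
                cfg.spec(b, "no_infection").params,
                cfg.spec(b, "infection").params,
            )
            assert abs(emp - closed) < 0.01, b


def test_fit_report_flags_inconsistent_pct_cell():
    report = fit_report(default_config(seed=5))
    notes = {
        (c["biomarker"], c["group"]): c["note"] for c in report["cells"]
    }
    assert "inconsistent" in notes[("pct", "infection")]
    assert "median/Q1" in notes[("il6", "infection")] or "Q1" in notes[("il6", "infection")]
    assert notes[("crp", "no_infection")] == ""
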