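"""Exposure x effects convolution and remediation arithmetic."""

import math

import numpy as np
import pytest

import sedrisk as sr
from sedrisk.distributions import (
    BurrIIIParams,
    FittedDistribution,
    LogNormalParams,
    lognormal_mle,
)
from sedrisk.risk import (
    fraction_affected,
    required_reduction_for_risk,
    required_reduction_to_target,
    species_affected,
)

from conftest import make_toxicity


def _dist(family, params):
    return FittedDistribution(family, params, 0, 0.0)


class TestFractionAffected:
    @pytest.mark.parametrize(
        "family,params",
        [("lognormal", LogNormalParams(1.0, 0.5)),
         ("burr3", BurrIIIParams(5.0, 1.8, 1.2))],
    )
    def test_identity_gives_half(self, family, params):
        d = _dist(family, params)
        assert fraction_affected(d, d) == pytest.approx(0.5, abs=1e-6)

    def test_separation_limit(self):
        ssd = _dist("lognormal", LogNormalParams(math.log(100), 0.3))
        low = ssd.quantile(0.001) * 1e-5
        pdd = _dist("lognormal", LogNormalParams(math.log(low), 0.2))
        assert fraction_affected(pdd, ssd) < 0.001

    def test_monte_carlo_oracle_single_pair(self):
        pdd = _dist("lognormal", LogNormalParams(0.3, 0.7))
        ssd = _dist("burr3", BurrIIIParams(3.0, 1.5, 0.9))
        val = fraction_affected(pdd, ssd)
        n = 10**5
        draws = pdd.sample(n, np.random.default_rng(21))
        mc = np.asarray(ssd.cdf(draws))
        se = mc.std() / math.sqrt(n)
        assert val == pytest.approx(float(mc.mean()), abs=3 * se + 1e-9)

    def test_monotone_under_upward_scaling(self):
        pdd = _dist("lognormal", LogNormalParams(0.0, 0.6))
        ssd = _dist("burr3", BurrIIIParams(10.0, 1.8, 1.2))
        vals = [fraction_affected(pdd.scaled(s), ssd) for s in (0.2, 0.5, 1, 2, 5)]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_unit_mismatch_rejected(self):
        a = _dist("lognormal", LogNormalParams(0.0, 0.5))
        b = FittedDistribution("lognormal", LogNormalParams(0.0, 0.5), 0, 0.0,
                               unit="ng/g")
        with pytest.raises(ValueError):
            fraction_affected(a, b)


class TestSpeciesAffected:
    def test_identity_case_near_half(self):
        # exposure and toxicity drawn from the same law: ~50% affected
        rng = np.random.default_rng(101)
        mu, sigma = math.log(5), 0.8
        exposure = np.exp(mu + sigma * rng.standard_normal(200))
        tox = make_toxicity(np.exp(mu + sigma * rng.standard_normal(100)))
        r = species_affected(exposure, tox, confidence_percent=50,
                             ssd_family="lognormal", pdd_family="lognormal")
        assert r.percent_affected == pytest.approx(50, abs=12)

    def test_far_separated_exposure_near_zero(self):
        rng = np.random.default_rng(102)
        exposure = np.exp(math.log(1e-4) + 0.3 * rng.standard_normal(50))
        tox = make_toxicity(np.exp(math.log(100) + 0.5 * rng.standard_normal(40)))
        r = species_affected(exposure, tox, confidence_percent=50,
                             ssd_family="lognormal", pdd_family="lognormal")
        assert r.percent_affected < 1.0

    def test_confidence_reported_above_point(self):
        rng = np.random.default_rng(103)
        exposure = np.exp(0.5 * rng.standard_normal(20))
        tox = make_toxicity(np.exp(math.log(3) + 0.8 * rng.standard_normal(30)))
        r = species_affected(exposure, tox, confidence_percent=95, n_boot=200,
                             seed=4, ssd_family="lognormal",
                             pdd_family="lognormal")
        assert 0 <= r.percent_affected <= 100
        assert r.method == "quadrature+bootstrap"


class TestRequiredReductionToTarget:
    def test_survey_consistency_cases(self, wami):
        # medians from the packaged survey vs published target concentrations
        s = sr.element_summary(wami)
        cd = required_reduction_to_target(s.median("Cd") * 1000, 0.8)  # ng/g
        pb = required_reduction_to_target(s.median("Pb") * 1000, 46.2)
        as_ = required_reduction_to_target(s.median("As") * 1000, 1618.7)
        assert f"{cd:.1f}" == "99.8"
        assert f"{pb:.1f}" == "99.8"
        assert as_ == 0.0

    def test_target_equal_to_median(self):
        assert required_reduction_to_target(5.0, 5.0) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            required_reduction_to_target(0.0, 1.0)
        with pytest.raises(ValueError):
            required_reduction_to_target(1.0, -1.0)


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(77)
    exposure = np.exp(math.log(30) + 0.5 * rng.standard_normal(20))
    tox = make_toxicity(np.exp(math.log(2) + 0.9 * rng.standard_normal(30)))
    return exposure, tox


class TestRequiredReductionForRisk:
    def test_already_compliant(self):
        rng = np.random.default_rng(78)
        exposure = np.exp(math.log(1e-3) + 0.3 * rng.standard_normal(20))
        tox = make_toxicity(np.exp(math.log(50) + 0.8 * rng.standard_normal(30)))
        r = required_reduction_for_risk(exposure, tox, 5, confidence_percent=50,
                                        ssd_family="lognormal",
                                        pdd_family="lognormal")
        assert r.nil and r.median_target == pytest.approx(float(np.median(exposure)))

    def test_bisection_matches_grid_scan_oracle(self, pair):
        exposure, tox = pair
        max_affected = 10.0
        r = required_reduction_for_risk(exposure, tox, max_affected,
                                        confidence_percent=50,
                                        ssd_family="lognormal",
                                        pdd_family="lognormal")
        # brute force: largest s on a 10^4 grid meeting the criterion
        pdd = lognormal_mle(exposure)
        ssd = sr.fit_ssd(tox, family="lognormal")
        grid = np.linspace(1e-4, 1.0, 10**4)
        ok = [s for s in grid
              if 100 * fraction_affected(pdd.scaled(s), ssd) <= max_affected]
        s_oracle = max(ok)
        s_found = 1.0 - r.required_reduction_percent / 100.0
        assert s_found == pytest.approx(s_oracle, abs=2.5e-4)
        # the returned scale satisfies the criterion when recomputed
        assert 100 * fraction_affected(pdd.scaled(s_found), ssd) <= max_affected + 1e-9

    def test_tightening_criterion_monotone(self, pair):
        exposure, tox = pair
        results = [
            required_reduction_for_risk(exposure, tox, n, confidence_percent=50,
                                        ssd_family="lognormal",
                                        pdd_family="lognormal")
            for n in (25, 10, 5)
        ]
        reds = [r.required_reduction_percent for r in results]
        targets = [r.median_target for r in results]
        assert reds[0] <= reds[1] <= reds[2]
        assert targets[0] >= targets[1] >= targets[2]
        # % affected reported identically regardless of the protection level
        assert len({round(r.percent_affected, 9) for r in results}) == 1

    def test_agrees_with_target_mode_on_constructed_case(self, pair):
        # pick the criterion that exactly corresponds to a known scale s0:
        # mode "risk" then recovers s0, and mode "target" applied to the
        # implied target returns the same reduction
        exposure, tox = pair
        pdd = lognormal_mle(exposure)
        ssd = sr.fit_ssd(tox, family="lognormal")
        s0 = 0.37
        criterion = 100 * fraction_affected(pdd.scaled(s0), ssd)
        r = required_reduction_for_risk(exposure, tox, criterion,
                                        confidence_percent=50,
                                        ssd_family="lognormal",
                                        pdd_family="lognormal")
        med = float(np.median(exposure))
        via_target = required_reduction_to_target(med, s0 * med)
        assert r.required_reduction_percent == pytest.approx(via_target, abs=0.05)

    def test_invalid_criterion(self, pair):
        exposure, tox = pair
        with pytest.raises(ValueError):
            required_reduction_for_risk(exposure, tox, 0.0)
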