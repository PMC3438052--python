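"""Proximity enrichment, calibration arithmetic, exact intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from ashmscreen.enrichment import (
    bonferroni_threshold,
    composite_proximity_filter,
    enrichment_test,
    posterior_odds,
    proportion_ci,
    proximity_fraction,
)

REGIONS = pd.DataFrame({
    "chrom": ["chrS", "chrS"], "start": [50_000, 200_000],
    "end": [60_000, 210_000], "label": ["r1", "r2"],
    "track": ["imprinted"] * 2})


def _sites(positions, chrom="chrS"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestProximity:
    def test_boundary_distance_inclusive(self):
        # region starts at 0-based 50_000 = 1-based 50_001; a site exactly
        # 10 kb upstream of the edge is included at a 10 kb window
        sites = _sites([40_001, 40_000])
        count, total, frac = proximity_fraction(sites, REGIONS, 10_000)
        assert (count, total) == (1, 2)

    def test_inside_region_distance_zero(self):
        count, _, _ = proximity_fraction(_sites([55_000]), REGIONS, 0)
        assert count == 1

    def test_constructed_fraction(self):
        inside = [55_000, 205_000, 59_000]
        outside = [500_000 + 10_000 * i for i in range(9)]
        count, total, frac = proximity_fraction(
            _sites(inside + outside), REGIONS, 10_000)
        assert (count, total, frac) == (3, 12, 0.25)

    def test_monotone_in_window(self):
        sites = _sites(list(range(10_000, 400_000, 7_000)))
        fracs = [proximity_fraction(sites, REGIONS, w)[2]
                 for w in (0, 1_000, 10_000, 100_000)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_site_targets_use_point_distance(self):
        targets = _sites([100_000])
        count, _, _ = proximity_fraction(
            _sites([90_000, 89_999]), targets, 10_000)
        assert count == 1

    def test_empty_targets_warn_zero(self):
        count, total, frac = proximity_fraction(
            _sites([1, 2]), REGIONS.iloc[:0], 10_000)
        assert (count, frac) == (0, 0.0)


class TestEnrichmentTest:
    def test_headline_fold_arithmetic(self):
        # 9/51 vs 0.6% of background reproduces a ~29.3-fold enrichment
        res = enrichment_test((9, 51), (486, 81_029))
        assert res.fold == pytest.approx(29.4, abs=0.2)
        assert res.p_value < 1e-15
        # 7/51 vs 0.5% of background gives the 27.4-fold figure
        res2 = enrichment_test((7, 51), (405, 81_029))
        assert res2.fold == pytest.approx(27.5, abs=0.2)

    def test_identical_proportions(self):
        res = enrichment_test((5, 100), (50, 1000))
        assert res.fold == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_fisher_and_chi2_agree_directionally(self):
        chi = enrichment_test((20, 100), (30, 1000), method="chi2")
        fis = enrichment_test((20, 100), (30, 1000), method="fisher")
        assert chi.p_value < 1e-6 and fis.p_value < 1e-6

    def test_swap_inverts_fold(self):
        a = enrichment_test((9, 51), (486, 81_029))
        b = enrichment_test((486, 81_029), (9, 51))
        assert a.fold == pytest.approx(1 / b.fold)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)


class TestCalibration:
    def test_posterior_odds_published_regime(self):
        # prior fraction 0.001%, power 0.1, alpha 1e-7 -> 10:1
        assert posterior_odds(1e-5, 0.1, 1e-7) == pytest.approx(10.0,
                                                                rel=1e-4)

    def test_posterior_odds_degenerate_regimes(self):
        assert posterior_odds(0.5, 0.3, 0.3) == pytest.approx(1.0)
        assert posterior_odds(0.5, 0.2, 1e-3) == pytest.approx(200.0)

    def test_posterior_odds_linear_in_power_inverse_in_alpha(self):
        base = posterior_odds(1e-4, 0.1, 1e-6)
        assert posterior_odds(1e-4, 0.2, 1e-6) == pytest.approx(2 * base)
        assert posterior_odds(1e-4, 0.1, 2e-6) == pytest.approx(base / 2)

    def test_posterior_odds_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            posterior_odds(1e-5, 0.1, 0.0)

    def test_bonferroni(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 500) == pytest.approx(1e-4)
        t = bonferroni_threshold(0.05, 3_410_426)
        assert t == pytest.approx(1.466e-8, rel=1e-3)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestProportionCi:
    def test_extremes(self):
        assert proportion_ci(0, 20)[0] == 0.0
        assert proportion_ci(20, 20)[1] == 1.0

    def test_matches_binomial_tail_inversion(self):
        low, high = proportion_ci(5, 100)
        # Clopper-Pearson bounds satisfy the tail equations
        assert binom.sf(4, 100, low) == pytest.approx(0.025, rel=1e-6)
        assert binom.cdf(5, 100, high) == pytest.approx(0.025, rel=1e-6)

    def test_contains_point_estimate(self):
        for k, n in [(1, 10), (37, 80), (500, 1000)]:
            low, high = proportion_ci(k, n)
            assert low <= k / n <= high


def test_composite_ase_deletion_filter():
    sites = _sites([100_000, 300_000, 500_000])
    ase = _sites([105_000, 501_000])
    dels = pd.DataFrame({"chrom": ["chrS"], "start": [250_000],
                         "end": [260_000], "label": ["d1"],
                         "track": ["deletion_syndrome"]})
    mask = composite_proximity_filter(sites, ase, dels,
                                      ase_window=10_000,
                                      deletion_window=250_000)
    # site 1: near ASE and within 250 kb of the deletion  -> kept
    # site 2: near deletion but no ASE within 10 kb       -> dropped
    # site 3: near ASE, 240 kb past the deletion end      -> kept
    assert mask.tolist() == [True, False, True]
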