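"""Omnibus ASHM calling: table reduction, immunity properties, QC."""

import numpy as np
import pandas as pd
import pytest

from ashmscreen.allele_counting import AlleleCountTensor, count_alleles
from ashmscreen.ashm_caller import (
    apply_qc,
    build_contingency_table,
    call_ashm,
    per_modification_imbalance,
    select_background_sites,
)
from ashmscreen.ashm_caller import test_cross_dataset_imbalance as omnibus_test
from ashmscreen.config import HISTONE_MODIFICATIONS

from .oracles import fisher_2x2_oracle


def _tensor(counts, alleles=("A", "G", "C", "T"),
            datasets=HISTONE_MODIFICATIONS[:3], site_id="s1"):
    counts = np.asarray(counts, dtype=int)
    return AlleleCountTensor(site_id=site_id,
                             alleles=list(alleles)[: counts.shape[0]],
                             datasets=list(datasets), counts=counts)


class TestContingencyReduction:
    def test_zero_coverage_modification_removed(self):
        t = _tensor([[3, 0, 5], [2, 0, 4], [0, 0, 0], [0, 0, 0]])
        table, alleles, mods = build_contingency_table(t)
        assert table.shape == (2, 2)
        assert mods == [HISTONE_MODIFICATIONS[0], HISTONE_MODIFICATIONS[2]]

    def test_single_allele_leaves_one_row(self):
        t = _tensor([[3, 1, 5], [0, 0, 0], [0, 0, 0], [0, 0, 0]])
        table, alleles, _ = build_contingency_table(t)
        assert table.shape == (1, 3)
        assert alleles == ["A"]

    def test_full_nonzero_table_unchanged(self):
        t = _tensor([[3, 1, 5], [2, 6, 4]])
        table, _, _ = build_contingency_table(t)
        assert (table == [[3, 1, 5], [2, 6, 4]]).all()

    def test_empty_tensor_degenerate(self):
        t = _tensor(np.zeros((4, 3)))
        table, _, _ = build_contingency_table(t)
        res = omnibus_test(table)
        assert res.p_value == 1.0 and not res.testable


class TestOmnibus:
    def test_identical_ratios_p_one(self):
        assert omnibus_test([[5, 5], [5, 5]]).p_value == 1.0

    def test_single_row_untestable(self):
        res = omnibus_test(np.array([[4, 7, 2]]))
        assert res.p_value == 1.0 and not res.testable

    def test_2x2_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = rng.integers(0, 7, size=(2, 2))
            res = omnibus_test(t)
            assert res.p_value == pytest.approx(fisher_2x2_oracle(t),
                                                rel=1e-9)

    def test_occupancy_scaling_leaves_null_structure(self):
        """Scaling one modification's coverage (occupancy, not identity)
        must not create dependence in expectation."""
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(50):
            depth = rng.poisson(4, 8)
            a = rng.binomial(depth, 0.8)       # same fraction everywhere
            tab = np.vstack([a, depth - a])
            ps.append(omnibus_test(tab).p_value)
        assert min(ps) > 1e-5   # no spuriously extreme independence p


class TestPerModification:
    def test_monoallelic_19_reads(self):
        t = _tensor([[19, 0, 7], [0, 0, 7]])
        res = per_modification_imbalance(t).set_index("modification")
        row = res.loc[HISTONE_MODIFICATIONS[0]]
        assert row["binomial_p"] == pytest.approx(2 * 0.5 ** 19, rel=1e-9)
        assert row["favored_allele"] == "A"

    def test_balanced_and_uncovered(self):
        t = _tensor([[7, 0, 15], [7, 0, 5]])
        res = per_modification_imbalance(t).set_index("modification")
        assert res.loc[HISTONE_MODIFICATIONS[0], "binomial_p"] == 1.0
        assert res.loc[HISTONE_MODIFICATIONS[0], "favored_allele"] is None
        assert res.loc[HISTONE_MODIFICATIONS[1], "binomial_p"] == 1.0
        assert res.loc[HISTONE_MODIFICATIONS[2], "binomial_p"] == \
            pytest.approx(0.0414, abs=5e-4)

    def test_restricted_to_site_alleles(self):
        # third-allele reads (sequencing error) don't enter the binomial
        t = _tensor([[10, 0, 0], [10, 0, 0], [5, 0, 0], [0, 0, 0]])
        res = per_modification_imbalance(t).set_index("modification")
        assert res.loc[HISTONE_MODIFICATIONS[0], "binomial_p"] == 1.0


class TestBackgroundAndQc:
    def test_coverage_floor_boundary(self):
        tensors = {
            "lo": _tensor([[17, 17, 0], [0, 0, 0]], site_id="lo"),
            "at": _tensor([[18, 17, 0], [0, 0, 0]], site_id="at"),
            "hi": _tensor([[20, 20, 5], [0, 0, 0]], site_id="hi")}
        assert set(select_background_sites(tensors, 35)) == {"at", "hi"}
        assert set(select_background_sites(tensors, 36)) == {"hi"}

    def test_hwe_boundary_strict(self):
        calls = pd.DataFrame({"site_id": ["x", "y"],
                              "omnibus_p": [1e-9, 1e-9]})
        # x: strong het excess (p << 0.05); y: balanced (p ~ 1)
        pop = pd.DataFrame({"site_id": ["x", "y"],
                            "hom_a": [2, 25], "het": [96, 50],
                            "hom_b": [2, 25]})
        out = apply_qc(calls, pop, hwe_alpha=0.05)
        by = out.set_index("site_id")
        assert not bool(by.loc["x", "passed_qc"])
        assert bool(by.loc["y", "passed_qc"])

    def test_allow_list_restricts_background(self):
        tensors = {
            "in": _tensor([[20, 20, 5], [0, 0, 0]], site_id="in"),
            "out": _tensor([[20, 20, 5], [0, 0, 0]], site_id="out")}
        calls, _, background = call_ashm(tensors, min_total_coverage=35,
                                         allow_list={"in"})
        assert background == ["in"]
        assert list(calls["site_id"]) == ["in"]

    def test_missing_population_data_leaves_qc_unchanged(self):
        calls = pd.DataFrame({"site_id": ["x"], "omnibus_p": [1e-9]})
        out = apply_qc(calls, None)
        assert bool(out.loc[0, "passed_qc"])
        assert not bool(out.loc[0, "hwe_assessed"])


class TestImmunityOnSyntheticData:
    def test_homozygous_false_hets_never_called(self, small_dataset):
        truth = small_dataset.truth
        hom_ids = truth.loc[truth["true_genotype"] == "hom", "site_id"]
        sites = small_dataset.sites[
            small_dataset.sites["site_id"].isin(set(hom_ids))]
        reads = small_dataset.chip_reads[
            small_dataset.chip_reads["site_id"].isin(set(hom_ids))]
        tensors = count_alleles(reads, sites,
                                datasets=HISTONE_MODIFICATIONS)
        calls, _, _ = call_ashm(tensors, min_total_coverage=1)
        assert not calls["significant"].any()
        # a stray sequencing-error read can make a table technically
        # testable, but never anywhere near significance
        assert (calls["omnibus_p"] > 1e-4).all()

    def test_significant_calls_are_true_implants(self, pipeline_result,
                                                 small_dataset):
        truth = small_dataset.truth.set_index("site_id")
        sig = pipeline_result.ashm_calls.loc[
            pipeline_result.ashm_calls["significant"], "site_id"]
        labels = truth.loc[sig, "ashm_label"]
        assert (labels.str.startswith("cluster")).all()
        recovered = len(sig)
        implanted = int(truth["ashm_label"].str.startswith("cluster").sum())
        assert recovered >= implanted // 2
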