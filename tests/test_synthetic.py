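"""Synthetic generator: determinism, implanted effects, fixture round-trip."""

import numpy as np
import pandas as pd
import pytest

from ashmscreen import (
    SimulationConfig,
    read_fixtures,
    simulate_dataset,
    write_fixtures,
)
from ashmscreen.config import ConfigError


def test_identical_seeds_identical_outputs():
    a = simulate_dataset(SimulationConfig(seed=5, n_sites=150))
    b = simulate_dataset(SimulationConfig(seed=5, n_sites=150))
    for attr in ("sites", "chip_reads", "bis_reads", "expression_reads",
                 "annotations", "truth", "population_genotypes"):
        pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))


def test_different_seeds_differ():
    a = simulate_dataset(SimulationConfig(seed=5, n_sites=100))
    b = simulate_dataset(SimulationConfig(seed=6, n_sites=100))
    assert not a.sites["pos"].equals(b.sites["pos"])


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="skew"):
        SimulationConfig(skew=1.5)
    with pytest.raises(ConfigError, match="cluster_pattern_weights"):
        SimulationConfig(cluster_pattern_weights=(1, 0, 0, 0, 0, 0.5))
    with pytest.raises(ConfigError, match="n_sites"):
        SimulationConfig(n_sites=0)


def test_null_sites_allele_fraction_near_half():
    """With no implants the per-modification allele fraction at null
    sites matches binomial(0.5) sampling within 3 SE."""
    cfg = SimulationConfig(
        seed=7, n_sites=800, ashm_fraction=0.0,
        occupancy_shift_fraction=0.0, false_het_fraction=0.0,
        asm_fraction=0.0, epiallele_fraction=0.0, ase_fraction=0.0,
        sequencing_error_rate=0.0)
    ds = simulate_dataset(cfg)
    sites = ds.sites.set_index("site_id")
    reads = ds.chip_reads
    is_a = (reads["observed_base"].to_numpy()
            == reads["site_id"].map(sites["allele_a"]).to_numpy())
    is_b = (reads["observed_base"].to_numpy()
            == reads["site_id"].map(sites["allele_b"]).to_numpy())
    n = int(is_a.sum() + is_b.sum())
    frac = is_a.sum() / n
    se = 0.5 / np.sqrt(n)
    assert abs(frac - 0.5) < 3 * se


def test_cluster5_only_h3k9me3_departs_from_half():
    """Sites of the H3K9me3-only pattern skew just that modification."""
    cfg = SimulationConfig(
        seed=9, n_sites=400, ashm_fraction=0.25,
        cluster_pattern_weights=(0, 0, 0, 0, 1, 0),
        occupancy_shift_fraction=0.0, false_het_fraction=0.0,
        asm_fraction=0.0, epiallele_fraction=0.0, ase_fraction=0.0,
        sequencing_error_rate=0.0)
    ds = simulate_dataset(cfg)
    truth = ds.truth.set_index("site_id")
    sites = ds.sites.set_index("site_id")
    reads = ds.chip_reads[ds.chip_reads["site_id"].map(
        truth["ashm_label"]) == "cluster_5"].copy()
    # orient by the designated (skewed) allele of each site
    designated = np.where(
        reads["site_id"].map(truth["designated_is_a"]),
        reads["site_id"].map(sites["allele_a"]),
        reads["site_id"].map(sites["allele_b"]))
    reads["hit"] = reads["observed_base"].to_numpy() == designated
    frac = reads.groupby("dataset_id", observed=True)["hit"].agg(
        ["mean", "count"])
    k9 = frac.loc["H3K9me3"]
    assert k9["mean"] == pytest.approx(0.9, abs=3 * 0.3 / np.sqrt(k9["count"]))
    others = frac.drop(index="H3K9me3")
    for mod, row in others.iterrows():
        se = 0.5 / np.sqrt(row["count"])
        assert abs(row["mean"] - 0.5) < 4 * se, mod


def test_occupancy_shift_skews_every_modification():
    cfg = SimulationConfig(
        seed=13, n_sites=300, ashm_fraction=0.0,
        occupancy_shift_fraction=0.3, false_het_fraction=0.0,
        asm_fraction=0.0, epiallele_fraction=0.0, ase_fraction=0.0,
        sequencing_error_rate=0.0)
    ds = simulate_dataset(cfg)
    truth = ds.truth.set_index("site_id")
    sites = ds.sites.set_index("site_id")
    reads = ds.chip_reads[ds.chip_reads["site_id"].map(
        truth["ashm_label"]) == "occupancy_shift"].copy()
    designated = np.where(
        reads["site_id"].map(truth["designated_is_a"]),
        reads["site_id"].map(sites["allele_a"]),
        reads["site_id"].map(sites["allele_b"]))
    reads["hit"] = reads["observed_base"].to_numpy() == designated
    frac = reads.groupby("dataset_id", observed=True)["hit"].agg(
        ["mean", "count"])
    for mod, row in frac.iterrows():
        se = 0.3 / np.sqrt(row["count"])
        assert row["mean"] == pytest.approx(0.9, abs=4 * se), mod


def test_false_het_sites_emit_single_allele_plus_error(small_dataset):
    truth = small_dataset.truth
    hom_ids = set(truth.loc[truth["true_genotype"] == "hom", "site_id"])
    reads = small_dataset.chip_reads[
        small_dataset.chip_reads["site_id"].isin(hom_ids)]
    major = reads.groupby("site_id")["observed_base"].agg(
        lambda s: s.value_counts().iloc[0] / len(s))
    assert (major > 0.97).all()


def test_cpg_sites_methylation_fully_linked_to_intact_allele(small_dataset):
    truth = small_dataset.truth.set_index("site_id")
    cpg = set(truth.index[truth["asm_label"] == "cpg_snp"])
    reads = small_dataset.bis_reads[
        small_dataset.bis_reads["site_id"].isin(cpg)]
    # G carries the intact CpG: methylation tracks it up to the noise rate
    g = reads[reads["observed_base"] == "G"]
    a = reads[reads["observed_base"] == "A"]
    assert g["methylated"].mean() > 0.85
    assert a["methylated"].mean() < 0.1


def test_epiallele_sites_have_both_alleles_and_differential_methylation(
        small_dataset):
    truth = small_dataset.truth.set_index("site_id")
    sites = small_dataset.sites.set_index("site_id")
    epi = truth.index[truth["asm_label"] == "epiallele"]
    assert len(epi) > 0
    for site_id in epi:
        reads = small_dataset.bis_reads[
            small_dataset.bis_reads["site_id"] == site_id]
        on_a = reads["observed_base"] == sites.loc[site_id, "allele_a"]
        on_b = reads["observed_base"] == sites.loc[site_id, "allele_b"]
        assert on_a.sum() > 0 and on_b.sum() > 0   # DNA intact on both
        delta = (reads.loc[on_a, "methylated"].mean()
                 - reads.loc[on_b, "methylated"].mean())
        assert abs(delta) > 0.5


def test_no_asm_means_equal_methylation_by_allele():
    cfg = SimulationConfig(seed=21, n_sites=400, asm_fraction=0.0,
                           epiallele_fraction=0.0)
    ds = simulate_dataset(cfg)
    sites = ds.sites.set_index("site_id")
    reads = ds.bis_reads
    on_a = (reads["observed_base"].to_numpy()
            == reads["site_id"].map(sites["allele_a"]).to_numpy())
    on_b = (reads["observed_base"].to_numpy()
            == reads["site_id"].map(sites["allele_b"]).to_numpy())
    meth = reads["methylated"].to_numpy()
    pa = meth[on_a].mean()
    pb = meth[on_b].mean()
    assert abs(pa - pb) < 0.02


def test_ase_linkage_fraction_matches_configuration():
    # ASE density kept low so chance colocalisation is negligible and the
    # truth-table count isolates the implanted linkage
    cfg = SimulationConfig(seed=17, n_sites=2000, ashm_fraction=0.05,
                           ase_fraction=0.01, ase_linked_fraction=0.2,
                           annotation_enrichment_fold=1.0,
                           mean_bis_depth=2, mean_rna_depth=2,
                           mean_chip_depth=0.5, driver_chip_depth=0.5)
    ds = simulate_dataset(cfg)
    truth = ds.truth
    ashm_pos = np.sort(truth.loc[
        truth["ashm_label"].str.startswith("cluster"), "pos"].to_numpy())
    ase_pos = np.sort(truth.loc[truth["ase_label"], "pos"].to_numpy())
    has_near = []
    for p in ashm_pos:
        i = np.searchsorted(ase_pos, p)
        near = False
        for j in (i - 1, i):
            if 0 <= j < len(ase_pos) and abs(int(ase_pos[j]) - int(p)) <= 10_000:
                near = True
        has_near.append(near)
    frac = np.mean(has_near)
    assert frac == pytest.approx(0.2, abs=0.08)


def test_fixture_round_trip(tmp_path, small_dataset):
    write_fixtures(small_dataset, tmp_path)
    back = read_fixtures(tmp_path)
    for attr in ("sites", "chip_reads", "bis_reads", "expression_reads",
                 "truth", "population_genotypes", "known_polymorphic"):
        pd.testing.assert_frame_equal(
            getattr(small_dataset, attr).reset_index(drop=True),
            getattr(back, attr).reset_index(drop=True),
            check_dtype=False)
    pd.testing.assert_frame_equal(
        small_dataset.annotations.sort_values(["track", "start"])
        .reset_index(drop=True),
        back.annotations.sort_values(["track", "start"])
        .reset_index(drop=True), check_dtype=False, check_like=True)


def test_bed_coordinate_convention(tmp_path):
    """A BED record [999, 2000) is the 1-based interval 1000..2000."""
    from ashmscreen import io
    bed = tmp_path / "r.bed"
    bed.write_text("chrS\t999\t2000\tregion_x\n")
    regions = io.read_bed(bed, track="imprinted")
    assert regions.loc[0, "start"] == 999 and regions.loc[0, "end"] == 2000
    # 1-based site at 1000 is the first base inside; 2000 the last
    from ashmscreen.enrichment import proximity_fraction
    sites = pd.DataFrame({"chrom": ["chrS"] * 3, "pos": [1000, 2000, 2001]})
    count, total, _ = proximity_fraction(sites, regions, window=0)
    assert (count, total) == (2, 3)


def test_truth_row_count_equals_n_sites(small_dataset, small_config):
    assert len(small_dataset.truth) == small_config.n_sites
    assert small_dataset.truth["site_id"].is_unique
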