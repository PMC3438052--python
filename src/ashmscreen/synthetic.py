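"""Seeded multi-assay allele-resolved dataset generator with known truth.

Emulates what the screen consumes: a table of putative heterozygotes with
imputation probabilities, per-read allele observations for 23
histone-modification ChIP datasets plus RNA and PolII, strand-resolved
bisulfite observations with per-read methylation calls, annotation tracks
(imprinted loci, deletion-syndrome regions) and population genotype counts
for the HWE filter.  Implanted effects:

* ASHM sites following the six cluster patterns (driver modifications
  skewed to allele fraction ``skew`` on a randomly designated allele,
  opposite-allele drivers mirrored, everything else balanced).  Driver
  marks receive ``driver_chip_depth`` mean coverage — a marked nucleosome
  is what ChIP enriches.
* occupancy-shift confounders: the *same* allele fraction applied to every
  modification (a nucleosome-presence difference, not a modification
  difference) — these must never be called ASHM;
* false-positive heterozygotes: truly homozygous sites that nonetheless
  carry an imputation probability >= 0.5 — they emit a single allele plus
  sequencing error;
* ASM driven by CpG-disrupting SNPs (methylation fully linked to the
  CpG-intact G allele at the base directly adjacent to the SNP) and
  epialleles (methylation differs between alleles with the DNA intact,
  query position well away from any polymorphism);
* ASE/ASP sites, a configurable fraction of which are placed within
  ``ase_link_distance`` of an ASHM site;
* proximity enrichment of ASHM sites around imprinted regions with a
  configurable implanted fold.

The generator never simulates raw sequence, alignment artefacts or
mappability bias; reads are exchangeable allele observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    CLUSTER_PATTERNS,
    EXPRESSION_ASSAYS,
    POLII_ASSAY,
    RNA_ASSAY,
    ConfigError,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])
#: window used when implanting annotation proximity (matches the 10 kb
#: reporting window of the screen)
IMPLANT_WINDOW = 10_000

ASHM_NONE = "none"
OCCUPANCY_SHIFT = "occupancy_shift"


@dataclass
class SimulatedDataset:
    """Bundle of every table the screen consumes, plus the truth."""

    config: SimulationConfig
    sites: pd.DataFrame
    chip_reads: pd.DataFrame
    bis_reads: pd.DataFrame
    expression_reads: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame
    population_genotypes: pd.DataFrame
    known_polymorphic: pd.DataFrame


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _sample_qualities(rng, dist: dict[int, float], size: int) -> np.ndarray:
    quals = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[q] for q in quals], dtype=float)
    return rng.choice(quals, size=size, p=probs)


def _place_regions(rng, n: int, length: int, chrom_length: int,
                   occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Non-overlapping half-open regions, kept clear of `occupied`."""
    regions: list[tuple[int, int]] = []
    attempts = 0
    while len(regions) < n:
        attempts += 1
        if attempts > 10_000:
            raise ConfigError(
                "could not place annotation regions; chrom_length too small "
                "for n_imprinted_regions/n_deletion_regions/region_length")
        start = int(rng.integers(IMPLANT_WINDOW,
                                 chrom_length - length - IMPLANT_WINDOW))
        cand = (start, start + length)
        pad = 2 * IMPLANT_WINDOW
        if any(cand[0] < e + pad and s - pad < cand[1]
               for s, e in regions + occupied):
            continue
        regions.append(cand)
    return sorted(regions)


def _footprint(regions, window, chrom_length):
    """Merged closed intervals of positions within `window` of a region."""
    iv = sorted((max(0, s - window), min(chrom_length, e + window))
                for s, e in regions)
    merged = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _sample_in_footprint(rng, footprint) -> int:
    lengths = np.array([e - s for s, e in footprint], dtype=float)
    i = int(rng.choice(len(footprint), p=lengths / lengths.sum()))
    s, e = footprint[i]
    return int(rng.integers(s, e))


def _sample_outside(rng, footprint, chrom_length) -> int:
    while True:  # rejection; footprint covers a few % of the chromosome
        pos = int(rng.integers(1000, chrom_length - 1000))
        if not any(s <= pos < e for s, e in footprint):
            return pos


def _expand_reads(rng, depth: np.ndarray, frac_a: np.ndarray,
                  allele_a_code: np.ndarray, allele_b_code: np.ndarray,
                  site_of_cell: np.ndarray, error_rate: float):
    """Flatten per-cell depths into per-read site indices and base codes."""
    counts = depth.ravel()
    read_site = np.repeat(site_of_cell.ravel(), counts)
    fa = np.repeat(frac_a.ravel(), counts)
    is_a = rng.random(fa.size) < fa
    true_base = np.where(is_a, allele_a_code[read_site],
                         allele_b_code[read_site])
    observed = true_base.copy()
    err = rng.random(observed.size) < error_rate
    if err.any():
        # error base uniform over the three other bases
        shift = rng.integers(1, 4, size=int(err.sum()))
        observed[err] = (observed[err] + shift) % 4
    return read_site, true_base, observed


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full dataset; identical configs give identical output."""
    if not isinstance(config, SimulationConfig):
        raise ConfigError("config must be a SimulationConfig")
    n = config.n_sites
    mods = config.modifications
    L = config.chrom_length

    # ---- annotation tracks -------------------------------------------
    rng_ann = _rng(config, 1)
    imprinted = _place_regions(rng_ann, config.n_imprinted_regions,
                               config.region_length, L, [])
    deletions = _place_regions(rng_ann, config.n_deletion_regions,
                               config.region_length, L, list(imprinted))
    annotations = pd.DataFrame(
        [{"chrom": config.chrom, "start": s, "end": e,
          "label": f"imprinted_{i + 1}", "track": "imprinted"}
         for i, (s, e) in enumerate(imprinted)]
        + [{"chrom": config.chrom, "start": s, "end": e,
            "label": f"deletion_{i + 1}", "track": "deletion_syndrome"}
           for i, (s, e) in enumerate(deletions)])

    # ---- per-site truth labels ---------------------------------------
    rng_lab = _rng(config, 2)
    n_ashm = int(round(n * config.ashm_fraction))
    n_occ = int(round(n * config.occupancy_shift_fraction))
    n_false = int(round(n * config.false_het_fraction))
    n_cpg = int(round(n * config.asm_fraction
                      * config.cpg_disrupting_fraction))
    n_epi = int(round(n * config.epiallele_fraction))
    n_ase = int(round(n * config.ase_fraction))
    n_special = n_ashm + n_occ + n_false + n_cpg + n_epi + n_ase
    if n_special > n:
        raise ConfigError("label fractions exceed available sites")

    clusters = 1 + rng_lab.choice(
        6, size=n_ashm, p=np.asarray(config.cluster_pattern_weights))
    ashm_label = np.array(
        [f"cluster_{c}" for c in clusters]
        + [OCCUPANCY_SHIFT] * n_occ
        + [ASHM_NONE] * (n - n_ashm - n_occ), dtype=object)
    asm_label = np.full(n, "none", dtype=object)
    asm_label[n_ashm + n_occ + n_false:
              n_ashm + n_occ + n_false + n_cpg] = "cpg_snp"
    asm_label[n_ashm + n_occ + n_false + n_cpg:
              n_ashm + n_occ + n_false + n_cpg + n_epi] = "epiallele"
    genotype = np.full(n, "het", dtype=object)
    genotype[n_ashm + n_occ: n_ashm + n_occ + n_false] = "hom"
    ase_label = np.zeros(n, dtype=bool)
    ase_label[n_special - n_ase: n_special] = True

    # ---- positions ----------------------------------------------------
    rng_pos = _rng(config, 3)
    fp = _footprint(imprinted, IMPLANT_WINDOW, L)
    p0 = sum(e - s for s, e in fp) / L
    q_in = min(1.0, config.annotation_enrichment_fold * p0)
    pos = np.zeros(n, dtype=np.int64)
    is_ashm = np.array([lab.startswith("cluster") for lab in ashm_label])
    for i in range(n):
        if is_ashm[i] and rng_pos.random() < q_in:
            pos[i] = _sample_in_footprint(rng_pos, fp)
        elif is_ashm[i]:
            pos[i] = _sample_outside(rng_pos, fp, L)
        else:
            pos[i] = int(rng_pos.integers(1000, L - 1000))
    # a configurable fraction of ASHM sites get an ASE site nearby
    ashm_idx = np.flatnonzero(is_ashm)
    ase_idx = np.flatnonzero(ase_label)
    n_linked = min(len(ase_idx),
                   int(round(config.ase_linked_fraction * len(ashm_idx))))
    linked_targets = rng_pos.choice(ashm_idx, size=n_linked, replace=False) \
        if n_linked else np.array([], dtype=int)
    for k in range(n_linked):
        d = config.ase_link_distance
        off = int(rng_pos.integers(10, max(11, d)))
        off *= -1 if rng_pos.random() < 0.5 else 1
        pos[ase_idx[k]] = int(np.clip(pos[linked_targets[k]] + off,
                                      1000, L - 1000))
    # enforce >= 3 bp separation so adjacency flags stay unambiguous
    for _ in range(100):
        order = np.argsort(pos, kind="stable")
        gaps_ok = np.diff(pos[order]) >= 3
        if gaps_ok.all():
            break
        pos[order[1:][~gaps_ok]] += 3
    order = np.argsort(pos, kind="stable")
    inv = order  # reorder every per-site array by genomic position
    pos = pos[inv]
    ashm_label = ashm_label[inv]
    asm_label = asm_label[inv]
    genotype = genotype[inv]
    ase_label = ase_label[inv]

    site_ids = np.array([f"s{i:06d}" for i in range(n)], dtype=object)

    # ---- alleles, imputation probabilities ---------------------------
    rng_al = _rng(config, 4)
    allele_a_code = rng_al.integers(0, 4, size=n)
    shift = rng_al.integers(1, 4, size=n)
    allele_b_code = (allele_a_code + shift) % 4
    is_cpg = asm_label == "cpg_snp"
    allele_a_code[is_cpg] = 2  # G: CpG intact
    allele_b_code[is_cpg] = 0  # A: guanine disrupted
    # which of the two alleles carries the implanted skew / homozygosity
    designated_is_a = rng_al.random(n) < 0.5
    source = np.where(rng_al.random(n) < 0.2, "array", "imputed")
    source[genotype == "hom"] = "imputed"  # false hets come from imputation
    p_het = rng_al.uniform(0.5, 1.0, size=n)
    p_het[source == "array"] = 1.0

    sites = pd.DataFrame({
        "site_id": site_ids, "chrom": config.chrom, "pos": pos + 1,
        "allele_a": BASES[allele_a_code], "allele_b": BASES[allele_b_code],
        "p_het": p_het, "source": source, "validated": False})

    # ---- ChIP reads ---------------------------------------------------
    rng_chip = _rng(config, 5)
    m = len(mods)
    mean_depth = np.full((n, m), float(config.mean_chip_depth))
    frac_a = np.full((n, m), 0.5)
    mod_index = {name: j for j, name in enumerate(mods)}
    for i in range(n):
        lab = ashm_label[i]
        if lab.startswith("cluster"):
            a_mods, b_mods = CLUSTER_PATTERNS[int(lab.split("_")[1])]
            for mod in a_mods | b_mods:
                j = mod_index[mod]
                mean_depth[i, j] = config.driver_chip_depth
                toward_designated = mod in a_mods
                if designated_is_a[i] == toward_designated:
                    frac_a[i, j] = config.skew
                else:
                    frac_a[i, j] = 1.0 - config.skew
        elif lab == OCCUPANCY_SHIFT:
            frac_a[i, :] = config.skew if designated_is_a[i] \
                else 1.0 - config.skew
        if genotype[i] == "hom":
            frac_a[i, :] = 1.0 if designated_is_a[i] else 0.0
    depth = rng_chip.poisson(mean_depth)
    site_of_cell = np.repeat(np.arange(n), m).reshape(n, m)
    read_site, _, observed = _expand_reads(
        rng_chip, depth, frac_a, allele_a_code, allele_b_code,
        site_of_cell, config.sequencing_error_rate)
    read_mod = np.repeat(np.tile(np.arange(m), n), depth.ravel())
    chip_reads = pd.DataFrame({
        "site_id": site_ids[read_site],
        "dataset_id": np.array(mods, dtype=object)[read_mod],
        "observed_base": BASES[observed],
        "base_quality": _sample_qualities(
            rng_chip, config.base_quality_distribution, observed.size),
        "strand": rng_chip.choice(np.array(["+", "-"]), size=observed.size)})

    # ---- bisulfite observations --------------------------------------
    bis_reads = simulate_bisulfite_observations(
        sites, _truth_frame(config, site_ids, pos, genotype, ashm_label,
                            asm_label, ase_label, designated_is_a,
                            annotations),
        config)

    # ---- expression / PolII reads ------------------------------------
    truth = _truth_frame(config, site_ids, pos, genotype, ashm_label,
                         asm_label, ase_label, designated_is_a, annotations)
    expression_reads = simulate_expression_counts(sites, truth, config)

    # ---- population genotype counts for the HWE filter ---------------
    rng_pop = _rng(config, 8)
    npop = config.n_population
    hom_a = np.zeros(n, dtype=int)
    het = np.zeros(n, dtype=int)
    hom_b = np.zeros(n, dtype=int)
    for i in range(n):
        if genotype[i] == "hom":
            # duplication-like artefact: gross heterozygote excess
            het[i] = int(round(0.9 * npop))
            hom_a[i] = (npop - het[i]) // 2
            hom_b[i] = npop - het[i] - hom_a[i]
        else:
            f = rng_pop.uniform(0.1, 0.9)
            draws = rng_pop.multinomial(
                npop, [f * f, 2 * f * (1 - f), (1 - f) * (1 - f)])
            hom_a[i], het[i], hom_b[i] = (int(x) for x in draws)
    population_genotypes = pd.DataFrame({
        "site_id": site_ids, "hom_a": hom_a, "het": het, "hom_b": hom_b})

    known_polymorphic = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos + 1})

    logger.info(
        "simulated %d sites: %d ASHM, %d occupancy-shift, %d false het, "
        "%d CpG-SNP ASM, %d epiallele, %d ASE",
        n, n_ashm, n_occ, n_false, n_cpg, n_epi, n_ase)
    return SimulatedDataset(
        config=config, sites=sites, chip_reads=chip_reads,
        bis_reads=bis_reads, expression_reads=expression_reads,
        annotations=annotations, truth=truth,
        population_genotypes=population_genotypes,
        known_polymorphic=known_polymorphic)


def _truth_frame(config, site_ids, pos, genotype, ashm_label, asm_label,
                 ase_label, designated_is_a, annotations) -> pd.DataFrame:
    def near(track, window):
        regs = annotations[annotations["track"] == track]
        out = np.zeros(len(pos), dtype=bool)
        for _, r in regs.iterrows():
            dist = np.maximum(
                np.maximum(r["start"] - pos, pos - (r["end"] - 1)), 0)
            out |= dist <= window
        return out

    return pd.DataFrame({
        "site_id": site_ids, "chrom": config.chrom, "pos": pos + 1,
        "true_genotype": genotype, "ashm_label": ashm_label,
        "asm_label": asm_label, "ase_label": ase_label,
        "designated_is_a": designated_is_a,
        "near_imprinted": near("imprinted", IMPLANT_WINDOW),
        "near_deletion": near("deletion_syndrome", 250_000)})


def simulate_bisulfite_observations(sites: pd.DataFrame,
                                    truth: pd.DataFrame,
                                    config: SimulationConfig) -> pd.DataFrame:
    """Strand-resolved bisulfite observations with methylation calls.

    Each row is one read overlapping a heterozygote candidate: the base it
    carries at the site, its strand, and its methylation call at the
    site's methylation query position.  CpG-SNP ASM sites methylate only
    reads carrying the CpG-intact G allele at the directly adjacent base;
    epiallele sites methylate the two alleles at probabilities separated
    by ``epiallele_meth_delta`` with the DNA itself intact (query position
    well away from any polymorphism); all other partially methylated
    positions are balanced.
    """
    rng = _rng(config, 6)
    n = len(sites)
    pos0 = sites["pos"].to_numpy() - 1
    truth = truth.set_index("site_id").loc[sites["site_id"]]
    genotype = truth["true_genotype"].to_numpy()
    asm_label = truth["asm_label"].to_numpy()
    designated_is_a = truth["designated_is_a"].to_numpy()
    code = {b: i for i, b in enumerate(BASES)}
    a_code = sites["allele_a"].map(code).to_numpy()
    b_code = sites["allele_b"].map(code).to_numpy()

    all_pos = np.sort(pos0)

    def clear_of_snps(p):
        i = np.searchsorted(all_pos, p)
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(all_pos) and abs(int(all_pos[j]) - p) <= 1:
                return False
        return True

    meth_pos = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if asm_label[i] == "cpg_snp":
            meth_pos[i] = pos0[i] - 1  # the cytosine whose CpG the SNP breaks
        else:
            offset = 37 if asm_label[i] == "epiallele" else 23
            p = pos0[i] + offset
            while not clear_of_snps(p):
                p += 3
            meth_pos[i] = p

    # per-strand depths; both strands observe every site except where the
    # extraction rules later drop an ambiguous strand
    depth = rng.poisson(config.mean_bis_depth, size=(n, 2))
    frac_a = np.where(genotype == "hom",
                      np.where(designated_is_a, 1.0, 0.0), 0.5)
    frac_a = np.repeat(frac_a[:, None], 2, axis=1)
    site_of_cell = np.repeat(np.arange(n), 2).reshape(n, 2)
    read_site, true_base, observed = _expand_reads(
        rng, depth, frac_a, a_code, b_code, site_of_cell,
        config.sequencing_error_rate)
    read_strand = np.repeat(np.tile(np.array(["+", "-"]), n), depth.ravel())

    hi = 0.5 + config.epiallele_meth_delta / 2
    lo = 0.5 - config.epiallele_meth_delta / 2
    meth_p = np.full(read_site.size, 0.7)
    lab_of_read = asm_label[read_site]
    cpg = lab_of_read == "cpg_snp"
    meth_p[cpg] = np.where(true_base[cpg] == 2, 0.95, 0.02)
    epi = lab_of_read == "epiallele"
    carries_a = true_base == a_code[read_site]
    meth_p[epi] = np.where(carries_a[epi], hi, lo)
    methylated = rng.random(read_site.size) < meth_p

    return pd.DataFrame({
        "site_id": sites["site_id"].to_numpy()[read_site],
        "strand": read_strand,
        "observed_base": BASES[observed],
        "base_quality": _sample_qualities(
            rng, config.base_quality_distribution, read_site.size),
        "meth_pos": meth_pos[read_site] + 1,
        "methylated": methylated})


def simulate_expression_counts(sites: pd.DataFrame, truth: pd.DataFrame,
                               config: SimulationConfig) -> pd.DataFrame:
    """RNA and PolII allele observations; ASE sites skewed, others 50/50."""
    rng = _rng(config, 7)
    n = len(sites)
    truth = truth.set_index("site_id").loc[sites["site_id"]]
    genotype = truth["true_genotype"].to_numpy()
    ase = truth["ase_label"].to_numpy()
    designated_is_a = truth["designated_is_a"].to_numpy()
    code = {b: i for i, b in enumerate(BASES)}
    a_code = sites["allele_a"].map(code).to_numpy()
    b_code = sites["allele_b"].map(code).to_numpy()

    frac = np.full(n, 0.5)
    frac[ase] = np.where(designated_is_a[ase], config.skew,
                         1.0 - config.skew)
    hom = genotype == "hom"
    frac[hom] = np.where(designated_is_a[hom], 1.0, 0.0)
    frac_cells = np.repeat(frac[:, None], 2, axis=1)
    mean = np.column_stack([
        np.full(n, float(config.mean_rna_depth)),
        np.full(n, float(config.mean_rna_depth) / 2.0)])
    depth = rng.poisson(mean)
    site_of_cell = np.repeat(np.arange(n), 2).reshape(n, 2)
    read_site, _, observed = _expand_reads(
        rng, depth, frac_cells, a_code, b_code, site_of_cell,
        config.sequencing_error_rate)
    read_assay = np.repeat(np.tile(np.array(EXPRESSION_ASSAYS, dtype=object),
                                   n), depth.ravel())
    return pd.DataFrame({
        "site_id": sites["site_id"].to_numpy()[read_site],
        "dataset_id": read_assay,
        "observed_base": BASES[observed],
        "base_quality": _sample_qualities(
            rng, config.base_quality_distribution, read_site.size),
        "strand": rng.choice(np.array(["+", "-"]), size=read_site.size)})


# ---------------------------------------------------------------------------
# fixtures on disk

FIXTURE_FILES = {
    "sites": "sites.tsv",
    "chip_reads": "chip_counts.tsv",
    "bis_reads": "bisulfite_obs.tsv",
    "expression_reads": "expression_counts.tsv",
    "truth": "truth.tsv",
    "population_genotypes": "pop_genotypes.tsv",
    "known_polymorphic": "known_polymorphic.tsv",
}


def write_fixtures(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write the dataset as TSV/BED files; round-trips via read_fixtures.

    Site tables use 1-based positions; BED tracks are 0-based half-open.
    """
    from . import io as io_mod
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for attr, fname in FIXTURE_FILES.items():
        path = directory / fname
        io_mod.write_table(getattr(dataset, attr), path)
        paths[attr] = path
    ann = dataset.annotations
    for track, fname in (("imprinted", "imprinted.bed"),
                         ("deletion_syndrome", "deletions.bed")):
        path = directory / fname
        io_mod.write_bed(ann[ann["track"] == track], path)
        paths[track] = path
    return paths


def read_fixtures(directory) -> SimulatedDataset:
    """Read fixtures written by :func:`write_fixtures`."""
    from . import io as io_mod
    directory = Path(directory)
    tables = {attr: io_mod.read_table(directory / fname)
              for attr, fname in FIXTURE_FILES.items()}
    imprinted = io_mod.read_bed(directory / "imprinted.bed",
                                track="imprinted")
    deletions = io_mod.read_bed(directory / "deletions.bed",
                                track="deletion_syndrome")
    annotations = pd.concat([imprinted, deletions], ignore_index=True)
    return SimulatedDataset(config=None, annotations=annotations, **tables)
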