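"""Strand-specific allele-specific methylation (ASM) calling.

At every at-least-partially-methylated query position, the proportions of
methylated and unmethylated calls are compared between reads carrying
each allele of the linked heterozygote with a two-sided Fisher exact test
(stranded independently).  Most strong ASM in practice is caused by SNPs
that destroy the guanine of a CpG, so calls are annotated with whether a
heterozygote lies directly adjacent to the methylation query position —
epialleles are the calls without that flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

#: number of strand-specific methylation tests behind the Bonferroni
#: rationale for the 1e-8 cut-off in the original genome-scale screen
GENOME_SCALE_ASM_TESTS = 3_410_426


def test_asm_site(table) -> float:
    """Two-sided Fisher exact p for a 2x2 allele x methylation table.

    Zero-margin tables (one allele absent, or no methylation contrast)
    are untestable and return p = 1.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2):
        raise ValueError("ASM table must be 2x2")
    if (tab < 0).any():
        raise ValueError("ASM table entries must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 1.0
    return float(fisher_exact(tab, alternative="two-sided")[1])


def call_asm(methyl_obs: pd.DataFrame, sites: pd.DataFrame,
             asm_alpha: float = 1e-8) -> pd.DataFrame:
    """Run the stranded ASM test at every partially methylated position.

    Parameters
    ----------
    methyl_obs
        Output of the methylation extraction: ``site_id, strand,
        allele_carried, pos, methylated, base_quality``.
    sites
        Validated heterozygote table (supplies the two alleles).
    asm_alpha
        Significance cut-off (Bonferroni-style; at genome scale 0.05 over
        ~3.4 million tests is of order 1e-8).

    Returns
    -------
    One row per (site, strand, position) tested: the 2x2 counts,
    ``p_value`` and ``significant``.  Positions with no methylated read
    are skipped; reads carrying neither site allele are ignored.
    """
    indexed = sites.set_index("site_id")
    obs = methyl_obs.copy()
    obs["is_a"] = obs["allele_carried"] == obs["site_id"].map(
        indexed["allele_a"])
    obs["is_b"] = obs["allele_carried"] == obs["site_id"].map(
        indexed["allele_b"])
    obs = obs[obs["is_a"] | obs["is_b"]]

    records = []
    for (site_id, strand, pos), grp in obs.groupby(
            ["site_id", "strand", "pos"], sort=True):
        meth = grp["methylated"].to_numpy()
        if not meth.any():
            continue    # only positions of at least partial methylation
        is_a = grp["is_a"].to_numpy()
        table = [[int((is_a & meth).sum()), int((is_a & ~meth).sum())],
                 [int((~is_a & meth).sum()), int((~is_a & ~meth).sum())]]
        p = test_asm_site(table)
        records.append({
            "site_id": site_id, "strand": strand, "pos": int(pos),
            "n_a_meth": table[0][0], "n_a_unmeth": table[0][1],
            "n_b_meth": table[1][0], "n_b_unmeth": table[1][1],
            "p_value": p, "significant": p < asm_alpha})
    logger.info("ASM: tested %d strand/position combinations "
                "(alpha %g; genome-scale Bonferroni context: 0.05/%d = %.2e)",
                len(records), asm_alpha, GENOME_SCALE_ASM_TESTS,
                0.05 / GENOME_SCALE_ASM_TESTS)
    columns = ["site_id", "strand", "pos", "n_a_meth", "n_a_unmeth",
               "n_b_meth", "n_b_unmeth", "p_value", "significant"]
    return pd.DataFrame.from_records(records, columns=columns)


def annotate_adjacent_polymorphism(asm_calls: pd.DataFrame,
                                   het_sites: pd.DataFrame,
                                   max_distance: int = 1) -> pd.DataFrame:
    """Flag calls whose query position is directly adjacent to a SNP.

    ``adjacent_polymorphism`` is True iff a heterozygote candidate with
    p_het >= 0.5 lies within ``max_distance`` bp of the methylation query
    position.  The default of 1 bp targets the CpG-partner base: the
    mechanism flagged is a SNP removing the guanine of a CpG motif.
    """
    out = asm_calls.copy()
    if out.empty:
        out["adjacent_polymorphism"] = pd.Series(dtype=bool)
        return out
    hets = het_sites[het_sites["p_het"] >= 0.5]
    flags = np.zeros(len(out), dtype=bool)
    chrom_of = het_sites.set_index("site_id")["chrom"]
    call_chrom = out["site_id"].map(chrom_of)
    for chrom, grp in hets.groupby("chrom"):
        snp_pos = np.sort(grp["pos"].to_numpy())
        mask = (call_chrom == chrom).to_numpy()
        if not mask.any() or len(snp_pos) == 0:
            continue
        qpos = out.loc[mask, "pos"].to_numpy()
        i = np.searchsorted(snp_pos, qpos)
        dist = np.full(qpos.shape, np.iinfo(np.int64).max)
        left_ok = i > 0
        dist[left_ok] = np.abs(qpos[left_ok] - snp_pos[i[left_ok] - 1])
        right_ok = i < len(snp_pos)
        dist[right_ok] = np.minimum(
            dist[right_ok], np.abs(snp_pos[i[right_ok]] - qpos[right_ok]))
        flags[mask] = dist <= max_distance
    out["adjacent_polymorphism"] = flags
    return out
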