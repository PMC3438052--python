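"""Allele-specific histone modification (ASHM) calling.

A site shows ASHM when the proportion of reads carrying each allele
differs between at least two histone-modification datasets.  The omnibus
statistic is an exact test of independence on the alleles x modifications
contingency table (zero-sum rows/columns removed).  This construction is
immune to the two dominant artefacts:

* occupancy shifts — a nucleosome-presence difference between alleles
  scales every modification's allele ratio identically and leaves the
  independence structure intact;
* false-positive heterozygotes — a truly homozygous site shows one
  allele, the reduced table has a single row, and the test is undefined
  (p = 1), so such sites can never be called.

QC per called SNP: an exact Hardy-Weinberg test on population genotype
counts (duplications and common CNVs push false-positive SNPs out of
HWE), and a reported-only comparison of bisulfite coverage at called
sites against the genome-wide mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allele_counting import AlleleCountTensor
from .config import HISTONE_MODIFICATIONS
from .exact import (
    ExactResult,
    binomial_two_sided,
    hwe_exact_test,
    rxc_fisher_exact,
)

logger = logging.getLogger(__name__)


def build_contingency_table(tensor: AlleleCountTensor
                            ) -> tuple[np.ndarray, list[str], list[str]]:
    """Alleles x modifications table with zero-sum rows/columns removed.

    Only histone-modification datasets enter the omnibus table (RNA and
    PolII are tested separately).  Returns the reduced matrix plus the
    surviving allele and modification labels; an empty tensor reduces to
    a 0 x 0 matrix, which downstream flags untestable.
    """
    mod_cols = [j for j, d in enumerate(tensor.datasets)
                if d in HISTONE_MODIFICATIONS]
    table = tensor.counts[:, mod_cols]
    mods = [tensor.datasets[j] for j in mod_cols]
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    reduced = table[keep_rows][:, keep_cols]
    alleles = [a for a, k in zip(tensor.alleles, keep_rows) if k]
    mods = [m for m, k in zip(mods, keep_cols) if k]
    return reduced, alleles, mods


def test_cross_dataset_imbalance(table, node_budget: int = 3_000_000
                                 ) -> ExactResult:
    """Omnibus exact test of allele x dataset independence.

    Tables with fewer than two rows or columns after reduction are
    untestable (p = 1).  Falls back to a flagged Pearson chi-square
    approximation beyond the complexity budget.
    """
    return rxc_fisher_exact(table, node_budget=node_budget)


def per_modification_imbalance(tensor: AlleleCountTensor) -> pd.DataFrame:
    """Two-sided binomial test of each modification against 50/50.

    Restricted to the site's two validated alleles.  Modifications with
    zero coverage yield p = 1 and no favored allele; the favored allele
    is the one with the larger count (ties favor neither).
    """
    pair = tensor.restrict_to_site_alleles()
    records = []
    for j, d in enumerate(pair.datasets):
        if d not in HISTONE_MODIFICATIONS:
            continue
        a, b = int(pair.counts[0, j]), int(pair.counts[1, j])
        if a + b == 0:
            p, favored = 1.0, None
        else:
            p = binomial_two_sided(a, a + b)
            favored = (pair.alleles[0] if a > b
                       else pair.alleles[1] if b > a else None)
        records.append({"site_id": tensor.site_id, "modification": d,
                        "count_a": a, "count_b": b,
                        "binomial_p": p, "favored_allele": favored})
    return pd.DataFrame.from_records(records)


def select_background_sites(tensors: dict[str, AlleleCountTensor],
                            min_total_coverage: int = 35) -> list[str]:
    """Sites whose summed modification coverage reaches the floor.

    This high-coverage set — heterozygotes at which ASHM was detectable
    had it existed — is the denominator of every enrichment comparison.
    """
    return [s for s, t in tensors.items()
            if t.total_coverage >= min_total_coverage]


@dataclass
class CoverageQC:
    """Reported-only duplication screen: bisulfite depth at called sites
    relative to the genome-wide mean (duplications inflate coverage; a
    ratio at or below 1 argues against hidden duplicated copies)."""

    mean_at_calls: float
    mean_genome_wide: float

    @property
    def ratio(self) -> float:
        if self.mean_genome_wide == 0:
            return float("nan")
        return self.mean_at_calls / self.mean_genome_wide


def coverage_qc(bis_reads: pd.DataFrame, called_site_ids) -> CoverageQC:
    """Compare mean bisulfite depth at called sites vs all sites."""
    depth = bis_reads.groupby("site_id", sort=False).size()
    called = set(called_site_ids)
    at_calls = depth[depth.index.isin(called)]
    return CoverageQC(
        mean_at_calls=float(at_calls.mean()) if len(at_calls) else 0.0,
        mean_genome_wide=float(depth.mean()) if len(depth) else 0.0)


def apply_qc(calls: pd.DataFrame,
             population_genotypes: pd.DataFrame | None,
             hwe_alpha: float = 0.05,
             coverage_summary: CoverageQC | None = None) -> pd.DataFrame:
    """Attach HWE p-values and set ``passed_qc``.

    Sites with HWE p strictly below ``hwe_alpha`` fail QC; sites without
    population genotype data are recorded as not assessed and keep their
    QC status.  The coverage comparison is reported, never filtered on.
    """
    out = calls.copy()
    if "passed_qc" not in out.columns:
        out["passed_qc"] = True
    out["hwe_p"] = np.nan
    out["hwe_assessed"] = False
    if population_genotypes is None or len(population_genotypes) == 0:
        logger.warning("no population genotypes supplied; HWE QC not "
                       "assessed, passed_qc unchanged")
    else:
        pop = population_genotypes.set_index("site_id")
        for i, site_id in enumerate(out["site_id"]):
            if site_id not in pop.index:
                logger.warning("site %s missing population genotypes; HWE "
                               "not assessed", site_id)
                continue
            row = pop.loc[site_id]
            p = hwe_exact_test((row["hom_a"], row["het"], row["hom_b"]))
            out.iloc[i, out.columns.get_loc("hwe_p")] = p
            out.iloc[i, out.columns.get_loc("hwe_assessed")] = True
        failed = out["hwe_assessed"] & (out["hwe_p"] < hwe_alpha)
        out.loc[failed, "passed_qc"] = False
        logger.info("HWE QC: %d of %d assessed calls excluded at p < %g",
                    int(failed.sum()), int(out["hwe_assessed"].sum()),
                    hwe_alpha)
    if coverage_summary is not None:
        logger.info("coverage QC (reported only): mean bisulfite depth at "
                    "called sites %.2f vs genome-wide %.2f (ratio %.3f)",
                    coverage_summary.mean_at_calls,
                    coverage_summary.mean_genome_wide,
                    coverage_summary.ratio)
    return out


def call_ashm(tensors: dict[str, AlleleCountTensor],
              ashm_alpha: float = 1e-7,
              min_total_coverage: int = 35,
              node_budget: int = 3_000_000,
              population_genotypes: pd.DataFrame | None = None,
              hwe_alpha: float = 0.05,
              bis_reads: pd.DataFrame | None = None,
              allow_list: set[str] | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Full ASHM stage: omnibus calls, per-modification tests, background.

    Parameters
    ----------
    tensors
        Allele-count tensors of validated heterozygotes.
    allow_list
        Optional set of site identifiers to retain (models restriction
        to SNPs present in a reference variation release).

    Returns
    -------
    (calls, per_modification, background_site_ids): calls has one row per
    background site with ``omnibus_p``, ``approximate``, ``total_coverage``,
    QC columns and ``significant``; per-modification binomial results are
    computed for significant omnibus sites.
    """
    background = select_background_sites(tensors, min_total_coverage)
    if allow_list is not None:
        background = [s for s in background if s in allow_list]
    logger.info("ASHM: %d sites at >= %dx summed modification coverage",
                len(background), min_total_coverage)
    records = []
    for site_id in background:
        tensor = tensors[site_id]
        table, _, _ = build_contingency_table(tensor)
        res = test_cross_dataset_imbalance(table, node_budget=node_budget)
        records.append({
            "site_id": site_id, "omnibus_p": res.p_value,
            "approximate": not res.exact, "testable": res.testable,
            "total_coverage": tensor.total_coverage})
    calls = pd.DataFrame.from_records(
        records, columns=["site_id", "omnibus_p", "approximate",
                          "testable", "total_coverage"])
    calls["passed_qc"] = True
    candidates = calls["omnibus_p"] < ashm_alpha
    cov = (coverage_qc(bis_reads, calls.loc[candidates, "site_id"])
           if bis_reads is not None else None)
    qc_input = calls[candidates]
    if len(qc_input):
        qc = apply_qc(qc_input, population_genotypes, hwe_alpha=hwe_alpha,
                      coverage_summary=cov)
        calls = calls.merge(
            qc[["site_id", "hwe_p", "hwe_assessed", "passed_qc"]],
            on="site_id", how="left", suffixes=("_pre", ""))
        calls["passed_qc"] = (calls["passed_qc"].astype("boolean")
                              .fillna(True).astype(bool))
        calls = calls.drop(columns=["passed_qc_pre"])
    else:
        calls["hwe_p"] = np.nan
        calls["hwe_assessed"] = False
    calls["significant"] = ((calls["omnibus_p"] < ashm_alpha)
                            & calls["passed_qc"])
    per_mod = [per_modification_imbalance(tensors[s])
               for s in calls.loc[calls["significant"], "site_id"]]
    per_mod_df = (pd.concat(per_mod, ignore_index=True) if per_mod
                  else pd.DataFrame(columns=[
                      "site_id", "modification", "count_a", "count_b",
                      "binomial_p", "favored_allele"]))
    logger.info("ASHM: %d significant calls at alpha %g",
                int(calls["significant"].sum()), ashm_alpha)
    return calls, per_mod_df, background
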