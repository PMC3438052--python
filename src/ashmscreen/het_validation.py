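"""Heterozygote-candidate validation from bisulfite allele support.

Imputed heterozygote calls contain false positives; requiring that
whole-genome bisulfite reads show both alleles (at least two reads each)
removes most of them.  Only validated sites enter any downstream caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allele_counting import ambiguous_strand_mask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HetCallPerformance:
    """Confusion counts and derived rates of heterozygote calling."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def bisulfite_allele_support(bis_reads: pd.DataFrame, sites: pd.DataFrame,
                             min_base_quality: int = 13) -> pd.DataFrame:
    """Reads supporting each site allele, regardless of methylation.

    Applies the quality floor and the per-strand C/T (plus) / G/A (minus)
    ambiguity exclusion; bases matching neither allele are not support.
    Returns ``site_id, n_allele_a, n_allele_b``.
    """
    reads = bis_reads[bis_reads["base_quality"] >= min_base_quality]
    reads = reads[~ambiguous_strand_mask(sites, reads["strand"],
                                         reads["site_id"])]
    indexed = sites.set_index("site_id")
    a_of = reads["site_id"].map(indexed["allele_a"])
    b_of = reads["site_id"].map(indexed["allele_b"])
    support = pd.DataFrame({
        "site_id": reads["site_id"],
        "is_a": (reads["observed_base"] == a_of).astype(int),
        "is_b": (reads["observed_base"] == b_of).astype(int),
    }).groupby("site_id", sort=False).sum()
    out = pd.DataFrame({
        "site_id": sites["site_id"],
        "n_allele_a": sites["site_id"].map(support["is_a"]).fillna(0).astype(int),
        "n_allele_b": sites["site_id"].map(support["is_b"]).fillna(0).astype(int),
    })
    return out


def filter_het_sites(candidates: pd.DataFrame, bis_support: pd.DataFrame,
                     p_min: float = 0.5,
                     min_reads_per_allele: int = 2) -> pd.DataFrame:
    """Retain candidates with p_het >= p_min and both alleles supported.

    A candidate absent from ``bis_support`` counts as zero support on both
    alleles and is excluded (logged).  Retained sites are flagged
    ``validated = True``; the returned table contains only retained rows.
    """
    support = bis_support.set_index("site_id")
    n_a = candidates["site_id"].map(support["n_allele_a"])
    n_b = candidates["site_id"].map(support["n_allele_b"])
    missing = n_a.isna()
    if missing.any():
        logger.warning("%d candidate site(s) missing from bisulfite "
                       "support; treated as unsupported", int(missing.sum()))
    n_a = n_a.fillna(0)
    n_b = n_b.fillna(0)
    keep = ((candidates["p_het"] >= p_min)
            & (n_a >= min_reads_per_allele)
            & (n_b >= min_reads_per_allele))
    validated = candidates[keep].copy()
    validated["validated"] = True
    logger.info("het validation: %d of %d candidates retained "
                "(p_het >= %g, >= %d reads per allele)",
                len(validated), len(candidates), p_min, min_reads_per_allele)
    return validated


def validate_from_bisulfite_only(candidates: pd.DataFrame,
                                 bis_support: pd.DataFrame,
                                 min_reads_per_allele: int = 2
                                 ) -> pd.DataFrame:
    """Validation without array/imputation input (IMR90-style).

    Sites at known-polymorphism positions with both alleles supported by
    at least ``min_reads_per_allele`` bisulfite reads are accepted,
    ignoring ``p_het``.
    """
    return filter_het_sites(candidates.assign(p_het=1.0), bis_support,
                            p_min=0.0,
                            min_reads_per_allele=min_reads_per_allele)


def evaluate_het_calls(calls, truth_genotypes: pd.DataFrame
                       ) -> HetCallPerformance:
    """Confusion counts of heterozygote calls against truth genotypes.

    Parameters
    ----------
    calls
        Site identifiers called heterozygous (iterable or frame with a
        ``site_id`` column).
    truth_genotypes
        One row per candidate with ``site_id`` and ``true_genotype``
        (``"het"`` or any homozygous label); defines the candidate
        universe scored.
    """
    if len(truth_genotypes) == 0:
        raise ValueError("empty candidate set: nothing to evaluate")
    if isinstance(calls, pd.DataFrame):
        calls = calls["site_id"]
    called = truth_genotypes["site_id"].isin(set(calls)).to_numpy()
    is_het = (truth_genotypes["true_genotype"] == "het").to_numpy()
    return HetCallPerformance(
        tp=int((called & is_het).sum()),
        fp=int((called & ~is_het).sum()),
        tn=int((~called & ~is_het).sum()),
        fn=int((~called & is_het).sum()))
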