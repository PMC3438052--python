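"""Allele-specific expression / PolII binding calling, and inversion
haplotype assignment.

ASE and allele-specific PolII binding are the same procedure on two
assays: at each validated heterozygote, allele read counts are tested
against the expected 50/50 ratio with a two-sided binomial test.  The
canonical anchor: 19 reads all carrying one allele give p = 2 x 0.5^19
= 3.8e-6 — real evidence, yet above a 1e-7 genome-wide cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .allele_counting import count_alleles
from .config import EXPRESSION_ASSAYS
from .exact import binomial_two_sided

logger = logging.getLogger(__name__)


def binomial_imbalance_test(count_a: int, count_b: int) -> float:
    """Two-sided binomial p for allele counts against a 50/50 ratio.

    Defined by minimum-likelihood summation; with no reads on one allele
    this is the closed form 2 x 0.5^(a+b).  Zero total reads is an error
    (the site is untestable).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("allele counts must be non-negative")
    if count_a + count_b == 0:
        raise ValueError("zero total reads: imbalance is untestable")
    return binomial_two_sided(count_a, count_a + count_b)


def call_ase(expression_reads: pd.DataFrame, sites: pd.DataFrame,
             ase_alpha: float = 1e-7,
             min_base_quality: int = 13) -> pd.DataFrame:
    """Binomial imbalance calls per site per assay (RNA and PolII).

    Only reads carrying one of the site's two alleles count; sites with
    zero retained coverage in an assay are not tested.
    """
    tensors = count_alleles(expression_reads, sites,
                            min_base_quality=min_base_quality,
                            datasets=EXPRESSION_ASSAYS)
    records = []
    for site_id, tensor in tensors.items():
        for j, assay in enumerate(tensor.datasets):
            a = int(tensor.counts[0, j])
            b = int(tensor.counts[1, j])
            if a + b == 0:
                continue
            p = binomial_imbalance_test(a, b)
            records.append({
                "site_id": site_id, "assay": assay,
                "count_a": a, "count_b": b,
                "p_value": p, "significant": p < ase_alpha})
    calls = pd.DataFrame.from_records(
        records, columns=["site_id", "assay", "count_a", "count_b",
                          "p_value", "significant"])
    logger.info("ASE/ASP: tested %d site/assay pairs, %d significant at %g",
                len(calls), int(calls["significant"].sum()), ase_alpha)
    return calls


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Label of one phased haplotype from inversion-marker SNPs."""

    haplotype: int            # 1 or 2 (phasing order)
    label: str                # "H1" | "H2"
    n_markers_used: int
    n_markers_concordant: int

    def __post_init__(self):
        if self.n_markers_concordant > self.n_markers_used:
            raise ValueError("concordant markers exceed markers used")


def assign_inversion_haplotypes(phased_genotypes: pd.DataFrame,
                                marker_table: pd.DataFrame
                                ) -> tuple[HaplotypeAssignment,
                                           HaplotypeAssignment]:
    """Label phased haplotypes H1/H2 by majority vote over marker SNPs.

    Parameters
    ----------
    phased_genotypes
        ``marker_id, hap1_allele, hap2_allele`` — the phased alleles of
        the sample at each marker.
    marker_table
        ``marker_id, h1_allele, h2_allele`` — which allele marks which
        structural haplotype.  Markers whose phased alleles do not match
        the listed pair are dropped (and not counted as used), mirroring
        marker lists that contain unmatched entries.
    """
    merged = phased_genotypes.merge(marker_table, on="marker_id")
    usable = merged[
        merged.apply(lambda r: {r["hap1_allele"], r["hap2_allele"]}
                     == {r["h1_allele"], r["h2_allele"]}, axis=1)]
    n_dropped = len(phased_genotypes) - len(usable)
    if n_dropped:
        logger.info("haplotype assignment: dropped %d unusable marker(s)",
                    n_dropped)
    if usable.empty:
        raise ValueError("no usable inversion markers")
    votes_h1 = int((usable["hap1_allele"] == usable["h1_allele"]).sum())
    n = len(usable)
    hap1_is_h1 = votes_h1 * 2 >= n
    concordant = votes_h1 if hap1_is_h1 else n - votes_h1
    label1, label2 = ("H1", "H2") if hap1_is_h1 else ("H2", "H1")
    return (HaplotypeAssignment(1, label1, n, concordant),
            HaplotypeAssignment(2, label2, n, concordant))
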