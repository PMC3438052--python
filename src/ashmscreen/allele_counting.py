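"""Per-site allele counting and strand-aware methylation extraction.

Read observations (one row per read per site: the base carried, its Phred
quality, the dataset it came from, the strand) become per-site count
tensors of datasets x alleles.  Bases below the quality floor are
ignored; bases matching neither site allele occupy third/fourth allele
rows so the table keeps its "4 x datasets" shape.

Bisulfite conversion turns unmethylated C into T, so a C/T polymorphism
cannot be genotyped from plus-strand bisulfite reads, nor a G/A
polymorphism from minus-strand reads; the extraction drops the ambiguous
strand.  Methylation status is never called at a known polymorphic
position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EXPRESSION_ASSAYS, HISTONE_MODIFICATIONS

logger = logging.getLogger(__name__)

DEFAULT_DATASETS: tuple[str, ...] = HISTONE_MODIFICATIONS + EXPRESSION_ASSAYS
_BASE_ORDER = ("A", "C", "G", "T")


@dataclass
class AlleleCountTensor:
    """Counts of reads per dataset and allele at one site.

    ``alleles`` lists up to four bases: the site's two alleles first, then
    any other observed bases in alphabetical order.  ``counts`` is
    alleles x datasets.
    """

    site_id: str
    alleles: list[str]
    datasets: list[str]
    counts: np.ndarray

    @property
    def total_coverage(self) -> int:
        """Summed reads over the histone-modification datasets only."""
        mod_cols = [j for j, d in enumerate(self.datasets)
                    if d in HISTONE_MODIFICATIONS]
        return int(self.counts[:, mod_cols].sum())

    def restrict_to_site_alleles(self) -> "AlleleCountTensor":
        """Tensor limited to the two validated alleles of the site."""
        return AlleleCountTensor(self.site_id, self.alleles[:2],
                                 self.datasets, self.counts[:2])


def count_alleles(reads: pd.DataFrame, sites: pd.DataFrame,
                  min_base_quality: int = 13,
                  datasets: tuple[str, ...] | None = None,
                  ) -> dict[str, AlleleCountTensor]:
    """Build one allele-count tensor per site from read observations.

    Parameters
    ----------
    reads
        Columns ``site_id, dataset_id, observed_base, base_quality``.
    sites
        Site table providing ``allele_a``/``allele_b`` per ``site_id``.
        Every site gets a tensor, all-zero when uncovered.
    min_base_quality
        Observations below this Phred value are ignored.
    datasets
        Permitted dataset labels, in tensor column order.  Defaults to
        the 23 histone modifications plus RNA and PolII.
    """
    if datasets is None:
        datasets = DEFAULT_DATASETS
    datasets = tuple(datasets)
    unknown = set(reads["dataset_id"].unique()) - set(datasets)
    if unknown:
        raise ValueError(
            f"unknown dataset_id(s) {sorted(unknown)}; permitted labels: "
            f"{list(datasets)}")

    site_ids = sites["site_id"].to_numpy()
    site_index = {s: i for i, s in enumerate(site_ids)}
    ds_index = {d: j for j, d in enumerate(datasets)}
    n, m = len(site_ids), len(datasets)

    # allele row order per site: allele_a, allele_b, remaining bases A<C<G<T
    allele_rows = np.empty((n, 4), dtype=object)
    for i, (a, b) in enumerate(zip(sites["allele_a"], sites["allele_b"])):
        others = [x for x in _BASE_ORDER if x not in (a, b)]
        allele_rows[i] = [a, b, *others]
    row_of_base = np.zeros((n, 4), dtype=np.int8)   # base code -> row
    base_code = {b: k for k, b in enumerate(_BASE_ORDER)}
    for i in range(n):
        for r in range(4):
            row_of_base[i, base_code[allele_rows[i, r]]] = r

    kept = reads[reads["base_quality"] >= min_base_quality]
    counts = np.zeros((n, 4, m), dtype=np.int64)
    if len(kept):
        si = kept["site_id"].map(site_index)
        if si.isna().any():
            missing = kept.loc[si.isna(), "site_id"].unique()
            raise ValueError(
                f"reads reference unknown site_id(s): {sorted(missing)[:5]}")
        si = si.to_numpy(dtype=np.int64)
        dj = kept["dataset_id"].map(ds_index).to_numpy(dtype=np.int64)
        bc = kept["observed_base"].map(base_code).to_numpy(dtype=np.int64)
        rows = row_of_base[si, bc]
        np.add.at(counts, (si, rows, dj), 1)

    return {
        s: AlleleCountTensor(site_id=s, alleles=list(allele_rows[i]),
                             datasets=list(datasets), counts=counts[i])
        for i, s in enumerate(site_ids)}


def ambiguous_strand_mask(sites: pd.DataFrame, strand: pd.Series,
                          site_of_read: pd.Series) -> np.ndarray:
    """True where a bisulfite read's strand cannot genotype its site.

    Plus-strand reads are ambiguous at C/T heterozygotes (unmethylated C
    reads as T); minus-strand reads at G/A heterozygotes (the same
    ambiguity in minus-strand space, expressed in plus-strand alleles).
    """
    pair = sites.set_index("site_id").apply(
        lambda r: "".join(sorted((r["allele_a"], r["allele_b"]))), axis=1)
    pair_of_read = site_of_read.map(pair)
    plus_ambig = (pair_of_read == "CT") & (strand == "+")
    minus_ambig = (pair_of_read == "AG") & (strand == "-")
    return (plus_ambig | minus_ambig).to_numpy()


def extract_methylation_observations(
        bisulfite_reads: pd.DataFrame, sites: pd.DataFrame,
        known_polymorphic_positions: pd.DataFrame,
        min_base_quality: int = 13) -> pd.DataFrame:
    """Allele-linked methylation observations under the exclusion rules.

    Parameters
    ----------
    bisulfite_reads
        Columns ``site_id, strand, observed_base, base_quality, meth_pos,
        methylated`` (1-based methylation query position).
    known_polymorphic_positions
        Frame with ``chrom, pos`` (1-based); methylation is never called
        at these positions.

    Returns
    -------
    DataFrame with ``site_id, strand, allele_carried, pos, methylated,
    base_quality`` — one row per retained read.
    """
    reads = bisulfite_reads[
        bisulfite_reads["base_quality"] >= min_base_quality]
    drop_strand = ambiguous_strand_mask(
        sites, reads["strand"], reads["site_id"])
    reads = reads[~drop_strand]

    chrom_of = sites.set_index("site_id")["chrom"]
    keys = pd.MultiIndex.from_frame(
        pd.DataFrame({"chrom": reads["site_id"].map(chrom_of).to_numpy(),
                      "pos": reads["meth_pos"].to_numpy()}))
    known = pd.MultiIndex.from_frame(
        known_polymorphic_positions[["chrom", "pos"]])
    at_snp = keys.isin(known)
    n_snp = int(at_snp.sum())
    if n_snp:
        logger.info("dropped %d methylation calls at known polymorphic "
                    "positions", n_snp)
    reads = reads[~at_snp]

    return pd.DataFrame({
        "site_id": reads["site_id"].to_numpy(),
        "strand": reads["strand"].to_numpy(),
        "allele_carried": reads["observed_base"].to_numpy(),
        "pos": reads["meth_pos"].to_numpy(),
        "methylated": reads["methylated"].to_numpy(),
        "base_quality": reads["base_quality"].to_numpy()})
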