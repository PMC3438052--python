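"""Configuration objects: simulation parameters and screen-wide thresholds.

All numeric cut-offs used by the callers live in :class:`PipelineThresholds`
so that every stage of the screen applies the same values.  Defaults follow
the published protocol: imputed heterozygote probability >= 0.5, >= 2
bisulfite reads per allele, Phred >= 13 base quality, omnibus ASHM alpha
1e-7, strand-specific ASM alpha 1e-8, ASE/PolII alpha 1e-7, >= 35 summed
ChIP reads for the background set, HWE exclusion below 0.05, and proximity
windows of 10 kb / 250 kb / 500 kb / 1 Mb.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

#: The 23 histone-modification ChIP datasets of the screen.  Names follow
#: standard histone nomenclature; the four Table-style driver marks
#: (H3K4me3, H3K9me3, H3K27me3, H3K36me3) are always present.
HISTONE_MODIFICATIONS: tuple[str, ...] = (
    "H2AK5ac", "H2BK5ac", "H2BK120ac",
    "H3K4me1", "H3K4me2", "H3K4me3",
    "H3K9ac", "H3K9me1", "H3K9me3",
    "H3K14ac", "H3K18ac", "H3K23ac", "H3K23me2",
    "H3K27ac", "H3K27me3", "H3K36me3", "H3K56ac",
    "H3K79me1", "H3K79me2",
    "H4K5ac", "H4K8ac", "H4K20me1", "H4K91ac",
)

RNA_ASSAY = "RNA"
POLII_ASSAY = "PolII"
EXPRESSION_ASSAYS: tuple[str, ...] = (RNA_ASSAY, POLII_ASSAY)

#: Allelic-imbalance patterns of the six ASHM clusters: modifications
#: preferentially associated with allele A vs allele B of a site.
CLUSTER_PATTERNS: dict[int, tuple[frozenset[str], frozenset[str]]] = {
    1: (frozenset({"H3K4me3"}), frozenset()),
    2: (frozenset({"H3K4me3"}), frozenset({"H3K27me3"})),
    3: (frozenset({"H3K27me3"}), frozenset()),
    4: (frozenset({"H3K36me3"}), frozenset()),
    5: (frozenset({"H3K9me3"}), frozenset()),
    6: (frozenset({"H3K9me3"}), frozenset({"H3K36me3"})),
}


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


def _check_prop(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


def _check_pos(name: str, value: float) -> None:
    if value <= 0:
        raise ConfigError(f"{name} must be positive, got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-assay allele-resolved dataset."""

    seed: int = 0
    n_sites: int = 2000
    n_modifications: int = 23
    chrom_length: int = 10_000_000
    chrom: str = "chrS"
    mean_chip_depth: float = 3.0        # reads / site / modification
    # ChIP coverage of a driver mark at a site where it is present on one
    # allele; immunoprecipitation enriches marked loci well above the
    # genomic background, which is what powers the omnibus test.
    driver_chip_depth: float = 150.0
    mean_bis_depth: float = 40.0        # bisulfite reads / strand / site
    mean_rna_depth: float = 80.0        # RNA reads / site
    ashm_fraction: float = 0.03
    cluster_pattern_weights: tuple[float, ...] = (
        1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6)
    skew: float = 0.9                   # driver-modification allele fraction
    occupancy_shift_fraction: float = 0.01
    false_het_fraction: float = 0.02
    asm_fraction: float = 0.05
    cpg_disrupting_fraction: float = 0.8
    epiallele_fraction: float = 0.01
    ase_fraction: float = 0.03
    ase_linked_fraction: float = 0.2
    ase_link_distance: int = 10_000
    sequencing_error_rate: float = 0.002
    # Two-point Phred distribution {quality: probability}; Q10 reads
    # exercise the Phred < 13 exclusion filter.
    base_quality_distribution: dict[int, float] = field(
        default_factory=lambda: {10: 0.1, 30: 0.9})
    epiallele_meth_delta: float = 0.9   # allele methylation difference
    n_imprinted_regions: int = 8
    n_deletion_regions: int = 4
    region_length: int = 20_000
    annotation_enrichment_fold: float = 20.0
    n_population: int = 100             # individuals behind HWE counts

    def __post_init__(self) -> None:
        for name in ("ashm_fraction", "occupancy_shift_fraction",
                     "false_het_fraction", "asm_fraction",
                     "cpg_disrupting_fraction", "epiallele_fraction",
                     "ase_fraction", "ase_linked_fraction", "skew",
                     "sequencing_error_rate", "epiallele_meth_delta"):
            _check_prop(name, getattr(self, name))
        for name in ("n_sites", "n_modifications", "chrom_length",
                     "mean_chip_depth", "driver_chip_depth",
                     "mean_bis_depth", "mean_rna_depth",
                     "ase_link_distance", "n_imprinted_regions",
                     "n_deletion_regions", "region_length",
                     "annotation_enrichment_fold", "n_population"):
            _check_pos(name, getattr(self, name))
        w = tuple(self.cluster_pattern_weights)
        if len(w) != 6:
            raise ConfigError(
                f"cluster_pattern_weights must have 6 entries, got {len(w)}")
        if any(x < 0 for x in w):
            raise ConfigError("cluster_pattern_weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError(
                f"cluster_pattern_weights must sum to 1, got {sum(w)!r}")
        label_mass = (self.ashm_fraction + self.occupancy_shift_fraction
                      + self.asm_fraction + self.epiallele_fraction
                      + self.ase_fraction + self.false_het_fraction)
        if label_mass > 1.0:
            raise ConfigError(
                "label fractions (ashm + occupancy_shift + asm + epiallele "
                f"+ ase + false_het) must sum to <= 1, got {label_mass:.3f}")
        if not self.base_quality_distribution:
            raise ConfigError("base_quality_distribution must be non-empty")
        qsum = sum(self.base_quality_distribution.values())
        if abs(qsum - 1.0) > 1e-9:
            raise ConfigError(
                f"base_quality_distribution must sum to 1, got {qsum!r}")
        if any(q < 0 for q in self.base_quality_distribution):
            raise ConfigError("base_quality_distribution has a negative Phred")
        if not 2 <= self.n_modifications <= len(HISTONE_MODIFICATIONS):
            raise ConfigError(
                "n_modifications must be in "
                f"[2, {len(HISTONE_MODIFICATIONS)}], got {self.n_modifications}")

    @property
    def modifications(self) -> tuple[str, ...]:
        mods = HISTONE_MODIFICATIONS[: self.n_modifications]
        required = {"H3K4me3", "H3K9me3", "H3K27me3", "H3K36me3"}
        if not required <= set(mods):
            # keep the four cluster-driver marks available at any width
            mods = tuple(sorted(required)) + tuple(
                m for m in mods if m not in required)[: self.n_modifications - 4]
        return mods


@dataclass
class PipelineThresholds:
    """Every numeric cut-off applied by the screen."""

    p_het_min: float = 0.5
    min_bis_reads_per_allele: int = 2
    min_base_quality: int = 13
    ashm_alpha: float = 1e-7
    asm_alpha: float = 1e-8
    ase_alpha: float = 1e-7
    min_chip_coverage: int = 35
    hwe_alpha: float = 0.05
    windows: tuple[int, ...] = (10_000, 250_000, 500_000, 1_000_000)
    adjacency_bp: int = 1
    driver_p_threshold: float = 0.01
    exact_node_budget: int = 3_000_000

    def __post_init__(self) -> None:
        for name in ("ashm_alpha", "asm_alpha", "ase_alpha", "hwe_alpha",
                     "driver_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v!r}")
        _check_prop("p_het_min", self.p_het_min)
        for name in ("min_bis_reads_per_allele", "min_chip_coverage",
                     "exact_node_budget"):
            _check_pos(name, getattr(self, name))
        if self.min_base_quality < 0:
            raise ConfigError("min_base_quality must be >= 0")
        if self.adjacency_bp < 0:
            raise ConfigError("adjacency_bp must be >= 0")
        if any(w <= 0 for w in self.windows):
            raise ConfigError("windows must be positive")


def _coerce(cls_field: dataclasses.Field, value):
    if cls_field.name == "cluster_pattern_weights" and isinstance(value, list):
        return tuple(float(x) for x in value)
    if cls_field.name == "windows" and isinstance(value, list):
        return tuple(int(x) for x in value)
    if cls_field.name == "base_quality_distribution" and isinstance(value, dict):
        return {int(k): float(v) for k, v in value.items()}
    return value


def _build(cls, raw: Mapping, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")
        kwargs[key] = _coerce(fields[key], value)
    try:
        return cls(**kwargs)
    except TypeError as exc:  # wrong type passed through
        raise ConfigError(f"bad value in section {section!r}: {exc}") from exc


def load_config(path) -> tuple[SimulationConfig, PipelineThresholds]:
    """Load a YAML config with optional ``simulation`` / ``thresholds``
    sections; absent keys take their defaults.  Unknown keys are an error.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a key-value mapping")
    known_sections = {"simulation", "thresholds"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"expected {sorted(known_sections)}")
    sim = _build(SimulationConfig, raw.get("simulation") or {}, "simulation")
    thr = _build(PipelineThresholds, raw.get("thresholds") or {}, "thresholds")
    logger.info("resolved simulation config: %s", sim)
    logger.info("resolved thresholds: %s", thr)
    return sim, thr
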