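"""End-to-end orchestration of the screen with consistent thresholds.

Stage order mirrors the protocol: heterozygote validation from bisulfite
support -> allele counting -> ASM, ASHM, ASE/ASP calling -> clustering of
significant ASHM sites -> proximity enrichment against annotation tracks.
Every output TSV carries provenance header lines (package version, seed,
resolved thresholds); a rerun with identical inputs and seed is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .allele_counting import count_alleles, extract_methylation_observations
from .ase_caller import call_ase
from .ashm_caller import call_ashm, coverage_qc
from .asm_caller import annotate_adjacent_polymorphism, call_asm
from .clustering import (
    build_imbalance_profiles,
    choose_cut_and_drivers,
    cluster_sites,
    serialize_dendrogram,
)
from .config import (
    HISTONE_MODIFICATIONS,
    PipelineThresholds,
    RNA_ASSAY,
    SimulationConfig,
)
from .enrichment import proximity_enrichment
from .het_validation import (
    bisulfite_allele_support,
    evaluate_het_calls,
    filter_het_sites,
)
from .synthetic import SimulatedDataset, read_fixtures, simulate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    validated_sites: pd.DataFrame
    asm_calls: pd.DataFrame
    ashm_calls: pd.DataFrame
    ashm_per_modification: pd.DataFrame
    background_site_ids: list[str]
    ase_calls: pd.DataFrame
    cluster_assignments: pd.DataFrame | None
    cluster_drivers: pd.DataFrame | None
    dendrogram: str | None
    enrichment: pd.DataFrame
    het_performance: dict | None = None
    output_files: dict[str, Path] = field(default_factory=dict)


def _header(config: SimulationConfig | None,
            thresholds: PipelineThresholds) -> list[str]:
    lines = [f"ashm-screen {__version__}"]
    if config is not None:
        lines.append(f"seed {config.seed}")
    lines.append(f"thresholds {thresholds}")
    return lines


def run_pipeline(config: SimulationConfig,
                 thresholds: PipelineThresholds | None = None,
                 input_dir: str | Path | None = None,
                 output_dir: str | Path | None = None,
                 dataset: SimulatedDataset | None = None) -> PipelineResult:
    """Run every stage of the screen.

    Inputs come from ``dataset`` (in memory), ``input_dir`` (fixture
    files) or, failing both, a fresh simulation from ``config``.
    """
    thresholds = thresholds or PipelineThresholds()
    if dataset is None:
        if input_dir is not None:
            try:
                dataset = read_fixtures(input_dir)
            except Exception as exc:
                raise StageError("load-inputs", exc) from exc
        else:
            try:
                dataset = simulate_dataset(config)
            except Exception as exc:
                raise StageError("simulate", exc) from exc

    # ---- heterozygote validation -------------------------------------
    try:
        support = bisulfite_allele_support(
            dataset.bis_reads, dataset.sites,
            min_base_quality=thresholds.min_base_quality)
        validated = filter_het_sites(
            dataset.sites, support, p_min=thresholds.p_het_min,
            min_reads_per_allele=thresholds.min_bis_reads_per_allele)
    except Exception as exc:
        raise StageError("validate-hets", exc) from exc
    logger.info("validate-hets: %d candidates -> %d validated",
                len(dataset.sites), len(validated))
    perf = None
    if dataset.truth is not None and len(dataset.truth):
        p = evaluate_het_calls(validated, dataset.truth)
        perf = {"tp": p.tp, "fp": p.fp, "tn": p.tn, "fn": p.fn,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity, "ppv": p.ppv}
        logger.info("het calling vs truth: sens %.3f spec %.3f ppv %.3f",
                    p.sensitivity, p.specificity, p.ppv)

    valid_ids = set(validated["site_id"])

    # ---- allele counting ---------------------------------------------
    try:
        chip = dataset.chip_reads[
            dataset.chip_reads["site_id"].isin(valid_ids)]
        tensors = count_alleles(
            chip, validated, min_base_quality=thresholds.min_base_quality,
            datasets=HISTONE_MODIFICATIONS)
        methyl_obs = extract_methylation_observations(
            dataset.bis_reads[dataset.bis_reads["site_id"].isin(valid_ids)],
            validated, dataset.known_polymorphic,
            min_base_quality=thresholds.min_base_quality)
    except Exception as exc:
        raise StageError("count-alleles", exc) from exc

    # ---- ASM ----------------------------------------------------------
    try:
        asm = call_asm(methyl_obs, validated,
                       asm_alpha=thresholds.asm_alpha)
        asm = annotate_adjacent_polymorphism(
            asm, dataset.sites, max_distance=thresholds.adjacency_bp)
    except Exception as exc:
        raise StageError("call-asm", exc) from exc

    # ---- ASHM ---------------------------------------------------------
    try:
        ashm, per_mod, background = call_ashm(
            tensors, ashm_alpha=thresholds.ashm_alpha,
            min_total_coverage=thresholds.min_chip_coverage,
            node_budget=thresholds.exact_node_budget,
            population_genotypes=dataset.population_genotypes,
            hwe_alpha=thresholds.hwe_alpha,
            bis_reads=dataset.bis_reads)
    except Exception as exc:
        raise StageError("call-ashm", exc) from exc

    # ---- ASE / PolII --------------------------------------------------
    try:
        expr = dataset.expression_reads[
            dataset.expression_reads["site_id"].isin(valid_ids)]
        ase = call_ase(expr, validated, ase_alpha=thresholds.ase_alpha,
                       min_base_quality=thresholds.min_base_quality)
    except Exception as exc:
        raise StageError("call-ase", exc) from exc

    # ---- clustering ---------------------------------------------------
    assignments = drivers = dendro = None
    sig_ids = ashm.loc[ashm["significant"], "site_id"]
    if len(sig_ids) >= 2:
        try:
            profiles = build_imbalance_profiles(
                per_mod, tuple(HISTONE_MODIFICATIONS))
            result = cluster_sites(profiles)
            result = choose_cut_and_drivers(
                result, profiles,
                driver_p_threshold=thresholds.driver_p_threshold)
            assignments = pd.DataFrame({"site_id": result.site_ids,
                                        "cluster": result.labels})
            drivers = result.driver_table()
            dendro = serialize_dendrogram(result)
        except Exception as exc:
            raise StageError("cluster", exc) from exc

    # ---- enrichment ---------------------------------------------------
    try:
        pos_of = dataset.sites.set_index("site_id")[["chrom", "pos"]]
        bg_sites = pos_of.loc[[s for s in background]].reset_index()
        call_sets = {"ashm": sig_ids,
                     "asm": asm.loc[asm["significant"], "site_id"].unique(),
                     "ase": ase.loc[ase["significant"]
                                    & (ase["assay"] == RNA_ASSAY),
                                    "site_id"]}
        rows = []
        for name, ids in call_sets.items():
            ids = [s for s in ids if s in pos_of.index]
            if not ids:
                continue
            fg_sites = pos_of.loc[ids].reset_index()
            for track, grp in dataset.annotations.groupby("track"):
                for window in thresholds.windows:
                    res = proximity_enrichment(fg_sites, bg_sites, grp,
                                               window)
                    rows.append({
                        "call_set": name, "track": track,
                        "window": window, "fg_in": res.fg_in,
                        "fg_total": res.fg_total, "bg_in": res.bg_in,
                        "bg_total": res.bg_total,
                        "fg_prop": res.fg_prop, "bg_prop": res.bg_prop,
                        "fold": res.fold, "p_value": res.p_value,
                        "test": res.test})
        enrich = pd.DataFrame.from_records(rows, columns=[
            "call_set", "track", "window", "fg_in", "fg_total", "bg_in",
            "bg_total", "fg_prop", "bg_prop", "fold", "p_value", "test"])
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    result = PipelineResult(
        validated_sites=validated, asm_calls=asm, ashm_calls=ashm,
        ashm_per_modification=per_mod, background_site_ids=background,
        ase_calls=ase, cluster_assignments=assignments,
        cluster_drivers=drivers, dendrogram=dendro, enrichment=enrich,
        het_performance=perf)

    if output_dir is not None:
        result.output_files = _write_outputs(result, Path(output_dir),
                                             config, thresholds)
    return result


def _write_outputs(result: PipelineResult, output_dir: Path,
                   config, thresholds) -> dict[str, Path]:
    output_dir.mkdir(parents=True, exist_ok=True)
    header = _header(config, thresholds)
    frames = {
        "validated_sites.tsv": result.validated_sites,
        "asm_calls.tsv": result.asm_calls,
        "ashm_calls.tsv": result.ashm_calls,
        "ashm_per_modification.tsv": result.ashm_per_modification,
        "ase_calls.tsv": result.ase_calls,
        "enrichment.tsv": result.enrichment,
    }
    if result.cluster_assignments is not None:
        frames["clusters.tsv"] = result.cluster_assignments
        frames["drivers.tsv"] = result.cluster_drivers
    paths = {}
    for fname, df in frames.items():
        paths[fname] = io.write_table(df, output_dir / fname,
                                      header_lines=header)
    if result.dendrogram is not None:
        p = output_dir / "dendrogram.txt"
        p.write_text(result.dendrogram + "\n")
        paths["dendrogram.txt"] = p
    bg = output_dir / "background_sites.txt"
    bg.write_text("".join(f"{s}\n" for s in result.background_site_ids))
    paths["background_sites.txt"] = bg
    return paths
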