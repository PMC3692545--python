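"""End-to-end orchestration: filter -> intersect -> ortholog consensus ->
tier classification -> emPAI ranking -> rank shift -> differential abundance
-> candidate pooling -> enrichment -> biomarker overlap.

All stage outputs are TSV files in the configured output directory plus a
JSON summary of every stage count.  Runs are deterministic for a fixed
configuration.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diffabund, empai, enrich as enrich_mod, orthology, rankshift, tiers
from .errors import InputError, PipelineStageError
from .formats import (
    IdentificationTable,
    filter_by_peptides,
    intersect_samples,
    pool_reference_sets,
    read_fasta,
    read_gene_set,
    read_id_map,
    read_identification_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one full analysis run."""

    proteome: str
    profiling_samples: list[str]          # >=2 deep-profiled perfusion urine tables
    reference_urine: str                  # normal-urine identification table
    manifest: str                         # sample_id / condition / rat for the diff stage
    identification_dir: str               # directory holding <sample_id>.tsv for the manifest
    ortholog_maps: list[str]              # one TSV per database
    kidney_set: str
    urine_set: str
    exosome_set: str
    plasma_set: str
    prior_biomarkers: str
    annotations: str
    term_edges: str
    outdir: str = "results"
    min_distinct: int = 2
    min_support: int = 2
    rank_threshold: int | str = rankshift.DEFAULT_THRESHOLD  # int or "calibrated"
    calibration_coverage: float = rankshift.DEFAULT_COVERAGE
    diff_alpha: float = 0.05
    enrich_alpha: float = 0.001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "proteome": self.proteome,
            "reference_urine": self.reference_urine,
            "manifest": self.manifest,
            "kidney_set": self.kidney_set,
            "urine_set": self.urine_set,
            "exosome_set": self.exosome_set,
            "plasma_set": self.plasma_set,
            "prior_biomarkers": self.prior_biomarkers,
            "annotations": self.annotations,
            "term_edges": self.term_edges,
        }
        for i, p in enumerate(self.profiling_samples):
            paths[f"profiling_sample_{i}"] = p
        for p in self.ortholog_maps:
            paths[f"ortholog_map:{Path(p).stem}"] = p
        return paths


@dataclass
class ValidationFinding:
    level: str  # "fatal" or "warning"
    target: str
    message: str


def validate_inputs(config: PipelineConfig) -> list[ValidationFinding]:
    """Report-only validation: existence, headers, duplicate identifiers."""
    findings: list[ValidationFinding] = []
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            findings.append(ValidationFinding("fatal", name, f"missing file: {p}"))
    if findings:
        return findings

    for p in [*config.profiling_samples, config.reference_urine]:
        try:
            read_identification_table(p)
        except (InputError, Exception) as exc:  # malformed header or duplicates
            findings.append(ValidationFinding("fatal", str(p), str(exc)))
    for p in config.ortholog_maps:
        df = pd.read_csv(p, sep="\t", nrows=5)
        if df.shape[1] < 2:
            findings.append(ValidationFinding(
                "fatal", str(p), "ortholog map needs two columns (rat_protein, human_gene)"))
    manifest = pd.read_csv(config.manifest, sep="\t")
    for col in ("sample_id", "condition", "rat"):
        if col not in manifest.columns:
            findings.append(ValidationFinding("fatal", config.manifest, f"missing column {col!r}"))
    if not findings:
        for sid in manifest["sample_id"]:
            if not (Path(config.identification_dir) / f"{sid}.tsv").exists():
                findings.append(ValidationFinding(
                    "fatal", config.identification_dir, f"no identification table for {sid}"))
    if not 1 <= config.min_support <= max(1, len(config.ortholog_maps)):
        findings.append(ValidationFinding(
            "fatal", "min_support",
            f"min_support={config.min_support} but only {len(config.ortholog_maps)} maps"))
    if isinstance(config.rank_threshold, str) and config.rank_threshold != "calibrated":
        findings.append(ValidationFinding(
            "fatal", "rank_threshold", "must be a positive integer or 'calibrated'"))
    return findings


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the summary dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"parameters": {
        "min_distinct": config.min_distinct, "min_support": config.min_support,
        "rank_threshold": config.rank_threshold,
        "calibration_coverage": config.calibration_coverage,
        "diff_alpha": config.diff_alpha, "enrich_alpha": config.enrich_alpha,
    }}

    fatal = [f for f in validate_inputs(config) if f.level == "fatal"]
    if fatal:
        raise PipelineStageError("validate", "; ".join(f"{f.target}: {f.message}" for f in fatal))

    # --- load + filter + intersect -------------------------------------
    @_stage("filter")
    def load_and_filter():
        tables = [read_identification_table(p) for p in config.profiling_samples]
        filtered = [filter_by_peptides(t, config.min_distinct) for t in tables]
        for raw, f in zip(tables, filtered):
            logger.info("filter: %s %d -> %d records", raw.sample_id, len(raw), len(f))
        return filtered

    filtered = load_and_filter()
    summary["profiling_identified"] = {t.sample_id: len(t) for t in filtered}
    common = intersect_samples(filtered)
    summary["common_proteins"] = len(common)
    logger.info("intersect: %d proteins common to all profiling samples", len(common))

    # --- ortholog consensus --------------------------------------------
    @_stage("orthologs")
    def consensus():
        maps = {Path(p).stem: read_id_map(p).rename(
            columns={"protein_accession": "rat_protein", "gene_id": "human_gene"})
            for p in config.ortholog_maps}
        return orthology.consensus_orthologs(maps, config.min_support)

    pairs = consensus()
    pairs.to_csv(outdir / "consensus_orthologs.tsv", sep="\t", index=False)
    pairs_common = pairs[pairs["rat_protein"].isin(common)].reset_index(drop=True)
    ortholog_genes = orthology.orthologs_to_gene_set(pairs_common)
    summary["consensus_pairs"] = len(pairs)
    summary["paired_common_proteins"] = int(pairs_common["rat_protein"].nunique())
    summary["ortholog_genes"] = len(ortholog_genes)

    # --- tier classification -------------------------------------------
    @_stage("tiers")
    def classify():
        kidney = read_gene_set(config.kidney_set, "kidney")
        urine = read_gene_set(config.urine_set, "urine")
        exo = read_gene_set(config.exosome_set, "exosome")
        plasma = read_gene_set(config.plasma_set, "plasma")
        urine_exo = pool_reference_sets([urine, exo], "urine_exo")
        return tiers.classify_tiers(ortholog_genes, kidney, urine_exo, plasma), urine_exo, plasma

    tier_report, urine_exo, plasma = classify()
    tier_report.table.to_csv(outdir / "tiers.tsv", sep="\t", index=False)
    summary["tiers"] = tier_report.counts()

    # --- emPAI ranking ---------------------------------------------------
    @_stage("empai")
    def gene_ranks():
        proteome = read_fasta(config.proteome)
        params = empai.DigestParams()
        universe = tier_report.kidney_origin
        reference = read_identification_table(config.reference_urine)

        def ranks_for(table: IdentificationTable) -> dict[str, int]:
            recs = empai.empai_table(proteome, table.records, params)
            gene_recs = empai.gene_level_empai(recs, pairs)
            gene_recs = gene_recs[gene_recs["gene_id"].isin(universe)]
            return empai.rank_by_empai(gene_recs, universe, id_column="gene_id")

        ref_ranks = ranks_for(reference)
        perf_ranks = {}
        for p in config.profiling_samples:
            table = filter_by_peptides(read_identification_table(p), config.min_distinct)
            restricted = table.records[table.records["protein_accession"].isin(common)]
            perf_ranks[table.sample_id] = empai.rank_by_empai(
                empai.gene_level_empai(
                    empai.empai_table(proteome, restricted, params), pairs,
                ).pipe(lambda df: df[df["gene_id"].isin(universe)]),
                universe, id_column="gene_id")
        return ref_ranks, perf_ranks

    ref_ranks, perf_ranks = gene_ranks()
    rank_df = pd.DataFrame({"gene_id": sorted(ref_ranks)})
    rank_df["rank_reference"] = rank_df["gene_id"].map(ref_ranks)
    for sid, ranks in sorted(perf_ranks.items()):
        rank_df[f"rank_{sid}"] = rank_df["gene_id"].map(ranks)
    rank_df.to_csv(outdir / "gene_ranks.tsv", sep="\t", index=False)

    # --- rank shift ------------------------------------------------------
    @_stage("rankshift")
    def shift():
        sids = sorted(perf_ranks)
        rep_changes = [perf_ranks[sids[0]][g] - perf_ranks[sids[1]][g] for g in ref_ranks]
        if config.rank_threshold == "calibrated":
            threshold = rankshift.calibrate_threshold(rep_changes, config.calibration_coverage)
        else:
            threshold = int(config.rank_threshold)
        logger.info("rankshift: threshold %d", threshold)
        table = rankshift.rank_shift(ref_ranks, perf_ranks, threshold)
        return table, threshold

    shift_table, threshold = shift()
    shift_table.to_csv(outdir / "rank_shift.tsv", sep="\t", index=False)
    shifted = rankshift.significant_genes(shift_table)
    summary["rank_threshold_used"] = threshold
    summary["rank_shifted"] = len(shifted)
    summary["rank_shifted_partition"] = rankshift.tier_annotate_shifted(shifted, urine_exo, plasma)

    # --- differential abundance -----------------------------------------
    @_stage("diffabund")
    def differential():
        manifest = pd.read_csv(config.manifest, sep="\t", dtype=str)
        tables = {
            sid: read_identification_table(
                Path(config.identification_dir) / f"{sid}.tsv").records
            for sid in manifest["sample_id"]
        }
        cm = diffabund.build_condition_matrix(tables, manifest)
        result = diffabund.differential_test(diffabund.normalize_counts(cm), config.diff_alpha)
        sig = set(result.loc[result["significant"], "protein_accession"])
        return result, diffabund.map_diff_to_orthologs(sig, pairs)

    diff_table, hypoxia_genes = differential()
    diff_table.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    summary["hypoxia_increased_proteins"] = int(diff_table["significant"].sum())
    summary["hypoxia_increased_genes"] = len(hypoxia_genes)

    # --- candidate pooling + biomarker overlap ---------------------------
    @_stage("candidates")
    def pool():
        cand = tiers.pool_candidates(tier_report, hypoxia_genes, shifted)
        prior = read_gene_set(config.prior_biomarkers, "prior_biomarkers")
        return cand, tiers.biomarker_overlap(set(cand["gene_id"]), prior)

    candidates, overlap = pool()
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    summary["candidate_pool"] = len(candidates)
    summary["high_quality_candidates"] = int(candidates["high_quality"].sum())
    summary["biomarker_overlap"] = overlap.counts()

    # --- enrichment -------------------------------------------------------
    @_stage("enrich")
    def enrichment():
        ann = pd.read_csv(config.annotations, sep="\t", dtype=str)
        edges = pd.read_csv(config.term_edges, sep="\t", dtype=str)
        universe = set(ann["gene_id"])
        study = set(candidates["gene_id"]) & universe
        dropped = len(candidates) - len(study)
        if dropped:
            logger.warning("enrich: %d candidates lack annotations and are excluded", dropped)
        return enrich_mod.enrich(study, universe, ann, edges, config.enrich_alpha)

    enr = enrichment()
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    summary["enriched_terms"] = int(enr["significant"].sum()) if len(enr) else 0
    summary["tested_terms"] = len(enr)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
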