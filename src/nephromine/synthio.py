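"""Synthetic study generator.

Emulates the inputs of an isolated-kidney perfusion urine proteomics study:
a rat protein database (FASTA), per-sample identification tables (distinct
peptide and spectral counts), several disagreeing rat->human ortholog
mapping tables, reference gene sets (kidney expression, normal urine,
urinary exosome, plasma, prior biomarkers), a toy annotation DAG, and a
truth table recording every planted effect.

The generative model:

* per-protein reference-urine abundance baselines are log-normal (median 50
  spectral counts, sigma 1 on the log scale);
* spectral counts are negative-binomial around the baseline with dispersion
  ``alpha`` (variance mu + alpha*mu^2), the standard overdispersed model for
  replicate spectral counting;
* hypoxia-increased proteins have their no-oxygen expected counts multiplied
  by ``hypoxia_fold_change`` in every rat;
* rank-shifted proteins get an elevated perfusion baseline relative to their
  reference-urine baseline; they are drawn from the lower tail of reference
  abundance (``rankshift_low_quantile``), since a protein already at the top
  of the normal-urine ranking has no room to shift up (and the method
  targets proteins scarce in normal urine);
* the reference-urine sample is drawn at ``reference_depth_factor`` times
  the baselines, emulating a deeply profiled normal-urine compendium.

Every generator is a pure function of (config, seed): identical
configuration yields byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .formats import (
    IdentificationTable,
    ReferenceSet,
    write_fasta,
    write_gene_set,
    write_identification_table,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# fixed sub-stream offsets so each generator stage has an independent,
# reproducible random stream derived from the one user-facing seed
_STREAMS = {
    "proteome": 1, "baselines": 2, "pairing": 3, "flags": 4,
    "identifications": 5, "orthologs": 6, "refsets": 7,
    "annotations": 8, "biomarkers": 9,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design being emulated: four rats, each
    perfused with and without oxygen; five ortholog databases; a 3-fold
    hypoxia effect; a 613/240/71/57 urine-plasma Venn partition over the
    kidney-expressed orthologs.
    """

    seed: int = 0
    n_proteins: int = 1000
    n_samples_per_condition: int = 4
    ortholog_db_count: int = 5
    ortholog_agreement: float = 0.8
    ortholog_noise: float = 0.01
    venn_partition: tuple[int, int, int, int] = (613, 240, 71, 57)
    planted_hypoxia_fraction: float = 0.05
    hypoxia_fold_change: float = 3.0
    planted_rankshift_fraction: float = 0.05
    rankshift_multiplier: float = 30.0
    rankshift_low_quantile: float = 0.5
    reference_depth_factor: float = 5.0
    spectral_noise_dispersion: float = 0.05
    baseline_log_median: float = 50.0
    baseline_log_sigma: float = 1.0
    min_protein_length: int = 100
    max_protein_length: int = 600
    multi_gene_fraction: float = 0.03
    background_genes_per_set: int = 200

    def __post_init__(self) -> None:
        self.venn_partition = tuple(int(v) for v in self.venn_partition)
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.n_samples_per_condition < 1:
            raise ConfigurationError("n_samples_per_condition must be >= 1")
        if self.ortholog_db_count < 1:
            raise ConfigurationError("ortholog_db_count must be >= 1")
        for name in ("ortholog_agreement", "ortholog_noise", "rankshift_low_quantile",
                     "planted_hypoxia_fraction", "planted_rankshift_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        if self.hypoxia_fold_change <= 0 or self.rankshift_multiplier <= 0:
            raise ConfigurationError("fold changes must be positive")
        if self.spectral_noise_dispersion <= 0:
            raise ConfigurationError("spectral_noise_dispersion must be positive")
        if self.reference_depth_factor <= 0:
            raise ConfigurationError("reference_depth_factor must be positive")
        if len(self.venn_partition) != 4 or any(v < 0 for v in self.venn_partition):
            raise ConfigurationError("venn_partition must be four non-negative counts")
        if sum(self.venn_partition) > self.n_proteins:
            raise ConfigurationError("sum of venn_partition exceeds n_proteins")
        if not 1 <= self.min_protein_length <= self.max_protein_length:
            raise ConfigurationError("invalid protein length range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


def _accessions(config: SimulationConfig) -> list[str]:
    return [f"RATP{i:05d}" for i in range(config.n_proteins)]


# ---------------------------------------------------------------------------
# proteome


def generate_proteome(config: SimulationConfig) -> dict[str, str]:
    """Random protein sequences over the 20 standard residues.

    Lengths are uniform on [min_protein_length, max_protein_length]; each
    sequence carries a unique accession.
    """
    rng = _rng(config, "proteome")
    lengths = rng.integers(config.min_protein_length, config.max_protein_length + 1,
                           size=config.n_proteins)
    return {
        acc: "".join(AMINO_ACIDS[rng.integers(0, 20, size=length)])
        for acc, length in zip(_accessions(config), lengths)
    }


# ---------------------------------------------------------------------------
# true ortholog pairing


def true_pairing(config: SimulationConfig) -> pd.DataFrame:
    """The ground-truth rat-protein -> human-gene pairing (many-to-many).

    Mostly one-to-one; a small fraction of proteins map to a second gene,
    mirroring the ortholog/co-ortholog expansion real databases show.
    """
    rng = _rng(config, "pairing")
    rows = []
    for i, acc in enumerate(_accessions(config)):
        rows.append((acc, f"HG{i:05d}"))
        if rng.random() < config.multi_gene_fraction:
            rows.append((acc, f"HG{i:05d}B"))
    return pd.DataFrame(rows, columns=["rat_protein", "human_gene"])


def gene_universe(config: SimulationConfig) -> list[str]:
    return sorted(set(true_pairing(config)["human_gene"]))


# ---------------------------------------------------------------------------
# abundance baselines and planted flags


def protein_baselines(config: SimulationConfig) -> np.ndarray:
    """Per-protein expected reference-urine spectral counts (log-normal)."""
    rng = _rng(config, "baselines")
    return config.baseline_log_median * np.exp(
        rng.normal(0.0, config.baseline_log_sigma, size=config.n_proteins))


def planted_flags(config: SimulationConfig) -> pd.DataFrame:
    """Per-protein hypoxia-increased and rank-shifted truth flags.

    Exactly round(fraction * n_proteins) proteins carry each flag; the two
    sets are drawn disjointly so each planted effect is tested cleanly.
    Rank-shift flags go to proteins below the ``rankshift_low_quantile`` of
    reference abundance: a protein already at the top of the normal-urine
    ranking has no room to shift up.
    """
    rng = _rng(config, "flags")
    n = config.n_proteins
    n_hyp = round(config.planted_hypoxia_fraction * n)
    n_shift = round(config.planted_rankshift_fraction * n)
    baselines = protein_baselines(config)
    order = np.argsort(baselines)  # ascending abundance
    low = order[: max(1, int(config.rankshift_low_quantile * n))]
    shift_pool = low if len(low) >= n_shift else order
    shift_idx = set(rng.choice(shift_pool, size=min(n_shift, len(shift_pool)), replace=False))
    remaining = np.array(sorted(set(range(n)) - shift_idx))
    hyp_idx = set(rng.choice(remaining, size=min(n_hyp, len(remaining)), replace=False))
    return pd.DataFrame({
        "protein_accession": _accessions(config),
        "baseline": baselines,
        "hypoxia_increased": [i in hyp_idx for i in range(n)],
        "rank_shifted": [i in shift_idx for i in range(n)],
    })


# ---------------------------------------------------------------------------
# identification tables


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


COVERAGE_HALF_SATURATION = 100.0  # spectra at which half the peptide capacity is covered


def _distinct_peptides(rng: np.random.Generator, spectral: np.ndarray,
                       caps: np.ndarray) -> np.ndarray:
    """Distinct peptide counts from a sequence-coverage model.

    A protein with spectral count s covers each of its ``caps`` candidate
    peptides independently with probability s / (s + half-saturation), so
    expected coverage saturates with abundance and scales with protein size —
    the relationship emPAI quantitation relies on.  An identified protein
    (s > 0) always has at least one peptide.
    """
    p = spectral / (spectral + COVERAGE_HALF_SATURATION)
    base = 1 + rng.binomial(np.maximum(caps - 1, 0), p)
    return np.where(spectral > 0, np.minimum(base, caps), 0)


def generate_identifications(
    proteome: Mapping[str, str],
    config: SimulationConfig,
) -> tuple[dict[str, IdentificationTable], pd.DataFrame]:
    """Identification tables for every sample plus the planted-effect truth table.

    Samples: one pooled reference-urine sample, plus one oxygen and one
    no-oxygen perfusion sample per rat.  A protein appears in a sample when
    its drawn spectral count is positive.  The reference sample emulates a
    deeply profiled normal-urine compendium: its expected counts are the
    baselines scaled by ``reference_depth_factor`` (uniform scaling keeps the
    abundance ordering but reduces dropout and rank noise).
    """
    if not proteome:
        raise ConfigurationError("empty proteome")
    from . import empai as _empai  # local import: synthio is otherwise upstream of empai

    rng = _rng(config, "identifications")
    flags = planted_flags(config)
    accs = np.array(flags["protein_accession"])
    mu_ref = flags["baseline"].to_numpy()
    shifted = flags["rank_shifted"].to_numpy()
    hypoxic = flags["hypoxia_increased"].to_numpy()
    mu_perf = np.where(shifted, mu_ref * config.rankshift_multiplier, mu_ref)
    alpha = config.spectral_noise_dispersion
    # peptide capacity = instrument-observable peptides, the coverage
    # denominator emPAI uses; degenerate proteins keep a capacity of 1
    params = _empai.DigestParams()
    caps = []
    for a in accs:
        try:
            caps.append(_empai.count_observable(_empai.digest(proteome[a], 0), params))
        except _empai.DegenerateProteinError:
            caps.append(1)
    caps = np.array(caps)

    def make_table(sample_id: str, mu: np.ndarray) -> IdentificationTable:
        spectral = _nb_counts(rng, mu, alpha)
        distinct = _distinct_peptides(rng, spectral, caps)
        present = spectral > 0
        df = pd.DataFrame({
            "protein_accession": accs[present],
            "distinct_peptides": distinct[present],
            "spectral_count": spectral[present],
            "observed_peptides": "",
        })
        return IdentificationTable(sample_id, df)

    tables = {"reference_urine": make_table(
        "reference_urine", mu_ref * config.reference_depth_factor)}
    fold = config.hypoxia_fold_change
    for r in range(1, config.n_samples_per_condition + 1):
        tables[f"oxygen_r{r}"] = make_table(f"oxygen_r{r}", mu_perf)
        mu_noo = np.where(hypoxic, mu_perf * fold, mu_perf)
        tables[f"no_oxygen_r{r}"] = make_table(f"no_oxygen_r{r}", mu_noo)
    truth = flags.drop(columns="baseline")
    return tables, truth


def sample_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Condition/rat manifest of the perfusion samples (reference urine excluded)."""
    rows = []
    for r in range(1, config.n_samples_per_condition + 1):
        rows.append((f"oxygen_r{r}", "oxygen", f"r{r}"))
        rows.append((f"no_oxygen_r{r}", "no_oxygen", f"r{r}"))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "rat"])


# ---------------------------------------------------------------------------
# ortholog maps


def generate_ortholog_maps(
    proteome: Mapping[str, str],
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """K noisy ortholog mapping tables around the true pairing.

    Each database reports each true pair with probability
    ``ortholog_agreement`` and, per protein, adds a spurious pair to a random
    wrong gene with probability ``ortholog_noise``.
    """
    rng = _rng(config, "orthologs")
    truth = true_pairing(config)
    genes = np.array(sorted(set(truth["human_gene"])))
    maps: dict[str, pd.DataFrame] = {}
    for d in range(1, config.ortholog_db_count + 1):
        keep = rng.random(len(truth)) < config.ortholog_agreement
        reported = truth[keep]
        spurious_rows = []
        for acc in _accessions(config):
            if rng.random() < config.ortholog_noise:
                spurious_rows.append((acc, str(rng.choice(genes))))
        spurious = pd.DataFrame(spurious_rows, columns=["rat_protein", "human_gene"])
        df = (pd.concat([reported, spurious], ignore_index=True)
              .drop_duplicates().reset_index(drop=True))
        maps[f"db{d}"] = df
    return maps


# ---------------------------------------------------------------------------
# reference sets


@dataclass
class VennFixture:
    """Reference sets inducing an exact four-way partition over an ortholog list."""

    ortholog_genes: list[str]
    kidney: ReferenceSet
    urine_exo: ReferenceSet
    plasma: ReferenceSet


def build_paper_venn_fixture(
    partition: tuple[int, int, int, int],
    prefix: str = "G",
) -> VennFixture:
    """Deterministic gene lists whose urine/plasma Venn partition over the
    kidney-expressed orthologs equals ``partition`` = (both, urine-only,
    plasma-only, neither) exactly.
    """
    both, urine_only, plasma_only, neither = (int(v) for v in partition)
    if min(both, urine_only, plasma_only, neither) < 0:
        raise ConfigurationError("partition counts must be non-negative")
    total = both + urine_only + plasma_only + neither
    genes = [f"{prefix}{i:06d}" for i in range(total)]
    urine = genes[: both + urine_only]
    plasma = genes[:both] + genes[both + urine_only: both + urine_only + plasma_only]
    return VennFixture(
        ortholog_genes=genes,
        kidney=ReferenceSet("kidney", frozenset(genes)),
        urine_exo=ReferenceSet("urine_exo", frozenset(urine)),
        plasma=ReferenceSet("plasma", frozenset(plasma)),
    )


def generate_reference_sets(config: SimulationConfig) -> dict[str, ReferenceSet]:
    """Kidney / urine / exosome / plasma reference sets over the true gene universe.

    A random subset of sum(venn_partition) genes is kidney-expressed and
    partitioned into the requested urine/plasma Venn cells; the urine-side
    members are split between the whole-urine and exosome lists (pooling them
    recovers the partition).  Non-kidney genes and extra background gene ids
    pad the sets so reference files are larger than the study, as real
    compendia are.
    """
    rng = _rng(config, "refsets")
    genes = np.array(gene_universe(config))
    n_kid = sum(config.venn_partition)
    kid = rng.choice(genes, size=n_kid, replace=False)
    rng.shuffle(kid)
    b, u, p, _ = config.venn_partition
    both, urine_only, plasma_only = kid[:b], kid[b:b + u], kid[b + u:b + u + p]
    urine_side = np.concatenate([both, urine_only])
    in_exo = rng.random(len(urine_side)) < 0.5
    urine = set(urine_side[~in_exo]) | set(urine_side[rng.random(len(urine_side)) < 0.3])
    exo = set(urine_side) - urine | set(urine_side[in_exo])
    # non-kidney genes scattered into the compendia
    non_kid = np.array(sorted(set(genes) - set(kid)))
    if len(non_kid):
        urine |= set(non_kid[rng.random(len(non_kid)) < 0.3])
        exo |= set(non_kid[rng.random(len(non_kid)) < 0.2])
    plasma = set(both) | set(plasma_only)
    if len(non_kid):
        plasma |= set(non_kid[rng.random(len(non_kid)) < 0.4])
    nbg = config.background_genes_per_set
    bg = [f"BG{i:05d}" for i in range(4 * nbg)]
    return {
        "kidney": ReferenceSet("kidney", frozenset(kid) | set(bg[:nbg])),
        "urine": ReferenceSet("urine", frozenset(urine) | set(bg[nbg:2 * nbg])),
        "exosome": ReferenceSet("exosome", frozenset(exo) | set(bg[2 * nbg:3 * nbg])),
        "plasma": ReferenceSet("plasma", frozenset(plasma) | set(bg[3 * nbg:])),
    }


# ---------------------------------------------------------------------------
# annotations and prior biomarkers


def generate_annotations(config: SimulationConfig, n_terms: int = 40) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A toy annotation corpus: a random term DAG plus 1-3 terms per gene."""
    rng = _rng(config, "annotations")
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(3, n_terms):  # first three terms are roots
        for parent in rng.choice(i, size=rng.integers(1, 3), replace=False):
            edges.append((terms[i], terms[parent]))
    edges_df = pd.DataFrame(sorted(set(edges)), columns=["child", "parent"])
    rows = []
    for g in gene_universe(config):
        for t in rng.choice(n_terms - 3, size=rng.integers(1, 4), replace=False):
            rows.append((g, terms[t + 3]))
    ann = pd.DataFrame(sorted(set(rows)), columns=["gene_id", "term_id"])
    return ann, edges_df


def generate_prior_biomarkers(config: SimulationConfig, fraction: float = 0.07) -> ReferenceSet:
    """A prior biomarker gene list: a random slice of the gene universe."""
    rng = _rng(config, "biomarkers")
    genes = np.array(gene_universe(config))
    n = max(1, round(fraction * len(genes)))
    return ReferenceSet("prior_biomarkers", frozenset(rng.choice(genes, size=n, replace=False)))


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    proteome: dict[str, str] = field(repr=False)
    identifications: dict[str, IdentificationTable] = field(repr=False)
    manifest: pd.DataFrame = field(repr=False)
    ortholog_maps: dict[str, pd.DataFrame] = field(repr=False)
    reference_sets: dict[str, ReferenceSet] = field(repr=False)
    annotations: pd.DataFrame = field(repr=False)
    term_edges: pd.DataFrame = field(repr=False)
    prior_biomarkers: ReferenceSet = field(repr=False)
    truth: pd.DataFrame = field(repr=False)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every input of one synthetic study, plus the truth table.

    The truth table is protein-level (hypoxia / rank-shift flags) joined with
    gene-level kidney-origin membership derived from the true pairing and the
    generated kidney reference set.
    """
    proteome = generate_proteome(config)
    identifications, truth = generate_identifications(proteome, config)
    refsets = generate_reference_sets(config)
    pairing = true_pairing(config)
    per_protein_genes = pairing.groupby("rat_protein")["human_gene"].agg(list)
    kid = refsets["kidney"].genes
    truth = truth.copy()
    truth["gene_ids"] = [
        "|".join(per_protein_genes.get(a, [])) for a in truth["protein_accession"]
    ]
    truth["kidney_origin"] = [
        any(g in kid for g in per_protein_genes.get(a, []))
        for a in truth["protein_accession"]
    ]
    ann, edges = generate_annotations(config)
    return SyntheticStudy(
        config=config,
        proteome=proteome,
        identifications=identifications,
        manifest=sample_manifest(config),
        ortholog_maps=generate_ortholog_maps(proteome, config),
        reference_sets=refsets,
        annotations=ann,
        term_edges=edges,
        prior_biomarkers=generate_prior_biomarkers(config),
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study inputs as FASTA/TSV files; returns the path of each piece."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["proteome"] = outdir / "proteome.fasta"
    write_fasta(study.proteome, paths["proteome"])

    ident_dir = outdir / "identifications"
    ident_dir.mkdir(exist_ok=True)
    for sid, table in study.identifications.items():
        p = ident_dir / f"{sid}.tsv"
        write_identification_table(table, p)
        paths[f"ident:{sid}"] = p

    paths["manifest"] = outdir / "manifest.tsv"
    study.manifest.to_csv(paths["manifest"], sep="\t", index=False)

    ortho_dir = outdir / "orthologs"
    ortho_dir.mkdir(exist_ok=True)
    for db, df in study.ortholog_maps.items():
        p = ortho_dir / f"{db}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"ortholog:{db}"] = p

    for name, rs in study.reference_sets.items():
        p = outdir / f"refset_{name}.tsv"
        write_gene_set(rs, p)
        paths[f"refset:{name}"] = p

    paths["annotations"] = outdir / "annotations.tsv"
    study.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["term_edges"] = outdir / "term_edges.tsv"
    study.term_edges.to_csv(paths["term_edges"], sep="\t", index=False)

    paths["prior_biomarkers"] = outdir / "prior_biomarkers.tsv"
    write_gene_set(study.prior_biomarkers, paths["prior_biomarkers"])

    paths["truth"] = outdir / "truth_table.tsv"
    study.truth.to_csv(paths["truth"], sep="\t", index=False)

    study.config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
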