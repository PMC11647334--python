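"""Tiered per-patient variant filtering and prioritisation.

The pipeline is phenotype-first: variants are restricted to the genes known
to cause the patient's clinical diagnosis, which keeps the false genotype
rate down, then passed through a fixed stage order:

1. select the phenotype gene subset;
2. flag known disease-causing variants seen in >= 2 registry families
   (flagged variants bypass every later exclusion);
3. filter by a lenient global MAF cut-off of 6%;
4. flag exonic variants in splice junctions (first/last two exon bases) from
   the curated boundary table — without this, synonymous or missense changes
   at exon edges would be erroneously discarded;
5. exclude synonymous variants (junction- and registry-flagged ones
   survive);
6. prioritise: splice-site variants, indels and nonsense variants
   automatically; missense only with >= 3 of 5 pathogenic predictor calls;
7. remove variants on the curated artefact elimination list.

If the patient remains unresolved the whole filter re-runs once
gene-agnostically over every panel gene.  Each stage logs input/output
counts to an audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genemodels import GeneInfo, TranscriptModel, build_boundary_list
from .observations import PipelineConfig, VariantObservation

__all__ = [
    "PatientCase",
    "Catalogues",
    "PatientResult",
    "select_phenotype_genes",
    "flag_known",
    "maf_filter",
    "flag_splice_junction",
    "exclude_synonymous",
    "prioritise",
    "splice_evidence",
    "apply_elimination_list",
    "run_patient",
    "run_cohort",
]


@dataclass
class PatientCase:
    """Manifest entry plus the patient's observations and supplemental data."""

    patient_id: str
    clinical_class: str
    population_group: str = "unknown"
    presumed_inheritance: str = "Unknown"
    familial_samples_available: bool = False
    observations: list[VariantObservation] = field(default_factory=list)
    div_genotypes: dict[str, str] = field(default_factory=dict)


@dataclass
class Catalogues:
    """Reference catalogues shared across the cohort."""

    registry: Mapping[str, int] = field(default_factory=dict)
    elimination_list: frozenset[str] = frozenset()
    div_catalogue: tuple = ()
    known_variants: frozenset[str] = frozenset()
    gene_info: Mapping[str, GeneInfo] = field(default_factory=dict)

    @property
    def gene_disease_map(self) -> dict[str, set[str]]:
        mapping: dict[str, set[str]] = {}
        for gene, info in self.gene_info.items():
            for cls in info.associated_classes:
                mapping.setdefault(cls, set()).add(gene)
        return mapping

    @property
    def gene_inheritance(self) -> dict[str, str]:
        return {g: info.inheritance_mode for g, info in self.gene_info.items()}


@dataclass
class PatientResult:
    """Outcome of the tiered filter for one patient."""

    patient_id: str
    call: "ResolutionCall"  # noqa: F821 - resolution imported lazily
    candidates: list[VariantObservation]
    audit: list[dict]
    gene_agnostic_used: bool = False


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    contig, pos, ref, alt = key.split(":")
    return contig, int(pos), ref, alt


def select_phenotype_genes(
    clinical_class: str, gene_disease_map: Mapping[str, Iterable[str]]
) -> set[str]:
    """Genes associated with the patient's clinical diagnosis.

    An unclear diagnosis is written 'Unclear:STGD|BEST' (candidate diagnoses
    after the colon); it returns the union over the candidate gene sets.
    """
    if clinical_class.startswith("Unclear"):
        _, _, rest = clinical_class.partition(":")
        candidates = [c for c in rest.split("|") if c]
        if not candidates:
            raise ValueError(
                "an 'Unclear' diagnosis needs candidate classes, "
                "e.g. 'Unclear:STGD|BEST'"
            )
        genes: set[str] = set()
        for cls in candidates:
            genes |= set(gene_disease_map.get(cls, ()))
        return genes
    if clinical_class not in gene_disease_map:
        raise KeyError(f"clinical class {clinical_class!r} not in gene-disease map")
    genes = set(gene_disease_map[clinical_class])
    if not genes:
        warnings.warn(f"no genes mapped to clinical class {clinical_class!r}")
    return genes


def flag_known(
    observations: Sequence[VariantObservation],
    registry: Mapping[str, int],
    config: PipelineConfig | None = None,
) -> list[VariantObservation]:
    """Flag known disease-causing variants seen in enough registry families.

    The flag exempts a variant from every subsequent exclusion filter.
    """
    config = config or PipelineConfig()
    out = []
    for obs in observations:
        families = registry.get(obs.variant_key, 0)
        if families >= config.registry_min_families:
            obs = obs.with_flag("known_registry")
        out.append(obs)
    return out


def maf_filter(
    observations: Sequence[VariantObservation],
    config: PipelineConfig | None = None,
) -> list[VariantObservation]:
    """Drop common variants: global MAF above the cut-off (default 6%).

    The boundary is inclusive (MAF == cut-off is retained) and a missing MAF
    never justifies exclusion.  Registry-flagged variants always survive.
    """
    config = config or PipelineConfig()
    return [
        obs
        for obs in observations
        if "known_registry" in obs.flags
        or obs.global_maf is None
        or obs.global_maf <= config.maf_cutoff
    ]


def flag_splice_junction(
    observations: Sequence[VariantObservation],
    boundary_table: pd.DataFrame,
) -> list[VariantObservation]:
    """Flag exonic variants falling in the first/last two bases of an exon.

    Positions come from the curated boundary table; indels are matched by
    their leftmost affected base (inputs are assumed left-normalised).  The
    flag protects the variant from the synonymous exclusion and marks it as
    splice-relevant for prioritisation.
    """
    junction_positions: set[tuple[str, int]] = set()
    for _, row in boundary_table.iterrows():
        for col in ("junction5_positions", "junction3_positions"):
            for p in str(row[col]).split(","):
                if p:
                    junction_positions.add((row["contig"], int(p)))
    out = []
    for obs in observations:
        try:
            contig, pos, _, _ = parse_variant_key(obs.variant_key)
        except ValueError:
            out.append(obs)
            continue
        if (contig, pos) in junction_positions:
            obs = obs.with_flag("splice_junction")
        out.append(obs)
    return out


def exclude_synonymous(
    observations: Sequence[VariantObservation],
) -> list[VariantObservation]:
    """Drop synonymous variants unless junction- or registry-flagged."""
    return [
        obs
        for obs in observations
        if obs.consequence != "synonymous"
        or obs.flags & {"splice_junction", "known_registry"}
    ]


def prioritise(
    observations: Sequence[VariantObservation],
    config: PipelineConfig | None = None,
) -> list[VariantObservation]:
    """Keep the variant classes worth manual inspection.

    Splice-site variants (canonical-site consequence or junction-flagged),
    indels and nonsense variants pass automatically; missense variants need
    pathogenic calls from at least three of the five predictors (a missing
    slot counts as non-pathogenic).  Registry-flagged variants always pass.
    """
    config = config or PipelineConfig()
    auto = {"nonsense", "frameshift_indel", "inframe_indel", "splice_region"}
    out = []
    for obs in observations:
        if obs.flags & {"known_registry", "splice_junction", "deep_intronic_catalogue"}:
            out.append(obs)
        elif obs.consequence in auto:
            out.append(obs)
        elif (
            obs.consequence == "missense"
            and obs.n_pathogenic_predictions() >= config.min_pathogenic_predictors
        ):
            out.append(obs)
    return out


def splice_evidence(
    observation: VariantObservation, config: PipelineConfig | None = None
) -> bool:
    """Whether the SpliceAI score counts as splicing pathogenicity evidence.

    Strictly greater than the threshold (default 0.1); an unscored variant
    yields False.  Recorded as evidence, never used as a filter.
    """
    config = config or PipelineConfig()
    if observation.spliceai_score is None:
        return False
    return observation.spliceai_score > config.spliceai_threshold


def apply_elimination_list(
    observations: Sequence[VariantObservation],
    elimination_list,
) -> list[VariantObservation]:
    """Remove variants on the curated artefact elimination list."""
    keys = getattr(elimination_list, "keys_set", None)
    keys = keys() if callable(keys) else set(elimination_list)
    return [obs for obs in observations if obs.variant_key not in keys]


def _run_filter(
    observations: Sequence[VariantObservation],
    gene_subset: set[str] | None,
    boundary_table: pd.DataFrame,
    catalogues: Catalogues,
    config: PipelineConfig,
    audit: list[dict],
    pass_name: str,
) -> list[VariantObservation]:
    def log(stage: str, n_in: int, n_out: int) -> None:
        audit.append(
            {"pass": pass_name, "stage": stage, "n_in": n_in, "n_out": n_out}
        )

    obs = list(observations)
    if gene_subset is not None:
        n = len(obs)
        obs = [o for o in obs if o.gene_id in gene_subset]
        log("phenotype_gene_subset", n, len(obs))
    else:
        log("gene_agnostic_subset", len(obs), len(obs))

    n = len(obs)
    obs = flag_known(obs, catalogues.registry, config)
    log("flag_known", n, len(obs))

    n = len(obs)
    obs = maf_filter(obs, config)
    log("maf_filter", n, len(obs))

    n = len(obs)
    obs = flag_splice_junction(obs, boundary_table)
    log("flag_splice_junction", n, len(obs))

    n = len(obs)
    obs = exclude_synonymous(obs)
    log("exclude_synonymous", n, len(obs))

    n = len(obs)
    obs = prioritise(obs, config)
    log("prioritise", n, len(obs))

    n = len(obs)
    obs = apply_elimination_list(obs, catalogues.elimination_list)
    log("elimination_list", n, len(obs))
    return obs


def run_patient(
    patient: PatientCase,
    models: Sequence[TranscriptModel],
    catalogues: Catalogues,
    config: PipelineConfig | None = None,
    boundary_table: pd.DataFrame | None = None,
) -> PatientResult:
    """Run the tiered filter and resolution call for one patient.

    The phenotype-first pass restricts observations to the genes associated
    with the patient's clinical class; if that leaves the patient
    unresolved, the filter re-runs once over all panel genes
    (gene-agnostic pass).  Supplemental deep-intronic genotypes are merged
    into the candidate set before each resolution call.
    """
    from .resolution import classify_resolution, merge_div_screen

    config = config or PipelineConfig()
    if boundary_table is None:
        boundary_table = build_boundary_list(models)
    audit: list[dict] = []

    try:
        gene_subset = select_phenotype_genes(
            patient.clinical_class, catalogues.gene_disease_map
        )
    except (KeyError, ValueError) as exc:
        warnings.warn(
            f"{patient.patient_id}: phenotype gene selection failed ({exc}); "
            "falling back to the gene-agnostic pass"
        )
        gene_subset = None

    phase = True if patient.familial_samples_available else None

    def classify(candidates):
        merged = merge_div_screen(
            candidates, patient.div_genotypes, catalogues.div_catalogue
        )
        call = classify_resolution(
            merged,
            catalogues.gene_inheritance,
            familial_available=patient.familial_samples_available,
            phase_confirmed=phase,
        )
        return merged, call

    candidates = _run_filter(
        patient.observations,
        gene_subset,
        boundary_table,
        catalogues,
        config,
        audit,
        "phenotype_first",
    )
    merged, call = classify(candidates)
    gene_agnostic_used = False
    if call.status == "unresolved" and gene_subset is not None:
        gene_agnostic_used = True
        candidates = _run_filter(
            patient.observations,
            None,
            boundary_table,
            catalogues,
            config,
            audit,
            "gene_agnostic",
        )
        merged, call = classify(candidates)
    return PatientResult(patient.patient_id, call, merged, audit, gene_agnostic_used)


def run_cohort(
    patients: Sequence[PatientCase],
    models: Sequence[TranscriptModel],
    catalogues: Catalogues,
    config: PipelineConfig | None = None,
) -> list[PatientResult]:
    """Run the full pipeline over a cohort (boundary table built once)."""
    boundary_table = build_boundary_list(models)
    return [
        run_patient(p, models, catalogues, config, boundary_table)
        for p in patients
    ]
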