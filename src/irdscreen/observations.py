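"""Core per-patient variant record and pipeline thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = ["CONSEQUENCES", "PREDICTORS", "VariantObservation", "PipelineConfig"]

CONSEQUENCES = (
    "missense",
    "synonymous",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_region",
    "intronic",
    "other",
)

#: the five binary pathogenicity predictors carried with each variant
PREDICTORS = ("SIFT", "PolyPhen-2", "Grantham", "FATHMM", "PhyloP")

_ZYGOSITIES = ("het", "hom", "hemi")
_ACMG = ("P", "LP", "VUS", "LB", "B")


@dataclass(frozen=True)
class VariantObservation:
    """One genotyped, annotated variant in one patient.

    ``variant_key`` is the canonical "contig:pos:ref:alt" string (or a
    catalogue locus key for supplemental screen entries).  Predictor calls
    map predictor name -> 'pathogenic' | 'benign'; absent slots are missing
    calls.  ``flags`` accumulate protections and provenance marks
    (known_registry, splice_junction, artefact, deep_intronic_catalogue).
    """

    variant_key: str
    gene_id: str
    consequence: str
    zygosity: str
    global_maf: float | None = None
    population_mafs: Mapping[str, float] = field(default_factory=dict)
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    spliceai_score: float | None = None
    acmg_class: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.zygosity not in _ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.acmg_class is not None and self.acmg_class not in _ACMG:
            raise ValueError(f"unknown ACMG class {self.acmg_class!r}")
        if self.global_maf is not None and not 0.0 <= self.global_maf <= 1.0:
            raise ValueError("global_maf must be in [0, 1]")

    def with_flag(self, flag: str) -> "VariantObservation":
        return replace(self, flags=self.flags | {flag})

    def n_pathogenic_predictions(self) -> int:
        return sum(1 for call in self.predictor_calls.values() if call == "pathogenic")


@dataclass(frozen=True)
class PipelineConfig:
    """Filtering thresholds.

    maf_cutoff: lenient global minor-allele-frequency ceiling (0.06, chosen
        against the frequency of the most common pathogenic alleles in
        ABCA4); the boundary is inclusive — a variant at exactly the cut-off
        is retained.
    min_pathogenic_predictors: of the five predictors, how many must call a
        missense variant pathogenic for it to be prioritised.
    spliceai_threshold: scores strictly above this count as splicing
        pathogenicity evidence (annotation only, never a filter).
    registry_min_families: a known variant must have appeared in at least
        this many families to earn the registry flag.
    """

    maf_cutoff: float = 0.06
    min_pathogenic_predictors: int = 3
    spliceai_threshold: float = 0.1
    registry_min_families: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_cutoff <= 1.0:
            raise ValueError("maf_cutoff must be in [0, 1]")
        if not 0 <= self.min_pathogenic_predictors <= len(PREDICTORS):
            raise ValueError("min_pathogenic_predictors must be in [0, 5]")
        if not 0.0 <= self.spliceai_threshold <= 1.0:
            raise ValueError("spliceai_threshold must be in [0, 1]")
        if self.registry_min_families < 1:
            raise ValueError("registry_min_families must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "maf_cutoff": self.maf_cutoff,
                    "min_pathogenic_predictors": self.min_pathogenic_predictors,
                    "spliceai_threshold": self.spliceai_threshold,
                    "registry_min_families": self.registry_min_families,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
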