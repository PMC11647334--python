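"""Resolution-status classification and the deep-intronic supplemental screen.

A patient is *genetically resolved* when the candidate variants explain the
disease under the gene's inheritance mode:

(i)   a single heterozygous (or hemizygous) pathogenic/likely-pathogenic
      variant in an autosomal dominant or X-linked gene;
(ii)  a single homozygous pathogenic/likely-pathogenic variant in an
      autosomal recessive gene;
(iii) two heterozygous pathogenic/likely-pathogenic variants in an autosomal
      recessive gene with the trans configuration confirmed by familial
      testing — without phase confirmation the patient is *very likely
      resolved* instead.

Patients not meeting these clauses may still carry a *potential diagnosis*:
(i) one het P/LP plus one het VUS in an AR gene, (ii) two het VUS in an AR
gene, or (iii) one het VUS in an AD or X-linked gene.  Everything else is
*unresolved*.

The deep-intronic screen targets a small catalogue of published, functionally
verified deep intronic variants (pseudoexon inclusion / exon skipping);
non-reference genotypes from that supplemental assay are merged into the
candidate set as pathogenic observations before classification, which can
convert a monoallelic recessive case into a resolvable compound heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .observations import VariantObservation

__all__ = [
    "STATUS_ORDER",
    "ResolutionCall",
    "DivCatalogueEntry",
    "merge_div_screen",
    "classify_resolution",
]

#: status severity ordering, weakest to strongest evidence
STATUS_ORDER = (
    "unresolved",
    "potential_diagnosis",
    "very_likely_resolved",
    "genetically_resolved",
)
_STATUS_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}

_CAUSAL_CLASSES = {"P", "LP"}


@dataclass(frozen=True)
class ResolutionCall:
    """The status decision for one patient, with its triggering clause."""

    status: str
    rule_id: str
    causal_variants: tuple[VariantObservation, ...] = ()
    resolving_gene: str | None = None
    phase_confirmed: bool | None = None
    needs_review: bool = False
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in _STATUS_RANK:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "unresolved":
            if not self.causal_variants:
                raise ValueError("non-unresolved call requires causal variants")
            genes = {v.gene_id for v in self.causal_variants}
            if len(genes) != 1:
                raise ValueError("causal variants must lie in a single gene")

    @property
    def rank(self) -> int:
        return _STATUS_RANK[self.status]


@dataclass(frozen=True)
class DivCatalogueEntry:
    """One published deep-intronic variant selected for supplemental screening."""

    gene: str
    transcript: str
    cdna_name: str
    locus: str
    mechanism: str  # pseudoexon_inclusion | exon_skipping

    def __post_init__(self) -> None:
        if self.mechanism not in ("pseudoexon_inclusion", "exon_skipping"):
            raise ValueError(f"unknown DIV mechanism {self.mechanism!r}")


def merge_div_screen(
    candidates: Sequence[VariantObservation],
    div_genotypes: Mapping[str, str],
    catalogue: Sequence[DivCatalogueEntry],
) -> list[VariantObservation]:
    """Merge supplemental deep-intronic genotypes into a candidate set.

    ``div_genotypes`` maps catalogue locus keys to genotype strings
    ('0/0', '0/1', '1/1'); non-reference genotypes become pathogenic candidate
    observations in the catalogue gene, flagged ``deep_intronic_catalogue``.
    A genotype at a locus not present in the catalogue is an error.
    """
    by_locus = {entry.locus: entry for entry in catalogue}
    merged = list(candidates)
    for locus, gt in div_genotypes.items():
        entry = by_locus.get(locus)
        if entry is None:
            raise KeyError(f"DIV genotype at locus {locus!r} not in catalogue")
        alts = sum(a == "1" for a in gt.replace("|", "/").split("/"))
        if alts == 0:
            continue
        merged.append(
            VariantObservation(
                variant_key=locus,
                gene_id=entry.gene,
                consequence="intronic",
                zygosity="hom" if alts >= 2 else "het",
                acmg_class="P",
                flags=frozenset({"deep_intronic_catalogue"}),
            )
        )
    return merged


def _gene_call(
    gene: str,
    observations: Sequence[VariantObservation],
    inheritance: str,
    familial_available: bool,
    phase_confirmed: bool | None,
) -> ResolutionCall:
    """Evaluate the resolution clauses for the candidates of a single gene."""
    plp = [o for o in observations if o.acmg_class in _CAUSAL_CLASSES]
    vus = [o for o in observations if o.acmg_class == "VUS"]
    plp_het = [o for o in plp if o.zygosity == "het"]
    plp_hom = [o for o in plp if o.zygosity == "hom"]
    plp_hemi = [o for o in plp if o.zygosity == "hemi"]
    vus_het = [o for o in vus if o.zygosity == "het"]
    vus_hom = [o for o in vus if o.zygosity == "hom"]
    notes: list[str] = []

    if inheritance in ("AD", "XL"):
        carriers = plp_het + plp_hemi + plp_hom
        if carriers:
            if inheritance == "XL" and any(o.zygosity == "het" for o in carriers):
                notes.append(
                    "heterozygous variant in an X-linked gene; "
                    "carrier status possible in females"
                )
            return ResolutionCall(
                "genetically_resolved",
                "resolved_i",
                tuple(carriers[:1]),
                gene,
                notes=tuple(notes),
            )
        vus_any = vus_het + [o for o in vus if o.zygosity in ("hemi", "hom")]
        if vus_any:
            pick = vus_any[0]
            return ResolutionCall(
                "potential_diagnosis", "potential_iii", (pick,), gene
            )
        return ResolutionCall("unresolved", "unresolved")

    # autosomal recessive
    if plp_hom:
        return ResolutionCall(
            "genetically_resolved", "resolved_ii", tuple(plp_hom[:1]), gene
        )
    if len(plp_het) >= 2:
        if phase_confirmed:
            return ResolutionCall(
                "genetically_resolved",
                "resolved_iii",
                tuple(plp_het[:2]),
                gene,
                phase_confirmed=True,
            )
        if familial_available and phase_confirmed is None:
            notes.append("familial samples available; phase confirmation pending")
        return ResolutionCall(
            "very_likely_resolved",
            "very_likely_comphet",
            tuple(plp_het[:2]),
            gene,
            phase_confirmed=False if phase_confirmed is False else None,
            notes=tuple(notes),
        )
    if plp_het and vus_het:
        return ResolutionCall(
            "potential_diagnosis",
            "potential_i",
            (plp_het[0], vus_het[0]),
            gene,
        )
    if len(vus_het) >= 2:
        return ResolutionCall(
            "potential_diagnosis", "potential_ii", tuple(vus_het[:2]), gene
        )
    if vus_hom:
        # a homozygous VUS supplies two uncertain alleles; accepted under
        # clause (ii) and noted for review
        return ResolutionCall(
            "potential_diagnosis",
            "potential_ii",
            tuple(vus_hom[:1]),
            gene,
            notes=("homozygous VUS accepted under potential clause (ii)",),
        )
    return ResolutionCall("unresolved", "unresolved")


def classify_resolution(
    candidates: Sequence[VariantObservation],
    gene_inheritance: Mapping[str, str],
    familial_available: bool = False,
    phase_confirmed: bool | None = None,
) -> ResolutionCall:
    """Decide a patient's resolution status from their candidate variants.

    Clauses are evaluated per gene in fixed precedence (resolved i-iii, the
    very-likely-resolved downgrade for unconfirmed compound heterozygotes,
    potential i-iii, else unresolved); the gene reaching the highest status
    is reported.  Two genes tying at the highest status are flagged for
    manual review rather than auto-picked.  P and LP are interchangeable
    throughout.  Candidates in genes with unknown inheritance are excluded
    from clause evaluation and logged in the call's notes.
    """
    by_gene: dict[str, list[VariantObservation]] = {}
    skipped: list[str] = []
    for obs in candidates:
        mode = gene_inheritance.get(obs.gene_id)
        if mode not in ("AD", "AR", "XL"):
            skipped.append(obs.gene_id)
            continue
        by_gene.setdefault(obs.gene_id, []).append(obs)

    calls = [
        _gene_call(
            gene,
            observations,
            gene_inheritance[gene],
            familial_available,
            phase_confirmed,
        )
        for gene, observations in sorted(by_gene.items())
    ]
    calls = [c for c in calls if c.status != "unresolved"]
    notes = tuple(
        f"gene {g} excluded: unknown inheritance mode" for g in sorted(set(skipped))
    )
    if not calls:
        return ResolutionCall("unresolved", "unresolved", notes=notes)
    best_rank = max(c.rank for c in calls)
    top = [c for c in calls if c.rank == best_rank]
    chosen = top[0]
    if notes:
        chosen = replace(chosen, notes=chosen.notes + notes)
    if len(top) > 1:
        chosen = replace(
            chosen,
            needs_review=True,
            notes=chosen.notes
            + (
                "multiple genes satisfy the same clause: "
                + ", ".join(sorted(c.resolving_gene for c in top)),
            ),
        )
    return chosen
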