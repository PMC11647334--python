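"""Synthetic IRD cohort generator with planted ground truth.

No registry data can be deposited, so every downstream stage is exercised on
a generated stand-in cohort: per-gene synthetic contigs and transcript
models, per-patient VCFs realising an inheritance-consistent genotype
configuration for each resolution category, a cohort annotation table,
reference catalogues (known-variant registry, artefact elimination list,
deep-intronic screening catalogue and genotypes), a patient manifest, and
FASTQ files with planted 23-bp junction reads for the Alu screen.

The generator's defaults emulate the registry cohort's composition: 135
patients; clinical classes BEST 2%, CRD 4%, LCA 5%, RP 50%, RPA 1%, RS 3%,
STGD 11%, USH 10%, Unclear 13% (normalised); population groups ~50%
indigenous African with Caucasian, mixed-ancestry and Indian subcohorts;
and a resolution-category mix reproducing 75/135 resolved overall with the
deep-intronic screen accounting for the last ~3 percentage points.

Every planted category maps deterministically to an expected resolution
status (``EXPECTED_STATUS``), which is what truth-recovery tests assert.
Identical (design, seed) inputs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import reverse_complement

from . import io as iomod
from .alu import MotifPair
from .artefacts import EliminationList
from .genemodels import GeneInfo, TranscriptModel
from .pipeline import Catalogues, PatientCase
from .resolution import DivCatalogueEntry

__all__ = [
    "CLINICAL_CLASSES",
    "POPULATION_GROUPS",
    "CATEGORIES",
    "EXPECTED_STATUS",
    "EXPECTED_STATUS_WITHOUT_DIV",
    "CohortDesign",
    "TruthRecord",
    "SyntheticCohort",
    "generate_gene_models",
    "generate_cohort",
    "generate_alu_fastq",
]

CLINICAL_CLASSES = ("BEST", "CRD", "LCA", "RP", "RPA", "RS", "STGD", "USH")
POPULATION_GROUPS = ("Indigenous African", "Caucasian", "Mixed ancestry", "Indian")

#: planted resolution categories and the status each must map to end-to-end
EXPECTED_STATUS = {
    "resolved-AD": "genetically_resolved",
    "resolved-hom-AR": "genetically_resolved",
    "resolved-comphet-phase-known": "genetically_resolved",
    "comphet-phase-unknown": "very_likely_resolved",
    "potential-i": "potential_diagnosis",
    "potential-ii": "potential_diagnosis",
    "potential-iii": "potential_diagnosis",
    "monoallelic-AR": "unresolved",
    "div-resolvable": "very_likely_resolved",
    "unresolved": "unresolved",
}
CATEGORIES = tuple(EXPECTED_STATUS)

#: expected status when the supplemental deep-intronic screen is NOT run
EXPECTED_STATUS_WITHOUT_DIV = dict(EXPECTED_STATUS, **{"div-resolvable": "unresolved"})

_DEF_CLASS_COUNTS = {
    "BEST": 2, "CRD": 4, "LCA": 5, "RP": 50, "RPA": 1,
    "RS": 3, "STGD": 11, "USH": 10, "Unclear": 13,
}
_DEF_POP_MIX = {
    "Indigenous African": 0.50, "Caucasian": 0.27,
    "Mixed ancestry": 0.17, "Indian": 0.06,
}
# per-mechanism split of the 75 resolved / 60 unresolved patients of the
# default 135-patient design (overall breakdown chosen to reproduce the
# reported 56% resolved, 19 potential and 12 monoallelic-recessive cases,
# with the deep-intronic screen resolving ~4 patients)
_DEF_CATEGORY_COUNTS = {
    "resolved-AD": 20, "resolved-hom-AR": 25, "resolved-comphet-phase-known": 12,
    "comphet-phase-unknown": 14, "potential-i": 7, "potential-ii": 6,
    "potential-iii": 6, "monoallelic-AR": 12, "div-resolvable": 4,
    "unresolved": 29,
}


def _normalise(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def _check_mix(name: str, mix: Mapping[str, float]) -> None:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions must sum to 1 (got {sum(mix.values())})")
    if any(v < 0 for v in mix.values()):
        raise ValueError(f"{name} proportions must be non-negative")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition: who is simulated and what is planted in whom."""

    n_patients: int = 135
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: _normalise(_DEF_CLASS_COUNTS)
    )
    population_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_POP_MIX)
    )
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: _normalise(_DEF_CATEGORY_COUNTS)
    )
    artefact_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        _check_mix("class_mix", self.class_mix)
        _check_mix("population_mix", self.population_mix)
        _check_mix("category_mix", self.category_mix)
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in category_mix: {sorted(unknown)}")
        if not 0.0 <= self.artefact_rate <= 1.0:
            raise ValueError("artefact_rate must be in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "n_patients": self.n_patients,
                    "class_mix": dict(self.class_mix),
                    "population_mix": dict(self.population_mix),
                    "category_mix": dict(self.category_mix),
                    "artefact_rate": self.artefact_rate,
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "CohortDesign":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated patient."""

    patient_id: str
    planted_category: str
    expected_status: str
    planted_causal_variants: tuple[str, ...]
    planted_artefacts: tuple[str, ...]
    planted_div: str | None
    planted_alu_status: str = "absent"


@dataclass
class SyntheticCohort:
    """In-memory handle on a generated cohort plus its on-disk layout."""

    design: CohortDesign
    models: list[TranscriptModel]
    gene_info: dict[str, GeneInfo]
    contig_sequences: dict[str, str]
    patients: list[PatientCase]
    catalogues: Catalogues
    truth: pd.DataFrame
    annotations: pd.DataFrame
    manifest: pd.DataFrame
    out_dir: Path | None = None


# ------------------------------------------------------------- gene models

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def generate_gene_models(
    n_genes: int, seed: int
) -> tuple[list[TranscriptModel], dict[str, GeneInfo], dict[str, str]]:
    """Generate gene models on synthetic per-gene contigs.

    Each gene carries one transcript with 2-10 exons, a strand, a valid CDS
    (ATG start, single terminal stop, length divisible by 3, no internal
    stops), an inheritance mode and at least one associated clinical class.
    The first four genes are pinned to modes AD, AR, AR, XL so every
    resolution category is realisable whenever ``n_genes >= 4``.  Introns
    are 250-600 bp, long enough to contain deep-intronic positions.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    gene_info: dict[str, GeneInfo] = {}
    contigs: dict[str, str] = {}
    forced_modes = {0: "AD", 1: "AR", 2: "AR", 3: "XL"}
    for i in range(n_genes):
        gene = f"GENE{i + 1:03d}"
        transcript = f"TX{i + 1:03d}"
        contig = f"ctg{i + 1:03d}"
        n_exons = int(rng.integers(2, 11))
        exon_lengths = [int(x) for x in rng.integers(60, 241, size=n_exons)]
        total = sum(exon_lengths)
        exon_lengths[-1] -= total % 3
        n_codons = sum(exon_lengths) // 3
        codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        cds = (
            "ATG"
            + "".join(_SENSE_CODONS[j] for j in codon_idx)
            + _STOPS[int(rng.integers(0, 3))]
        )
        intron_lengths = [int(x) for x in rng.integers(250, 601, size=n_exons - 1)]
        flank5, flank3 = _random_seq(rng, 100), _random_seq(rng, 100)

        parts, exon_spans, cursor, offset = [flank5], [], 0, 100
        for j, elen in enumerate(exon_lengths):
            parts.append(cds[cursor : cursor + elen])
            exon_spans.append((offset + 1, offset + elen))
            cursor += elen
            offset += elen
            if j < n_exons - 1:
                parts.append(_random_seq(rng, intron_lengths[j]))
                offset += intron_lengths[j]
        parts.append(flank3)
        built = "".join(parts)

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq = built
            exons = tuple(exon_spans)
            cds_start, cds_end = exons[0][0], exons[-1][1]
        else:
            seq = reverse_complement(built)
            L = len(built)
            exons = tuple((L - e + 1, L - s + 1) for s, e in exon_spans)
            cds_start, cds_end = exons[0][1], exons[-1][0]

        mode = forced_modes.get(
            i, str(rng.choice(["AR", "AD", "XL"], p=[0.6, 0.25, 0.15]))
        )
        n_classes = int(rng.integers(1, 4))
        classes = tuple(
            sorted(rng.choice(CLINICAL_CLASSES, size=n_classes, replace=False))
        )
        models.append(
            TranscriptModel(gene, transcript, contig, strand, exons, cds_start, cds_end)
        )
        gene_info[gene] = GeneInfo(gene, mode, classes)
        contigs[contig] = seq
    return models, gene_info, contigs


# ------------------------------------------------------------- site catalog


def _snv(seq: str, pos: int) -> tuple[str, str]:
    ref = seq[pos - 1]
    return ref, _BASES[(_BASES.index(ref) + 1) % 4]


def _deletion(seq: str, pos: int) -> tuple[str, str]:
    ref = seq[pos - 1 : pos + 1]
    return ref, ref[0]


@dataclass(frozen=True)
class _Site:
    name: str
    key: str
    gene: str
    consequence: str
    global_maf: float | None
    n_path_preds: int
    spliceai: float | None
    acmg: str | None


_BG_MAFS = (0.01, 0.04, 0.055, 0.06, 0.065, 0.07, 0.12, 0.30)


def _gene_sites(tm: TranscriptModel, seq: str) -> dict[str, _Site]:
    """Deterministic catalogue of plantable variant sites for one gene."""
    exons = tm.exons_genomic
    e0s, e0e = exons[0]
    e1s, _ = exons[1]

    def snv_key(pos: int) -> str:
        ref, alt = _snv(seq, pos)
        return f"{tm.contig}:{pos}:{ref}:{alt}"

    def del_key(pos: int) -> str:
        ref, alt = _deletion(seq, pos)
        return f"{tm.contig}:{pos}:{ref}:{alt}"

    g = tm.gene_id
    sites = {
        "missense_p1": _Site("missense_p1", snv_key(e0s + 10), g, "missense", 0.001, 4, None, "P"),
        "missense_p2": _Site("missense_p2", snv_key(e0s + 20), g, "missense", 0.0005, 3, None, "LP"),
        "missense_vus1": _Site("missense_vus1", snv_key(e0s + 30), g, "missense", None, 3, None, "VUS"),
        "missense_vus2": _Site("missense_vus2", snv_key(e0s + 40), g, "missense", 0.002, 4, None, "VUS"),
        "nonsense": _Site("nonsense", snv_key(e0s + 16), g, "nonsense", None, 0, None, "P"),
        "frameshift": _Site("frameshift", del_key(e0s + 25), g, "frameshift_indel", None, 0, None, "P"),
        "junction_syn": _Site("junction_syn", snv_key(e0e), g, "synonymous", 0.0003, 0, 0.62, "P"),
        "canonical_splice": _Site("canonical_splice", snv_key(e0e + 1), g, "splice_region", None, 0, 0.85, "P"),
        "registry_syn": _Site("registry_syn", snv_key(e1s + 10), g, "synonymous", 0.07, 0, 0.4, "P"),
        "div": _Site("div", snv_key(e0e + 150), g, "intronic", None, 0, 0.3, "P"),
    }
    # common benign background sites with MAFs straddling the 6% cut-off
    consequences = ("synonymous", "missense", "intronic")
    for b, maf in enumerate(_BG_MAFS):
        pos = e1s + 20 + 3 * b
        cons = consequences[b % 3]
        if cons == "intronic":
            pos = e0e + 50 + b  # near-intronic, never deep
            key = snv_key(pos)
        else:
            key = snv_key(pos)
        sites[f"background_{b}"] = _Site(
            f"background_{b}", key, g, cons, maf, b % 3, None, "B" if b % 2 else "LB"
        )
    return sites


def _apportion(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n among the mix keys."""
    keys = list(mix)
    floors = {k: int(np.floor(mix[k] * n)) for k in keys}
    short = n - sum(floors.values())
    remainders = sorted(
        keys, key=lambda k: (-(mix[k] * n - floors[k]), keys.index(k))
    )
    for k in remainders[:short]:
        floors[k] += 1
    return floors


# ------------------------------------------------------------- cohort


def _assign(mix: Mapping[str, float], n: int, rng: np.random.Generator) -> list[str]:
    labels = [k for k, c in _apportion(mix, n).items() for _ in range(c)]
    rng.shuffle(labels)
    return labels


def generate_cohort(
    design: CohortDesign,
    models_bundle: tuple[list[TranscriptModel], dict[str, GeneInfo], dict[str, str]],
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate per-patient VCFs, manifest, catalogues and the truth table.

    Each patient's VCF realises their planted resolution category (e.g.
    resolved-hom-AR plants one homozygous P/LP variant in an AR gene that
    matches the clinical class), plus common benign background variants with
    MAFs on both sides of the 6% cut-off and — in ``artefact_rate`` of
    patients — the cohort-wide platform artefact, which ships on the
    elimination list.  Every tenth resolved patient is planted discordantly
    (causal gene not associated with the clinical class) to exercise the
    gene-agnostic pass and discordance reporting.
    """
    models, gene_info, contigs = models_bundle
    if not models:
        raise ValueError("models must be non-empty")
    rng = np.random.default_rng(design.seed)
    by_gene = {tm.gene_id: tm for tm in models}
    sites = {
        g: _gene_sites(tm, contigs[tm.contig]) for g, tm in sorted(by_gene.items())
    }
    genes_by_mode: dict[str, list[str]] = {"AD": [], "AR": [], "XL": []}
    for g in sorted(gene_info):
        genes_by_mode[gene_info[g].inheritance_mode].append(g)

    needed_mode = {
        "resolved-AD": "AD", "resolved-hom-AR": "AR",
        "resolved-comphet-phase-known": "AR", "comphet-phase-unknown": "AR",
        "potential-i": "AR", "potential-ii": "AR", "potential-iii": "AD",
        "monoallelic-AR": "AR", "div-resolvable": "AR",
    }
    for cat, count in _apportion(design.category_mix, design.n_patients).items():
        mode = needed_mode.get(cat)
        if count > 0 and mode and not genes_by_mode[mode]:
            raise ValueError(
                f"category {cat!r} needs a gene with inheritance mode {mode}, "
                "but the model set has none"
            )

    categories = _assign(design.category_mix, design.n_patients, rng)
    classes = _assign(design.class_mix, design.n_patients, rng)
    populations = _assign(design.population_mix, design.n_patients, rng)

    artefact_gene = sorted(gene_info)[0]
    artefact_site = sites[artefact_gene]["frameshift"]
    # the artefact must never double as a plantable causal allele
    artefact_key = artefact_site.key

    def pick_gene(mode: str, match_classes: Sequence[str], idx: int, discordant: bool) -> str:
        pool = genes_by_mode[mode]
        matching = [
            g for g in pool
            if set(gene_info[g].associated_classes) & set(match_classes)
        ]
        non_matching = [g for g in pool if g not in matching]
        if discordant and non_matching:
            chosen_pool = non_matching
        else:
            chosen_pool = matching or pool
        return chosen_pool[idx % len(chosen_pool)]

    used_sites: dict[str, _Site] = {artefact_key: artefact_site}
    patients: list[PatientCase] = []
    truth_rows: list[TruthRecord] = []
    vcf_records: dict[str, list[tuple[str, int, str, str, str]]] = {}
    div_genotypes_all: dict[str, dict[str, str]] = {}
    resolved_cats = {
        "resolved-AD", "resolved-hom-AR",
        "resolved-comphet-phase-known", "comphet-phase-unknown",
    }
    xl_rotation = 0

    for idx in range(design.n_patients):
        pid = f"SYN{idx + 1:04d}"
        category = categories[idx]
        cls = classes[idx]
        if cls == "Unclear":
            pair = sorted(rng.choice(CLINICAL_CLASSES, size=2, replace=False))
            clinical_class = f"Unclear:{pair[0]}|{pair[1]}"
            match_classes = pair
        else:
            clinical_class = cls
            match_classes = [cls]

        discordant = category in resolved_cats and idx % 10 == 0
        planted: list[tuple[_Site, str]] = []  # (site, GT)
        div_key: str | None = None
        familial = bool(rng.random() < 0.5)
        mode = needed_mode.get(category)

        if category == "resolved-AD":
            use_xl = genes_by_mode["XL"] and xl_rotation % 5 == 4
            xl_rotation += 1
            if use_xl:
                gene = pick_gene("XL", match_classes, idx, discordant)
                planted.append((sites[gene]["nonsense"], "1"))
            else:
                gene = pick_gene("AD", match_classes, idx, discordant)
                site = "nonsense" if idx % 2 == 0 else "missense_p1"
                planted.append((sites[gene][site], "0/1"))
        elif category == "resolved-hom-AR":
            gene = pick_gene("AR", match_classes, idx, discordant)
            site = "registry_syn" if idx % 4 == 0 else "missense_p1"
            planted.append((sites[gene][site], "1/1"))
        elif category in ("resolved-comphet-phase-known", "comphet-phase-unknown"):
            gene = pick_gene("AR", match_classes, idx, discordant)
            second = "canonical_splice" if idx % 2 == 0 else "junction_syn"
            planted.append((sites[gene]["missense_p1"], "0/1"))
            planted.append((sites[gene][second], "0/1"))
            familial = category == "resolved-comphet-phase-known"
        elif category == "potential-i":
            gene = pick_gene("AR", match_classes, idx, False)
            planted.append((sites[gene]["missense_p2"], "0/1"))
            planted.append((sites[gene]["missense_vus1"], "0/1"))
        elif category == "potential-ii":
            gene = pick_gene("AR", match_classes, idx, False)
            planted.append((sites[gene]["missense_vus1"], "0/1"))
            planted.append((sites[gene]["missense_vus2"], "0/1"))
        elif category == "potential-iii":
            gene = pick_gene("AD", match_classes, idx, False)
            planted.append((sites[gene]["missense_vus1"], "0/1"))
        elif category == "monoallelic-AR":
            gene = pick_gene("AR", match_classes, idx, False)
            planted.append((sites[gene]["missense_p1"], "0/1"))
        elif category == "div-resolvable":
            gene = pick_gene("AR", match_classes, idx, False)
            planted.append((sites[gene]["missense_p1"], "0/1"))
            div_key = sites[gene]["div"].key
            div_genotypes_all[pid] = {div_key: "0/1"}
            familial = False

        records: list[tuple[str, int, str, str, str]] = []
        record_keys: set[str] = set()
        causal_keys = []
        for site, gt in planted:
            if site.key == artefact_key:
                raise RuntimeError("artefact site reused as causal")
            used_sites[site.key] = site
            contig, pos, ref, alt = site.key.split(":")
            records.append((contig, int(pos), ref, alt, gt))
            record_keys.add(site.key)
            causal_keys.append(site.key)

        # benign background draw (3-6 sites from random genes)
        n_bg = int(rng.integers(3, 7))
        gene_order = sorted(sites)
        for _ in range(n_bg):
            bg_gene = gene_order[int(rng.integers(0, len(gene_order)))]
            bg = sites[bg_gene][f"background_{int(rng.integers(0, len(_BG_MAFS)))}"]
            if bg.key in record_keys:
                continue
            used_sites[bg.key] = bg
            contig, pos, ref, alt = bg.key.split(":")
            records.append((contig, int(pos), ref, alt, "0/1"))
            record_keys.add(bg.key)

        artefacts: tuple[str, ...] = ()
        if rng.random() < design.artefact_rate:
            contig, pos, ref, alt = artefact_key.split(":")
            if not any(r[0] == contig and r[1] == int(pos) for r in records):
                records.append((contig, int(pos), ref, alt, "0/1"))
                artefacts = (artefact_key,)

        vcf_records[pid] = records
        patients.append(
            PatientCase(
                patient_id=pid,
                clinical_class=clinical_class,
                population_group=populations[idx],
                presumed_inheritance={"AD": "Dominant", "AR": "Recessive", "XL": "X-Linked"}.get(mode or "", "Unknown"),
                familial_samples_available=familial,
                div_genotypes=dict(div_genotypes_all.get(pid, {})),
            )
        )
        truth_rows.append(
            TruthRecord(
                patient_id=pid,
                planted_category=category,
                expected_status=EXPECTED_STATUS[category],
                planted_causal_variants=tuple(causal_keys),
                planted_artefacts=artefacts,
                planted_div=div_key,
            )
        )

    # ---------------- catalogues
    registry: dict[str, int] = {}
    known: set[str] = set()
    for j, g in enumerate(sorted(sites)):
        registry[sites[g]["registry_syn"].key] = 3
        known.add(sites[g]["registry_syn"].key)
        if j % 2 == 0:  # alternate genes keep their causal alleles novel
            for name in ("missense_p1", "missense_p2", "nonsense",
                         "canonical_splice", "junction_syn"):
                known.add(sites[g][name].key)
    # one below-threshold registry row, never flagged
    first_gene = sorted(sites)[0]
    registry[sites[first_gene]["background_0"].key] = 1

    elimination = EliminationList()
    elimination.add(artefact_key, "recurrent 1-bp deletion in every cohort sample", "2024-01-01")

    div_catalogue = []
    mechs = ("pseudoexon_inclusion", "exon_skipping")
    for j, g in enumerate(genes_by_mode["AR"]):
        tm = by_gene[g]
        div_catalogue.append(
            DivCatalogueEntry(
                gene=g,
                transcript=tm.transcript_id,
                cdna_name=f"c.synthetic_intron1+150A>G",
                locus=sites[g]["div"].key,
                mechanism=mechs[j % 2],
            )
        )

    catalogues = Catalogues(
        registry=registry,
        elimination_list=frozenset(elimination.keys_set()),
        div_catalogue=tuple(div_catalogue),
        known_variants=frozenset(known),
        gene_info=gene_info,
    )

    # ---------------- annotation table
    ann_rows = []
    for key in sorted(used_sites):
        site = used_sites[key]
        preds = {}
        pred_cols = ["pred_sift", "pred_polyphen2", "pred_grantham", "pred_fathmm", "pred_phylop"]
        for k, col in enumerate(pred_cols):
            if site.consequence == "missense":
                preds[col] = "pathogenic" if k < site.n_path_preds else "benign"
            else:
                preds[col] = ""
        ann_rows.append(
            {
                "variant_key": key,
                "gene": site.gene,
                "consequence": site.consequence,
                "global_maf": "" if site.global_maf is None else site.global_maf,
                "maf_IndigenousAfrican": "" if site.global_maf is None else site.global_maf,
                **preds,
                "spliceai": "" if site.spliceai is None else site.spliceai,
                "acmg_class": "" if site.acmg is None else site.acmg,
            }
        )
    annotations = pd.DataFrame(ann_rows)

    manifest = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "clinical_class": p.clinical_class,
                "population_group": p.population_group,
                "presumed_inheritance": p.presumed_inheritance,
                "familial_samples_available": p.familial_samples_available,
            }
            for p in patients
        ]
    )
    truth = pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "planted_category": t.planted_category,
                "expected_status": t.expected_status,
                "planted_causal_variants": ",".join(t.planted_causal_variants),
                "planted_artefacts": ",".join(t.planted_artefacts),
                "planted_div": t.planted_div or "",
                "planted_alu_status": t.planted_alu_status,
            }
            for t in truth_rows
        ]
    )

    cohort = SyntheticCohort(
        design=design,
        models=models,
        gene_info=gene_info,
        contig_sequences=contigs,
        patients=patients,
        catalogues=catalogues,
        truth=truth,
        annotations=annotations,
        manifest=manifest,
    )

    # attach observations so the cohort is runnable without file round-trips
    _attach_observations(cohort, vcf_records, annotations)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "vcf").mkdir(parents=True, exist_ok=True)
        (out / "catalogues").mkdir(exist_ok=True)
        contig_lengths = {c: len(s) for c, s in sorted(contigs.items())}
        for pid in sorted(vcf_records):
            iomod.write_patient_vcf(
                out / "vcf" / f"{pid}.vcf", pid, vcf_records[pid], contig_lengths
            )
        iomod.write_manifest(out / "manifest.tsv", manifest)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        iomod.write_annotations(out / "annotations.tsv", annotations)
        iomod.write_gene_models(
            out / "gene_models.gff3", out / "gene_models.tsv", models, gene_info
        )
        iomod.write_fasta(out / "reference.fa", dict(sorted(contigs.items())))
        iomod.write_registry(out / "catalogues" / "registry.tsv", registry)
        elimination.save(out / "catalogues" / "elimination_list.tsv")
        iomod.write_div_catalogue(
            out / "catalogues" / "div_catalogue.tsv", div_catalogue
        )
        iomod.write_div_genotypes(
            out / "catalogues" / "div_genotypes.tsv", div_genotypes_all
        )
        pd.DataFrame({"variant_key": sorted(known)}).to_csv(
            out / "catalogues" / "known_variants.tsv", sep="\t", index=False
        )
        cohort.out_dir = out
    return cohort


def _attach_observations(
    cohort: SyntheticCohort,
    vcf_records: Mapping[str, list[tuple[str, int, str, str, str]]],
    annotations: pd.DataFrame,
) -> None:
    from .io import _observation_from_row

    ann_map = annotations.set_index("variant_key").to_dict("index")
    for patient in cohort.patients:
        obs = []
        for contig, pos, ref, alt, gt in vcf_records[patient.patient_id]:
            key = f"{contig}:{pos}:{ref}:{alt}"
            alleles = [int(a) for a in gt.replace("|", "/").split("/")]
            if len(alleles) == 1:
                zyg = "hemi"
            elif all(a > 0 for a in alleles):
                zyg = "hom"
            else:
                zyg = "het"
            obs.append(_observation_from_row(key, zyg, ann_map[key]))
        patient.observations = obs


# ------------------------------------------------------------- FASTQ


def generate_alu_fastq(
    n_mutant: int,
    n_wildtype: int,
    n_background: int,
    read_len: int,
    seed: int,
    path: str | Path,
    motif_pair: MotifPair | None = None,
) -> Path:
    """Write a FASTQ with exactly the requested junction-read counts.

    Exactly ``n_mutant`` reads contain the mutant motif (in forward or
    reverse-complement orientation, chosen at random), ``n_wildtype`` the
    wild-type motif, and ``n_background`` neither motif in either
    orientation (verified by exhaustive scan with rejection sampling).
    """
    pair = motif_pair or MotifPair()
    if read_len < pair.length:
        raise ValueError(
            f"read_len must be >= motif length ({pair.length}); got {read_len}"
        )
    if min(n_mutant, n_wildtype, n_background) < 0:
        raise ValueError("read counts must be >= 0")
    rng = np.random.default_rng(seed)
    all_patterns = pair.wildtype_patterns() + pair.mutant_patterns()

    def make_read(kind: str) -> str:
        for _ in range(1000):
            seq = _random_seq(rng, read_len)
            if kind != "background":
                motif = (
                    pair.mutant_motif if kind == "mutant" else pair.wildtype_motif
                )
                if rng.random() < 0.5:
                    motif = reverse_complement(motif)
                offset = int(rng.integers(0, read_len - pair.length + 1))
                seq = seq[:offset] + motif + seq[offset + pair.length :]
                own = (
                    pair.mutant_patterns()
                    if kind == "mutant"
                    else pair.wildtype_patterns()
                )
                other = tuple(p for p in all_patterns if p not in own)
                if not any(p in seq for p in other):
                    return seq
            elif not any(p in seq for p in all_patterns):
                return seq
        raise RuntimeError("could not construct a conforming read")

    kinds = ["mutant"] * n_mutant + ["wildtype"] * n_wildtype + ["background"] * n_background
    rng.shuffle(kinds)
    path = Path(path)
    with open(path, "w") as fh:
        for i, kind in enumerate(kinds, start=1):
            seq = make_read(kind)
            fh.write(f"@synthetic_read_{i:06d}\n{seq}\n+\n{'I' * read_len}\n")
    return path
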