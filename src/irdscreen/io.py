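"""File-format plumbing: VCF, GFF3, FASTA, and the pipeline's TSV tables.

All external coordinates are 1-based (VCF/GFF3 convention).  VCF reading
goes through cyvcf2; only genotype-bearing records (a GT with at least one
alternate allele) become observations.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from .genemodels import GeneInfo, TranscriptModel
from .observations import PREDICTORS, VariantObservation
from .resolution import DivCatalogueEntry

__all__ = [
    "read_patient_vcf",
    "write_patient_vcf",
    "read_annotations",
    "write_annotations",
    "read_manifest",
    "write_manifest",
    "write_gene_models",
    "read_gene_models",
    "write_fasta",
    "read_registry",
    "write_registry",
    "read_div_catalogue",
    "write_div_catalogue",
    "read_div_genotypes",
    "write_div_genotypes",
]

_PRED_COLS = {
    "SIFT": "pred_sift",
    "PolyPhen-2": "pred_polyphen2",
    "Grantham": "pred_grantham",
    "FATHMM": "pred_fathmm",
    "PhyloP": "pred_phylop",
}

MANIFEST_COLUMNS = [
    "patient_id",
    "clinical_class",
    "population_group",
    "presumed_inheritance",
    "familial_samples_available",
]


# ---------------------------------------------------------------- VCF


def _zygosity_from_alleles(alleles: Sequence[int]) -> str | None:
    alts = [a for a in alleles if a > 0]
    if not alts:
        return None
    if len(alleles) == 1:
        return "hemi"
    return "hom" if len(alts) == len(alleles) else "het"


def read_patient_vcf(
    path: str | Path,
    annotations: pd.DataFrame | None = None,
) -> list[VariantObservation]:
    """Read one patient's VCF into annotated observations.

    ``annotations`` is the cohort annotation table indexed by variant_key;
    records without an annotation row are kept with consequence 'other' and
    a warning, never silently dropped.
    """
    ann_map = {}
    if annotations is not None:
        ann_map = annotations.set_index("variant_key").to_dict("index")
    observations = []
    unannotated = 0
    for record in VCF(str(path)):
        alleles = [a for a in record.genotypes[0][:-1] if a is not None and a >= 0]
        zygosity = _zygosity_from_alleles(alleles)
        if zygosity is None:
            continue
        alt = record.ALT[0] if record.ALT else "."
        key = f"{record.CHROM}:{record.POS}:{record.REF}:{alt}"
        row = ann_map.get(key)
        if row is None:
            unannotated += 1
            observations.append(
                VariantObservation(key, "unknown", "other", zygosity)
            )
            continue
        observations.append(_observation_from_row(key, zygosity, row))
    if unannotated:
        warnings.warn(
            f"{path}: {unannotated} genotype-bearing record(s) missing from the "
            "annotation table; carried forward with consequence 'other'"
        )
    return observations


def _clean(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value in ("", "."):
        return None
    return value


def _observation_from_row(key: str, zygosity: str, row: Mapping) -> VariantObservation:
    preds = {}
    for name, col in _PRED_COLS.items():
        call = _clean(row.get(col))
        if call is not None:
            preds[name] = str(call)
    pop_mafs = {
        col[len("maf_") :]: float(v)
        for col, v in row.items()
        if col.startswith("maf_") and _clean(v) is not None
    }
    maf = _clean(row.get("global_maf"))
    spliceai = _clean(row.get("spliceai"))
    return VariantObservation(
        variant_key=key,
        gene_id=str(row.get("gene", "unknown")),
        consequence=str(row.get("consequence", "other")),
        zygosity=zygosity,
        global_maf=float(maf) if maf is not None else None,
        population_mafs=pop_mafs,
        predictor_calls=preds,
        spliceai_score=float(spliceai) if spliceai is not None else None,
        acmg_class=_clean(row.get("acmg_class")),
    )


def write_patient_vcf(
    path: str | Path,
    sample_id: str,
    records: Sequence[tuple[str, int, str, str, str]],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write a minimal sorted single-sample VCF 4.2.

    ``records`` are (contig, pos, ref, alt, gt) tuples; gt is the GT string
    ('0/1', '1/1' or haploid '1').
    """
    order = {c: i for i, c in enumerate(contig_lengths)}
    records = sorted(records, key=lambda r: (order.get(r[0], len(order)), r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=irdscreen-synthetic\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for contig, pos, ref, alt, gt in records:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------- tables


def write_annotations(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_key": str})


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    df["familial_samples_available"] = df["familial_samples_available"].astype(bool)
    return df


def read_registry(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["variant_key"], df["families"].astype(int)))


def write_registry(path: str | Path, registry: Mapping[str, int]) -> None:
    pd.DataFrame(
        {"variant_key": list(registry), "families": list(registry.values())}
    ).to_csv(path, sep="\t", index=False)


def write_div_catalogue(path: str | Path, catalogue: Sequence[DivCatalogueEntry]) -> None:
    pd.DataFrame(
        [
            {
                "gene": e.gene,
                "transcript": e.transcript,
                "cdna_name": e.cdna_name,
                "locus": e.locus,
                "mechanism": e.mechanism,
            }
            for e in catalogue
        ]
    ).to_csv(path, sep="\t", index=False)


def read_div_catalogue(path: str | Path) -> tuple[DivCatalogueEntry, ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(
        DivCatalogueEntry(
            gene=row["gene"],
            transcript=row["transcript"],
            cdna_name=row["cdna_name"],
            locus=row["locus"],
            mechanism=row["mechanism"],
        )
        for _, row in df.iterrows()
    )


def write_div_genotypes(
    path: str | Path, genotypes: Mapping[str, Mapping[str, str]]
) -> None:
    rows = [
        {"patient_id": pid, "locus": locus, "genotype": gt}
        for pid in genotypes
        for locus, gt in genotypes[pid].items()
    ]
    pd.DataFrame(rows, columns=["patient_id", "locus", "genotype"]).to_csv(
        path, sep="\t", index=False
    )


def read_div_genotypes(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["patient_id"], {})[row["locus"]] = row["genotype"]
    return out


# ---------------------------------------------------------------- gene models


def write_gene_models(
    gff3_path: str | Path,
    tsv_path: str | Path,
    models: Sequence[TranscriptModel],
    gene_info: Mapping[str, GeneInfo],
) -> None:
    """Emit models as GFF3 plus a companion gene-metadata TSV."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tm in models:
            lo, hi = tm.span
            fh.write(
                f"{tm.contig}\tirdscreen\tgene\t{lo}\t{hi}\t.\t{tm.strand}\t.\t"
                f"ID={tm.gene_id}\n"
            )
            fh.write(
                f"{tm.contig}\tirdscreen\tmRNA\t{lo}\t{hi}\t.\t{tm.strand}\t.\t"
                f"ID={tm.transcript_id};Parent={tm.gene_id}\n"
            )
            for idx, (s, e) in enumerate(tm.exons, start=1):
                lo_e, hi_e = min(s, e), max(s, e)
                fh.write(
                    f"{tm.contig}\tirdscreen\texon\t{lo_e}\t{hi_e}\t.\t"
                    f"{tm.strand}\t.\tID={tm.transcript_id}.exon{idx};"
                    f"Parent={tm.transcript_id}\n"
                )
            c_lo, c_hi = sorted((tm.cds_start, tm.cds_end))
            fh.write(
                f"{tm.contig}\tirdscreen\tCDS\t{c_lo}\t{c_hi}\t.\t{tm.strand}\t0\t"
                f"ID={tm.transcript_id}.cds;Parent={tm.transcript_id}\n"
            )
    pd.DataFrame(
        [
            {
                "gene": g,
                "transcript": next(
                    tm.transcript_id for tm in models if tm.gene_id == g
                ),
                "inheritance_mode": info.inheritance_mode,
                "associated_classes": "|".join(info.associated_classes),
            }
            for g, info in gene_info.items()
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def _gff3_attributes(field: str) -> dict[str, str]:
    return dict(
        part.split("=", 1) for part in field.strip().split(";") if "=" in part
    )


def read_gene_models(
    gff3_path: str | Path, tsv_path: str | Path
) -> tuple[list[TranscriptModel], dict[str, GeneInfo]]:
    """Load models written by :func:`write_gene_models`."""
    mrna_parent: dict[str, str] = {}
    strands: dict[str, str] = {}
    contigs: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, tuple[int, int]] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff3_path}: malformed GFF3 row: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = fields
            attrs = _gff3_attributes(attrs)
            if ftype == "mRNA":
                tid = attrs["ID"]
                mrna_parent[tid] = attrs["Parent"]
                strands[tid] = strand
                contigs[tid] = contig
            elif ftype == "exon":
                exons.setdefault(attrs["Parent"], []).append(
                    (int(start), int(end))
                )
            elif ftype == "CDS":
                cds[attrs["Parent"]] = (int(start), int(end))
    models = []
    for tid, gene in mrna_parent.items():
        ex = sorted(exons[tid])
        if strands[tid] == "-":
            ex = ex[::-1]
        c_lo, c_hi = cds[tid]
        if strands[tid] == "-":
            cds_start, cds_end = c_hi, c_lo
        else:
            cds_start, cds_end = c_lo, c_hi
        models.append(
            TranscriptModel(
                gene_id=gene,
                transcript_id=tid,
                contig=contigs[tid],
                strand=strands[tid],
                exons=tuple(ex),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    info_df = pd.read_csv(tsv_path, sep="\t")
    gene_info = {
        row["gene"]: GeneInfo(
            gene_id=row["gene"],
            inheritance_mode=row["inheritance_mode"],
            associated_classes=tuple(row["associated_classes"].split("|")),
        )
        for _, row in info_df.iterrows()
    }
    models.sort(key=lambda tm: tm.gene_id)
    return models, gene_info


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
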