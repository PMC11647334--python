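"""Cohort-level diagnostic summaries.

From per-patient resolution calls and the manifest this module derives the
numbers a diagnostic screening study reports: the overall resolution rate
(patients genetically resolved or very likely resolved), rates per clinical
classification and per population group with causal-gene counts, causal
variants recurring in two or more probands, putative novel causal variants
relative to a known-variant catalogue, and patients whose molecular
diagnosis is discordant with the referring clinical diagnosis (candidates
for clinical re-examination).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pipeline import PatientResult

__all__ = [
    "RESOLVED_STATUSES",
    "CohortSummary",
    "calls_to_frame",
    "resolution_rates",
    "recurrent_causal",
    "novel_scan",
    "discordance_check",
    "make_summary",
    "percent_display",
]

#: statuses that count as a probable genetic diagnosis for rate purposes
RESOLVED_STATUSES = frozenset({"genetically_resolved", "very_likely_resolved"})

CALL_COLUMNS = [
    "patient_id",
    "status",
    "rule_id",
    "resolving_gene",
    "causal_variants",
    "phase_confirmed",
]


def percent_display(numerator: int, denominator: int) -> int:
    """Percentage rounded half-up to an integer for display."""
    if denominator == 0:
        return 0
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def calls_to_frame(results: Sequence[PatientResult]) -> pd.DataFrame:
    """Tabulate pipeline results into the resolution-call TSV layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "patient_id": r.patient_id,
                "status": r.call.status,
                "rule_id": r.call.rule_id,
                "resolving_gene": r.call.resolving_gene or "",
                "causal_variants": ";".join(
                    v.variant_key for v in r.call.causal_variants
                ),
                "phase_confirmed": (
                    "" if r.call.phase_confirmed is None else r.call.phase_confirmed
                ),
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _class_label(clinical_class: str) -> str:
    # unclear diagnoses ('Unclear:STGD|BEST') report as their own class
    return "Unclear" if str(clinical_class).startswith("Unclear") else clinical_class


def _merged(manifest: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    m_ids, c_ids = set(manifest["patient_id"]), set(calls["patient_id"])
    if m_ids != c_ids:
        raise ValueError(
            "manifest and resolution calls cover different patients "
            f"(only-manifest: {sorted(m_ids - c_ids)[:5]}, "
            f"only-calls: {sorted(c_ids - m_ids)[:5]})"
        )
    if len(calls) != len(c_ids):
        raise ValueError("expected exactly one resolution call per patient")
    df = manifest.merge(calls, on="patient_id", validate="one_to_one")
    df["class_label"] = df["clinical_class"].map(_class_label)
    df["is_resolved"] = df["status"].isin(RESOLVED_STATUSES)
    return df


@dataclass
class CohortSummary:
    """Cohort-level results bundle."""

    n_patients: int
    n_resolved: int
    overall_resolution_percent: int
    overall_resolution_fraction: float
    by_clinical_class: pd.DataFrame
    by_population: pd.DataFrame
    recurrent_variants: pd.DataFrame | None = None
    novel_variants: pd.DataFrame | None = None
    discordant_patients: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "n_patients": self.n_patients,
            "n_resolved": self.n_resolved,
            "overall_resolution_percent": self.overall_resolution_percent,
            "overall_resolution_fraction": self.overall_resolution_fraction,
            "by_clinical_class": self.by_clinical_class.to_dict("records"),
            "by_population": self.by_population.to_dict("records"),
        }
        for name in ("recurrent_variants", "novel_variants", "discordant_patients"):
            table = getattr(self, name)
            if table is not None:
                out[name] = table.to_dict("records")
        return out

    def render_text(self) -> str:
        lines = [
            "Cohort diagnostic summary",
            "=========================",
            f"Patients: {self.n_patients}",
            f"Resolved (genetically or very likely): {self.n_resolved} "
            f"({self.overall_resolution_percent}%)",
            "",
            "By clinical classification:",
        ]
        for _, row in self.by_clinical_class.iterrows():
            lines.append(
                f"  {row['clinical_class']:<10} {row['resolved_n']:>3}/{row['n']:<3} "
                f"({row['percent']}%)  causal genes: {row['n_causal_genes']}"
            )
        lines.append("")
        lines.append("By population group:")
        for _, row in self.by_population.iterrows():
            lines.append(
                f"  {row['population_group']:<20} {row['resolved_n']:>3}/{row['n']:<3} "
                f"({row['percent']}%)"
            )
        for name, title in (
            ("recurrent_variants", "Recurrent causal variants (>= 2 probands)"),
            ("novel_variants", "Putative novel causal variants"),
            ("discordant_patients", "Clinically discordant molecular diagnoses"),
        ):
            table = getattr(self, name)
            if table is not None:
                lines += ["", f"{title}: {len(table)}"]
        return "\n".join(lines) + "\n"


def resolution_rates(manifest: pd.DataFrame, calls: pd.DataFrame) -> CohortSummary:
    """Resolution rates overall, per clinical class and per population group.

    'Resolved' means genetically resolved or very likely resolved.  The
    per-class table also counts distinct causal genes among that class's
    resolved patients.  Requires exactly one call per manifest patient.
    """
    df = _merged(manifest, calls)
    n = len(df)
    n_res = int(df["is_resolved"].sum())

    class_rows = []
    for label, grp in df.groupby("class_label", sort=True):
        res = grp[grp["is_resolved"]]
        class_rows.append(
            {
                "clinical_class": label,
                "n": len(grp),
                "resolved_n": len(res),
                "percent": percent_display(len(res), len(grp)),
                "n_causal_genes": res["resolving_gene"].replace("", pd.NA).nunique(),
            }
        )
    pop_rows = []
    for group, grp in df.groupby("population_group", sort=True):
        res_n = int(grp["is_resolved"].sum())
        pop_rows.append(
            {
                "population_group": group,
                "n": len(grp),
                "resolved_n": res_n,
                "percent": percent_display(res_n, len(grp)),
            }
        )
    return CohortSummary(
        n_patients=n,
        n_resolved=n_res,
        overall_resolution_percent=percent_display(n_res, n),
        overall_resolution_fraction=n_res / n if n else 0.0,
        by_clinical_class=pd.DataFrame(class_rows),
        by_population=pd.DataFrame(pop_rows),
    )


def _causal_long(calls: pd.DataFrame) -> pd.DataFrame:
    """One row per (proband, causal variant), resolved patients only."""
    rows = []
    for _, row in calls.iterrows():
        if row["status"] not in RESOLVED_STATUSES:
            continue
        for key in str(row["causal_variants"]).split(";"):
            if key:
                rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "variant_key": key,
                        "gene": row["resolving_gene"],
                        "population_group": row.get("population_group", "unknown"),
                    }
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "variant_key", "gene", "population_group"]
    )


def recurrent_causal(calls: pd.DataFrame) -> pd.DataFrame:
    """Causal variants identified in two or more probands.

    ``calls`` must carry a ``population_group`` column (merge the manifest
    first); the output lists per-population proband counts per variant.
    """
    long = _causal_long(calls)
    if long.empty:
        return pd.DataFrame(
            columns=["variant_key", "gene", "n_probands", "population_counts"]
        )
    rows = []
    for (key, gene), grp in long.groupby(["variant_key", "gene"], sort=True):
        probands = grp.drop_duplicates("patient_id")
        if len(probands) < 2:
            continue
        pop_counts = probands["population_group"].value_counts().to_dict()
        rows.append(
            {
                "variant_key": key,
                "gene": gene,
                "n_probands": len(probands),
                "population_counts": json.dumps(pop_counts, sort_keys=True),
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_key", "gene", "n_probands", "population_counts"]
    )


def novel_scan(calls: pd.DataFrame, known_catalogue: Iterable[str]) -> pd.DataFrame:
    """Causal variants absent from the known-variant catalogue.

    Novelty is relative to the supplied catalogue (published variants plus
    any in-house database the user maintains); the output carries per-variant
    proband counts.
    """
    known = set(known_catalogue)
    long = _causal_long(calls)
    rows = []
    if not long.empty:
        for (key, gene), grp in long.groupby(["variant_key", "gene"], sort=True):
            if key in known:
                continue
            rows.append(
                {
                    "variant_key": key,
                    "gene": gene,
                    "n_probands": grp["patient_id"].nunique(),
                }
            )
    return pd.DataFrame(rows, columns=["variant_key", "gene", "n_probands"])


def discordance_check(
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    gene_disease_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Patients whose resolving gene is not associated with their diagnosis.

    A patient is discordant when the resolving gene's associated disease set
    does not contain the clinical class; for unclear diagnoses a match with
    any candidate diagnosis counts as concordant.  Genes missing from the
    map are flagged 'unmappable' rather than silently treated as discordant.
    """
    df = _merged(manifest, calls)
    rows = []
    for _, row in df.iterrows():
        if not row["is_resolved"] or not row["resolving_gene"]:
            continue
        gene = row["resolving_gene"]
        clinical = str(row["clinical_class"])
        if clinical.startswith("Unclear"):
            _, _, rest = clinical.partition(":")
            patient_classes = {c for c in rest.split("|") if c}
        else:
            patient_classes = {clinical}
        if gene not in gene_disease_map:
            verdict = "unmappable"
            diseases: tuple[str, ...] = ()
        else:
            diseases = tuple(gene_disease_map[gene])
            verdict = (
                "concordant"
                if patient_classes & set(diseases)
                else "discordant"
            )
        if verdict == "concordant":
            continue
        rows.append(
            {
                "patient_id": row["patient_id"],
                "clinical_class": clinical,
                "resolving_gene": gene,
                "gene_associated_diseases": "|".join(diseases),
                "verdict": verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "clinical_class",
            "resolving_gene",
            "gene_associated_diseases",
            "verdict",
        ],
    )


def make_summary(
    results: Sequence[PatientResult],
    manifest: pd.DataFrame,
    known_catalogue: Iterable[str] = (),
    gene_disease_map: Mapping[str, Iterable[str]] | None = None,
) -> CohortSummary:
    """Full cohort summary from pipeline results."""
    calls = calls_to_frame(results)
    summary = resolution_rates(manifest, calls)
    with_pop = calls.merge(
        manifest[["patient_id", "population_group"]], on="patient_id"
    )
    summary.recurrent_variants = recurrent_causal(with_pop)
    summary.novel_variants = novel_scan(with_pop, known_catalogue)
    if gene_disease_map is not None:
        gene_to_classes = {}
        for cls, genes in gene_disease_map.items():
            for g in genes:
                gene_to_classes.setdefault(g, set()).add(cls)
        summary.discordant_patients = discordance_check(
            calls, manifest, {g: sorted(c) for g, c in gene_to_classes.items()}
        )
    return summary
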