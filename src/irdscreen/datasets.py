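"""Packaged reference catalogues.

Three small curated tables ship with the package:

* the default deep-intronic screening catalogue — seven published,
  functionally verified deep intronic variants in ABCA4, CEP290 and USH2A
  (pseudoexon inclusion or exon skipping);
* the recurrent causal variants reported from the South African IRD panel
  cohort, with per-population proband counts;
* the putative novel causal variants from the same cohort.

The latter two load as resolution-call frames so the cohort-report
operations can be exercised on published per-proband counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .resolution import DivCatalogueEntry

__all__ = [
    "load_div_catalogue",
    "load_published_recurrent_table",
    "load_published_recurrent_calls",
    "load_published_novel_table",
    "load_published_novel_calls",
]

_POP_COLS = {
    "n_indigenous_african": "Indigenous African",
    "n_caucasian": "Caucasian",
    "n_mixed_ancestry": "Mixed ancestry",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("irdscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_div_catalogue() -> tuple[DivCatalogueEntry, ...]:
    """The default seven-variant deep-intronic screening catalogue."""
    df = _read("div_catalogue.tsv")
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


def load_published_recurrent_table() -> pd.DataFrame:
    return _read("published_recurrent_variants.tsv")


def load_published_novel_table() -> pd.DataFrame:
    return _read("published_novel_variants.tsv")


def _expand_probands(rows) -> pd.DataFrame:
    """One synthetic resolved call per reported proband."""
    out = []
    counter = 0
    for variant_key, gene, pop, count in rows:
        for _ in range(int(count)):
            counter += 1
            out.append(
                {
                    "patient_id": f"PUB{counter:04d}",
                    "status": "genetically_resolved",
                    "rule_id": "published",
                    "resolving_gene": gene,
                    "causal_variants": variant_key,
                    "phase_confirmed": "",
                    "population_group": pop,
                }
            )
    return pd.DataFrame(out)


def load_published_recurrent_calls() -> pd.DataFrame:
    """Per-proband call frame expanded from the recurrent-variant counts."""
    df = load_published_recurrent_table()
    rows = []
    for _, row in df.iterrows():
        key = f"{row['gene']}:{row['cdna']}"
        for col, pop in _POP_COLS.items():
            if row[col] > 0:
                rows.append((key, row["gene"], pop, row[col]))
    return _expand_probands(rows)


def load_published_novel_calls() -> pd.DataFrame:
    """Per-proband call frame expanded from the novel-variant counts."""
    df = load_published_novel_table()
    rows = [
        (
            f"{row['gene']}:{row['cdna']}",
            row["gene"],
            "unknown",
            row["n_probands"],
        )
        for _, row in df.iterrows()
    ]
    return _expand_probands(rows)
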