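"""Artefact elimination list and cohort-recurrence screening.

Amplicon panel sequencing produces recurrent platform artefacts — calls that
appear across unrelated samples at frequencies no genuine rare variant
could.  The canonical example in IRD panels is a 1-bp deletion reported as
likely pathogenic in ClinVar yet present in every sample of a cohort.  The
registry keeps a manually curated elimination list (only listed variants are
ever excluded from analysis) and a recurrence scanner that flags candidates
for that curation: recurrence alone never auto-excludes, since founder
variants legitimately recur in a population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["EliminationList", "recurrence_scan"]

_COLUMNS = ["contig", "pos", "ref", "alt", "reason", "date"]


@dataclass
class EliminationList:
    """Curated set of artefact variant keys with free-text reason and date."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, EliminationList) and self.entries == other.entries

    def keys_set(self) -> set[str]:
        return set(self.entries)

    def add(self, key: str, reason: str = "", date: str = "") -> None:
        self.entries[key] = (reason, date)

    def merge(self, other: "EliminationList") -> "EliminationList":
        """Set-union merge; idempotent, other's metadata wins on collision."""
        merged = dict(self.entries)
        merged.update(other.entries)
        return EliminationList(merged)

    @classmethod
    def load(cls, path: str | Path) -> "EliminationList":
        entries: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _COLUMNS:
                raise ValueError(f"{path}: expected header {_COLUMNS}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != len(_COLUMNS):
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}: {line!r}"
                    )
                contig, pos, ref, alt, reason, date = fields
                try:
                    int(pos)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer position at line {lineno}"
                    ) from None
                entries[f"{contig}:{pos}:{ref}:{alt}"] = (reason, date)
        return cls(entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(_COLUMNS) + "\n")
            for key in sorted(self.entries):
                contig, pos, ref, alt = key.split(":")
                reason, date = self.entries[key]
                fh.write("\t".join([contig, pos, ref, alt, reason, date]) + "\n")


def recurrence_scan(
    cohort_variants: Mapping[str, Iterable[str]],
    review_fraction: float = 0.05,
    family_ids: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flag variants recurring across the cohort as artefact candidates.

    ``cohort_variants`` maps patient_id -> iterable of variant keys carried
    by that patient.  Reports, per variant, the fraction of probands carrying
    it; fractions at or above ``review_fraction`` (default 5%) are flagged
    for review and a fraction of exactly 1.0 is additionally labelled a
    probable artefact.  When ``family_ids`` is given only one proband per
    family is counted, so founder alleles segregating in a sampled family do
    not inflate the fraction.
    """
    if len(cohort_variants) < 2:
        raise ValueError("recurrence scan needs at least 2 patients")
    if family_ids:
        seen_families: set[str] = set()
        probands = {}
        for pid in sorted(cohort_variants):
            fam = family_ids.get(pid, pid)
            if fam in seen_families:
                continue
            seen_families.add(fam)
            probands[pid] = cohort_variants[pid]
    else:
        probands = dict(cohort_variants)
    n = len(probands)
    counts: dict[str, int] = {}
    for keys in probands.values():
        for key in set(keys):
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for key in sorted(counts):
        frac = counts[key] / n
        rows.append(
            {
                "variant_key": key,
                "n_carriers": counts[key],
                "n_probands": n,
                "fraction": frac,
                "flagged_for_review": frac >= review_fraction,
                "probable_artefact": frac == 1.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_key",
            "n_carriers",
            "n_probands",
            "fraction",
            "flagged_for_review",
            "probable_artefact",
        ],
    )
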