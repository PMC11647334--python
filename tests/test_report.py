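"""Cohort summaries: rates, recurrence, novelty, discordance."""

import pandas as pd
import pytest

from irdscreen.datasets import (
    load_div_catalogue,
    load_published_novel_calls,
    load_published_recurrent_calls,
)
from irdscreen.report import (
    calls_to_frame,
    discordance_check,
    make_summary,
    novel_scan,
    percent_display,
    recurrent_causal,
    resolution_rates,
)


def make_cohort(n, n_resolved, cls="RP", pop="Caucasian"):
    manifest = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "clinical_class": [cls] * n,
            "population_group": [pop] * n,
            "presumed_inheritance": ["Unknown"] * n,
            "familial_samples_available": [False] * n,
        }
    )
    calls = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "status": [
                "genetically_resolved" if i < n_resolved else "unresolved"
                for i in range(n)
            ],
            "rule_id": ["resolved_i" if i < n_resolved else "unresolved"
                        for i in range(n)],
            "resolving_gene": ["G1" if i < n_resolved else "" for i in range(n)],
            "causal_variants": ["G1:c.1A>T" if i < n_resolved else ""
                                for i in range(n)],
            "phase_confirmed": [""] * n,
        }
    )
    return manifest, calls


class TestResolutionRates:
    def test_75_of_135_prints_56_percent(self):
        manifest, calls = make_cohort(135, 75)
        summary = resolution_rates(manifest, calls)
        assert summary.n_resolved == 75
        assert summary.overall_resolution_percent == 56

    def test_all_unresolved_zero_everywhere(self):
        manifest, calls = make_cohort(20, 0)
        summary = resolution_rates(manifest, calls)
        assert summary.overall_resolution_percent == 0
        assert (summary.by_clinical_class["percent"] == 0).all()
        assert (summary.by_population["percent"] == 0).all()

    def test_very_likely_resolved_counts_as_resolved(self):
        manifest, calls = make_cohort(4, 2)
        calls.loc[0, "status"] = "very_likely_resolved"
        calls.loc[2, "status"] = "potential_diagnosis"
        summary = resolution_rates(manifest, calls)
        assert summary.n_resolved == 2  # potential does not count

    def test_per_class_counts_sum_to_cohort(self):
        manifest, calls = make_cohort(30, 12)
        manifest.loc[10:, "clinical_class"] = "STGD"
        manifest.loc[20:, "clinical_class"] = "Unclear:STGD|BEST"
        summary = resolution_rates(manifest, calls)
        assert summary.by_clinical_class["n"].sum() == 30
        assert summary.by_clinical_class["resolved_n"].sum() == summary.n_resolved
        assert "Unclear" in set(summary.by_clinical_class["clinical_class"])

    def test_patient_set_mismatch_rejected(self):
        manifest, calls = make_cohort(5, 2)
        with pytest.raises(ValueError, match="different patients"):
            resolution_rates(manifest.iloc[:4], calls)

    @pytest.mark.parametrize(
        "num,den,pct", [(75, 135, 56), (1, 3, 33), (1, 2, 50), (55, 99, 56)]
    )
    def test_percent_display_half_up(self, num, den, pct):
        assert percent_display(num, den) == pct


class TestRecurrentCausal:
    def test_two_probands_listed_one_absent(self):
        manifest, calls = make_cohort(3, 3)
        calls["causal_variants"] = ["G1:a", "G1:a", "G1:b"]
        with_pop = calls.merge(
            manifest[["patient_id", "population_group"]], on="patient_id"
        )
        table = recurrent_causal(with_pop)
        assert list(table["variant_key"]) == ["G1:a"]
        assert table.iloc[0]["n_probands"] == 2

    def test_order_invariant_and_idempotent(self):
        manifest, calls = make_cohort(4, 4)
        calls["causal_variants"] = ["G1:a", "G1:b", "G1:a", "G1:b"]
        with_pop = calls.merge(
            manifest[["patient_id", "population_group"]], on="patient_id"
        )
        t1 = recurrent_causal(with_pop)
        t2 = recurrent_causal(with_pop.iloc[::-1])
        assert t1.equals(t2)
        assert recurrent_causal(with_pop).equals(t1)

    def test_published_counts_17_variants_9_genes(self):
        table = recurrent_causal(load_published_recurrent_calls())
        assert len(table) == 17
        assert table["gene"].nunique() == 9


class TestNovelScan:
    def test_catalogued_variant_not_novel(self):
        manifest, calls = make_cohort(2, 2)
        calls["causal_variants"] = ["G1:a", "G1:b"]
        table = novel_scan(calls, known_catalogue={"G1:a"})
        assert list(table["variant_key"]) == ["G1:b"]

    def test_empty_catalogue_everything_novel(self):
        manifest, calls = make_cohort(2, 2)
        calls["causal_variants"] = ["G1:a", "G1:b"]
        assert len(novel_scan(calls, known_catalogue=())) == 2

    def test_published_counts_16_variants_12_genes(self):
        table = novel_scan(load_published_novel_calls(), known_catalogue=())
        assert len(table) == 16
        assert table["gene"].nunique() == 12
        assert table["n_probands"].max() == 2  # one variant seen in two probands


class TestDiscordance:
    GENE_MAP = {"CRB1x": ["LCA", "RP"], "RS1x": ["RS"], "RPgene": ["RP"]}

    def make(self, cls, gene):
        manifest, calls = make_cohort(1, 1, cls=cls)
        calls["resolving_gene"] = gene
        return calls, manifest

    def test_rs_patient_resolved_by_lca_rp_gene_discordant(self):
        calls, manifest = self.make("RS", "CRB1x")
        table = discordance_check(calls, manifest, self.GENE_MAP)
        assert list(table["verdict"]) == ["discordant"]
        assert table.iloc[0]["gene_associated_diseases"] == "LCA|RP"

    def test_stgd_patient_resolved_by_rs_gene_discordant(self):
        calls, manifest = self.make("STGD", "RS1x")
        assert len(discordance_check(calls, manifest, self.GENE_MAP)) == 1

    def test_concordant_patient_absent(self):
        calls, manifest = self.make("RP", "RPgene")
        assert discordance_check(calls, manifest, self.GENE_MAP).empty

    def test_unclear_matching_any_candidate_is_concordant(self):
        calls, manifest = self.make("Unclear:STGD|RS", "RS1x")
        assert discordance_check(calls, manifest, self.GENE_MAP).empty

    def test_unmapped_gene_flagged_unmappable(self):
        calls, manifest = self.make("RP", "GHOST")
        table = discordance_check(calls, manifest, self.GENE_MAP)
        assert list(table["verdict"]) == ["unmappable"]


class TestMakeSummary:
    def test_end_to_end_summary_from_synthetic_cohort(self, small_cohort):
        import warnings

        from irdscreen.pipeline import run_cohort

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_cohort(
                small_cohort.patients, small_cohort.models, small_cohort.catalogues
            )
        summary = make_summary(
            results,
            small_cohort.manifest,
            known_catalogue=small_cohort.catalogues.known_variants,
            gene_disease_map=small_cohort.catalogues.gene_disease_map,
        )
        truth = small_cohort.truth
        expected_resolved = int(
            truth["expected_status"]
            .isin(["genetically_resolved", "very_likely_resolved"])
            .sum()
        )
        assert summary.n_resolved == expected_resolved
        assert summary.by_clinical_class["n"].sum() == len(small_cohort.patients)
        text = summary.render_text()
        assert f"{summary.overall_resolution_percent}%" in text


class TestDivCatalogueData:
    def test_seven_default_entries_in_three_genes(self):
        catalogue = load_div_catalogue()
        assert len(catalogue) == 7
        assert {e.gene for e in catalogue} == {"ABCA4", "CEP290", "USH2A"}
        assert all(
            e.mechanism in ("pseudoexon_inclusion", "exon_skipping")
            for e in catalogue
        )
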