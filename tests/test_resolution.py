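"""Resolution-status clauses, phase handling and the deep-intronic merge."""

import copy
import itertools

import pytest

from irdscreen.observations import VariantObservation
from irdscreen.pipeline import run_cohort
from irdscreen.resolution import (
    STATUS_ORDER,
    DivCatalogueEntry,
    classify_resolution,
    merge_div_screen,
)
from irdscreen.synthetic import CohortDesign, generate_cohort

GENE_INH = {"GA": "AD", "GR": "AR", "GX": "XL"}


def obs(gene, zyg, acmg, key="k"):
    return VariantObservation(
        variant_key=f"{gene}:{key}:{zyg}:{acmg}",
        gene_id=gene,
        consequence="missense",
        zygosity=zyg,
        acmg_class=acmg,
    )


def oracle_status(inheritance, variants, phase_confirmed):
    """Hand-built truth table, independent of the implementation.

    ``variants`` is a list of (zygosity, acmg_class) in one gene.
    """
    plp = [(z, c) for z, c in variants if c in ("P", "LP")]
    vus = [(z, c) for z, c in variants if c == "VUS"]
    if inheritance in ("AD", "XL"):
        if plp:
            return "genetically_resolved"
        if vus:
            return "potential_diagnosis"
        return "unresolved"
    # AR
    if any(z == "hom" for z, _ in plp):
        return "genetically_resolved"
    het_plp = [v for v in plp if v[0] == "het"]
    het_vus = [v for v in vus if v[0] == "het"]
    if len(het_plp) >= 2:
        return "genetically_resolved" if phase_confirmed else "very_likely_resolved"
    if het_plp and het_vus:
        return "potential_diagnosis"
    if len(het_vus) >= 2 or any(z == "hom" for z, _ in vus):
        return "potential_diagnosis"
    return "unresolved"


class TestClauses:
    def test_single_het_pathogenic_ad_gene_resolved(self):
        call = classify_resolution([obs("GA", "het", "P")], GENE_INH)
        assert call.status == "genetically_resolved"
        assert call.rule_id == "resolved_i"

    def test_hom_pathogenic_ar_gene_resolved_without_phase(self):
        call = classify_resolution(
            [obs("GR", "hom", "LP")], GENE_INH, familial_available=False
        )
        assert call.status == "genetically_resolved"
        assert call.rule_id == "resolved_ii"

    def test_comphet_with_confirmed_trans_resolved(self):
        call = classify_resolution(
            [obs("GR", "het", "P", "a"), obs("GR", "het", "LP", "b")],
            GENE_INH,
            familial_available=True,
            phase_confirmed=True,
        )
        assert call.status == "genetically_resolved"
        assert call.rule_id == "resolved_iii"

    def test_comphet_without_familial_samples_very_likely(self):
        call = classify_resolution(
            [obs("GR", "het", "LP", "a"), obs("GR", "het", "LP", "b")],
            GENE_INH,
            familial_available=False,
            phase_confirmed=False,
        )
        assert call.status == "very_likely_resolved"

    def test_het_plp_plus_het_vus_ar_is_potential(self):
        call = classify_resolution(
            [obs("GR", "het", "LP", "a"), obs("GR", "het", "VUS", "b")], GENE_INH
        )
        assert call.status == "potential_diagnosis"
        assert call.rule_id == "potential_i"

    def test_monoallelic_ar_pathogenic_unresolved(self):
        call = classify_resolution([obs("GR", "het", "P")], GENE_INH)
        assert call.status == "unresolved"

    def test_hemizygous_xl_resolved_under_clause_i(self):
        call = classify_resolution([obs("GX", "hemi", "P")], GENE_INH)
        assert call.status == "genetically_resolved"
        assert call.rule_id == "resolved_i"

    def test_het_xl_resolved_with_carrier_note(self):
        call = classify_resolution([obs("GX", "het", "P")], GENE_INH)
        assert call.status == "genetically_resolved"
        assert any("carrier" in n for n in call.notes)

    def test_unknown_inheritance_gene_excluded_and_logged(self):
        call = classify_resolution([obs("G?", "het", "P")], {"G?": "mystery"})
        assert call.status == "unresolved"
        assert any("unknown inheritance" in n for n in call.notes)

    def test_two_gene_tie_flagged_for_review(self):
        call = classify_resolution(
            [obs("GA", "het", "P"), obs("GX", "hemi", "P")], GENE_INH
        )
        assert call.status == "genetically_resolved"
        assert call.needs_review


class TestTruthTableOracle:
    def test_exhaustive_up_to_two_variants(self):
        """All (zygosity x class x inheritance x phase) combos of <= 2 variants."""
        classes = ("P", "LP", "VUS", "LB", "B")
        checked = 0
        for inh in ("AD", "AR", "XL"):
            gene = {"AD": "GA", "AR": "GR", "XL": "GX"}[inh]
            zygs = ("het", "hom", "hemi") if inh == "XL" else ("het", "hom")
            singles = list(itertools.product(zygs, classes))
            combos = [()] + [(v,) for v in singles] + [
                pair for pair in itertools.product(singles, singles)
            ]
            for variants in combos:
                variants = list(variants) if variants and isinstance(
                    variants[0], tuple
                ) else list(variants)
                for phase in (None, False, True):
                    for familial in (False, True):
                        cands = [
                            obs(gene, z, c, key=f"v{i}")
                            for i, (z, c) in enumerate(variants)
                        ]
                        call = classify_resolution(
                            cands, GENE_INH, familial, phase
                        )
                        assert call.status == oracle_status(
                            inh, variants, phase
                        ), (inh, variants, phase, familial)
                        checked += 1
        assert checked > 1000

    def test_exactly_one_clause_fires(self):
        """Every call names a rule and non-unresolved calls carry evidence."""
        for z, c in itertools.product(("het", "hom"), ("P", "VUS", "B")):
            for inh_gene in ("GA", "GR"):
                call = classify_resolution([obs(inh_gene, z, c)], GENE_INH)
                assert call.rule_id
                if call.status != "unresolved":
                    assert call.causal_variants
                    assert call.resolving_gene == inh_gene


class TestMonotoneEvidence:
    def test_upgrading_vus_never_downgrades_status(self):
        rank = {s: i for i, s in enumerate(STATUS_ORDER)}
        base_sets = [
            [("het", "VUS")],
            [("het", "VUS"), ("het", "VUS")],
            [("het", "P"), ("het", "VUS")],
            [("hom", "VUS")],
        ]
        for gene in ("GA", "GR"):
            for variants in base_sets:
                before = classify_resolution(
                    [obs(gene, z, c, key=f"v{i}") for i, (z, c) in enumerate(variants)],
                    GENE_INH,
                )
                for i, (z, c) in enumerate(variants):
                    if c != "VUS":
                        continue
                    upgraded = list(variants)
                    upgraded[i] = (z, "LP")
                    after = classify_resolution(
                        [
                            obs(gene, z2, c2, key=f"v{j}")
                            for j, (z2, c2) in enumerate(upgraded)
                        ],
                        GENE_INH,
                    )
                    assert rank[after.status] >= rank[before.status]

    def test_phase_confirmation_upgrades_comphet_only(self):
        comphet = [obs("GR", "het", "P", "a"), obs("GR", "het", "LP", "b")]
        unconfirmed = classify_resolution(comphet, GENE_INH, True, None)
        confirmed = classify_resolution(comphet, GENE_INH, True, True)
        assert unconfirmed.status == "very_likely_resolved"
        assert confirmed.status == "genetically_resolved"
        hom = [obs("GR", "hom", "P")]
        assert (
            classify_resolution(hom, GENE_INH, False, None).status
            == classify_resolution(hom, GENE_INH, True, True).status
            == "genetically_resolved"
        )


CATALOGUE = (
    DivCatalogueEntry("GR", "T1", "c.100+200A>G", "GR:c.100+200A>G", "pseudoexon_inclusion"),
)


class TestDivMerge:
    def test_all_reference_genotypes_identity(self):
        cands = [obs("GR", "het", "P")]
        assert merge_div_screen(cands, {"GR:c.100+200A>G": "0/0"}, CATALOGUE) == cands

    def test_nonref_div_added_as_pathogenic_flagged(self):
        merged = merge_div_screen([], {"GR:c.100+200A>G": "0/1"}, CATALOGUE)
        assert len(merged) == 1
        div = merged[0]
        assert div.acmg_class == "P"
        assert div.zygosity == "het"
        assert "deep_intronic_catalogue" in div.flags

    def test_div_converts_monoallelic_to_comphet(self):
        cands = merge_div_screen(
            [obs("GR", "het", "P")], {"GR:c.100+200A>G": "0/1"}, CATALOGUE
        )
        call = classify_resolution(cands, GENE_INH, familial_available=False)
        assert call.status == "very_likely_resolved"

    def test_unknown_locus_rejected(self):
        with pytest.raises(KeyError, match="not in catalogue"):
            merge_div_screen([], {"nowhere": "0/1"}, CATALOGUE)

    def test_screen_strictly_increases_resolution_rate(self, models_bundle):
        """Paired cohort run: with vs without the supplemental screen."""
        design = CohortDesign(
            n_patients=8, category_mix={"div-resolvable": 1.0}, seed=5
        )
        cohort = generate_cohort(design, models_bundle)
        with_screen = run_cohort(cohort.patients, cohort.models, cohort.catalogues)
        stripped = copy.deepcopy(cohort.patients)
        for p in stripped:
            p.div_genotypes = {}
        without = run_cohort(stripped, cohort.models, cohort.catalogues)
        resolved = lambda rs: sum(
            r.call.status in ("genetically_resolved", "very_likely_resolved")
            for r in rs
        )
        assert resolved(with_screen) > resolved(without)
        assert resolved(with_screen) == len(cohort.patients)
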