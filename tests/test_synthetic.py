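"""Synthetic cohort generator: determinism, construction invariants, truth."""

import hashlib
import warnings
from pathlib import Path

import pytest
from Bio.Seq import Seq

from irdscreen.alu import MotifPair
from irdscreen.pipeline import run_cohort
from irdscreen.synthetic import (
    CATEGORIES,
    EXPECTED_STATUS,
    CohortDesign,
    generate_alu_fastq,
    generate_cohort,
    generate_gene_models,
)


def tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestGeneModels:
    def test_same_seed_identical_models(self, tmp_path):
        import irdscreen.io as iomod

        for d in ("a", "b"):
            models, info, contigs = generate_gene_models(1, seed=7)
            out = tmp_path / d
            out.mkdir()
            iomod.write_gene_models(
                out / "m.gff3", out / "m.tsv", models, info
            )
            iomod.write_fasta(out / "ref.fa", contigs)
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_cds_is_translatable_without_internal_stops(self, models_bundle):
        models, _, contigs = models_bundle
        for tm in models:
            seq = contigs[tm.contig]
            if tm.strand == "+":
                cds = "".join(seq[s - 1 : e] for s, e in tm.exons_genomic)
            else:
                cds = str(
                    Seq(
                        "".join(seq[s - 1 : e] for s, e in tm.exons_genomic)
                    ).reverse_complement()
                )
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_gene_attributes_valid(self, models_bundle):
        models, info, _ = models_bundle
        assert len(models) == 10
        for tm in models:
            assert 2 <= len(tm.exons) <= 10
            meta = info[tm.gene_id]
            assert meta.inheritance_mode in ("AD", "AR", "XL")
            assert len(meta.associated_classes) >= 1

    def test_exon_edges_classifiable(self, models_bundle):
        from irdscreen.genemodels import classify_position

        models, _, _ = models_bundle
        for tm in models:
            for s, e in tm.exons_genomic:
                for pos in (s, e):
                    label = classify_position(tm.contig, pos, models).label
                    assert label == "exonic_splice_junction"

    def test_invalid_n_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            generate_gene_models(0, seed=1)


class TestCohortDesign:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortDesign(category_mix={"resolved-AD": 0.5})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown categories"):
            CohortDesign(category_mix={"spontaneously-cured": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        design = CohortDesign(n_patients=12, seed=4)
        design.to_yaml(tmp_path / "d.yaml")
        assert CohortDesign.from_yaml(tmp_path / "d.yaml") == design


class TestGenerateCohort:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            bundle = generate_gene_models(6, seed=3)
            generate_cohort(
                CohortDesign(n_patients=12, seed=5), bundle, tmp_path / d
            )
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_degenerate_mix_all_resolved_ad(self, models_bundle):
        design = CohortDesign(
            n_patients=5, category_mix={"resolved-AD": 1.0}, seed=2,
            artefact_rate=0.0,
        )
        cohort = generate_cohort(design, models_bundle)
        assert len(cohort.patients) == 5
        info = cohort.gene_info
        for t in cohort.truth.itertuples():
            keys = t.planted_causal_variants.split(",")
            assert len(keys) == 1
            assert t.planted_category == "resolved-AD"
        for patient, t in zip(cohort.patients, cohort.truth.itertuples()):
            causal = [
                o for o in patient.observations
                if o.variant_key == t.planted_causal_variants
            ]
            assert len(causal) == 1
            assert causal[0].acmg_class in ("P", "LP")
            assert info[causal[0].gene_id].inheritance_mode in ("AD", "XL")
            assert causal[0].zygosity in ("het", "hemi")

    def test_artefact_rate_one_plants_in_every_vcf(self, models_bundle):
        design = CohortDesign(n_patients=10, artefact_rate=1.0, seed=6)
        cohort = generate_cohort(design, models_bundle)
        artefact_keys = set(cohort.catalogues.elimination_list)
        assert artefact_keys
        for patient in cohort.patients:
            assert artefact_keys & {o.variant_key for o in patient.observations}

    def test_impossible_category_rejected(self):
        # a single gene is pinned to AD, so recessive categories cannot be planted
        bundle = generate_gene_models(1, seed=1)
        with pytest.raises(ValueError, match="inheritance mode AR"):
            generate_cohort(
                CohortDesign(n_patients=3, category_mix={"resolved-hom-AR": 1.0}),
                bundle,
            )

    def test_vcf_refs_match_reference_sequence(self, small_cohort, tmp_path):
        cohort = small_cohort
        for patient in cohort.patients[:10]:
            for o in patient.observations:
                contig, pos, ref, _ = o.variant_key.split(":")
                pos = int(pos)
                seq = cohort.contig_sequences[contig]
                assert seq[pos - 1 : pos - 1 + len(ref)] == ref

    def test_benign_background_straddles_maf_cutoff(self, small_cohort):
        mafs = [
            o.global_maf
            for p in small_cohort.patients
            for o in p.observations
            if o.acmg_class in ("B", "LB") and o.global_maf is not None
        ]
        assert any(m > 0.06 for m in mafs)
        assert any(m <= 0.06 for m in mafs)

    def test_truth_recovery_on_full_mixed_design(self, models_bundle):
        """Planted categories map to the expected resolution status."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = generate_cohort(
                CohortDesign(n_patients=60, seed=3), models_bundle
            )
            results = run_cohort(
                cohort.patients, cohort.models, cohort.catalogues
            )
        truth = cohort.truth.set_index("patient_id")
        for r in results:
            assert r.call.status == truth.loc[r.patient_id, "expected_status"]

    def test_every_category_has_an_expected_status(self):
        assert set(CATEGORIES) == set(EXPECTED_STATUS)


class TestGenerateAluFastq:
    def test_background_reads_motif_free(self, tmp_path):
        """Exhaustive scan: no planted background read contains either motif."""
        pair = MotifPair()
        path = generate_alu_fastq(0, 0, 300, 60, 8, tmp_path / "bg.fastq")
        patterns = pair.wildtype_patterns() + pair.mutant_patterns()
        with open(path) as fh:
            lines = fh.read().splitlines()
        assert len(lines) == 4 * 300
        for i in range(0, len(lines), 4):
            assert not any(p in lines[i + 1] for p in patterns)

    def test_read_len_below_motif_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="read_len"):
            generate_alu_fastq(1, 1, 1, 22, 0, tmp_path / "x.fastq")

    def test_negative_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError, match=">= 0"):
            generate_alu_fastq(-1, 0, 0, 50, 0, tmp_path / "x.fastq")

    def test_same_seed_identical_bytes(self, tmp_path):
        a = generate_alu_fastq(5, 5, 50, 60, 4, tmp_path / "a.fastq")
        b = generate_alu_fastq(5, 5, 50, 60, 4, tmp_path / "b.fastq")
        assert a.read_bytes() == b.read_bytes()
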