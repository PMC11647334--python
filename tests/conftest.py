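import warnings

import pytest

from irdscreen.genemodels import TranscriptModel
from irdscreen.synthetic import CohortDesign, generate_cohort, generate_gene_models


@pytest.fixture(scope="session")
def models_bundle():
    """Ten synthetic genes with their metadata and contig sequences."""
    return generate_gene_models(10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(models_bundle):
    """A 40-patient cohort over the default mixes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortDesign(n_patients=40, seed=11), models_bundle)


@pytest.fixture
def two_exon_plus():
    """Hand-built plus-strand transcript: exons 101-200 and 501-600."""
    return TranscriptModel(
        gene_id="G1",
        transcript_id="T1",
        contig="chrT",
        strand="+",
        exons=((101, 200), (501, 600)),
        cds_start=101,
        cds_end=600,
    )


@pytest.fixture
def single_exon_plus():
    """Single-exon transcript spanning bases 1-10."""
    return TranscriptModel(
        gene_id="G2",
        transcript_id="T2",
        contig="chrS",
        strand="+",
        exons=((1, 10),),
        cds_start=1,
        cds_end=9,
    )
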