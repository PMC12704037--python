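import datetime as dt

import pytest

from litscreen.fixtures import dcn_like_corpus
from litscreen.model import (
    Backend,
    CandidateInput,
    IdType,
    PublicationRecord,
    ResolvedCandidate,
    Scope,
    SearchSpec,
    Term,
    TermClass,
)
from litscreen.resolve import OfflineSynonymTable, SynonymRecord


@pytest.fixture(scope="session")
def dcn_corpus():
    return dcn_like_corpus()


@pytest.fixture()
def synonym_table():
    return OfflineSynonymTable([
        SynonymRecord("P00001", 10090, "FIXG1", ("FIXS1A", "FIXS1B"), ("Fixprotein one", "FP-1")),
        SynonymRecord("P00002", 10090, "FIXG2", (), ("Fixprotein two",)),
        SynonymRecord("P00003", 9606, "FIXG3", ("FIXS3A",), ()),
    ])


@pytest.fixture()
def decorin_candidate():
    """Hand-built bundle mirroring the classic decorin synonym set."""
    return ResolvedCandidate(
        input=CandidateInput("DCN", IdType.GENE_NAME, 9606),
        primary_accession="PX9001",
        terms=(
            Term("DCN", TermClass.GENE_NAME),
            Term("SLRR1B", TermClass.SYNONYM),
            Term("Decorin", TermClass.PROTEIN_NAME),
            Term("Bone-proteoglycan-II", TermClass.PROTEIN_NAME),
            Term("PG-S2", TermClass.PROTEIN_NAME),
            Term("PG40", TermClass.PROTEIN_NAME),
        ),
        is_valid=True,
    )


@pytest.fixture()
def tiny_corpus():
    """Six documents with known term/keyword placement."""
    d = dt.date
    return [
        PublicationRecord("p1", "Decorin roles in cancer biology", "filler text",
                          ("Journal Article",), d(2018, 5, 1), Backend.OFFLINE),
        PublicationRecord("p2", "Decorin and cancer stroma", "more filler",
                          ("Journal Article", "Review"), d(2019, 1, 2), Backend.OFFLINE),
        PublicationRecord("p3", "Decorin without the keyword", "no disease words",
                          ("Journal Article",), d(2017, 3, 3), Backend.OFFLINE),
        PublicationRecord("p4", "cancer but no term here", "unrelated",
                          ("Journal Article",), d(2020, 7, 4), Backend.OFFLINE),
        PublicationRecord("p5", "nothing relevant at all", "Decorin only in abstract with cancer",
                          ("Journal Article",), d(2016, 9, 5), Backend.OFFLINE),
        PublicationRecord("p6", "DCN expression in cancer", "",
                          ("Journal Article",), d(2015, 11, 6), Backend.OFFLINE),
    ]


@pytest.fixture()
def title_spec():
    return SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY, backend=Backend.OFFLINE)


@pytest.fixture()
def wide_spec():
    return SearchSpec(keywords=("cancer",), scope=Scope.TITLE_AND_ABSTRACT, backend=Backend.OFFLINE)
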