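import pytest

from seizekit.evidence import CitationRecord, EvidenceDatabase


def record(gene, species="human", source="1", source_type="pmid",
           evidence_class="variant_association", note=None):
    return CitationRecord(
        gene_symbol=gene, species=species, evidence_class=evidence_class,
        source_type=source_type, source_id=source, phenotype_note=note,
    )


@pytest.fixture
def tiny_db():
    """Two genes, three records: GENEA human+rodent, GENEB human."""
    return EvidenceDatabase(
        [
            record("GENEA", "human", "1"),
            record("GENEA", "rodent", "2"),
            record("GENEB", "human", "3"),
        ]
    )


@pytest.fixture
def tiny_evidence_tsv(tmp_path):
    path = tmp_path / "evidence.tsv"
    path.write_text(
        "gene_symbol\tspecies\tevidence_class\tsource_type\tsource_id\tphenotype_note\tyear\n"
        "GENEA\thuman\tvariant_association\tpmid\t1\tDravet syndrome\t2018\n"
        "GENEA\trodent\tdirect_manipulation\tpmid\t2\t\t\n"
        "GENEB\thuman\tvariant_association\tpmid\t3\t\t2020\n"
    )
    return path
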