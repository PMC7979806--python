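import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pikkmap.catalog import MutationCatalog, MutationRecord, parse_protein_change


def make_record(gene, sample, ctype, change):
    return MutationRecord(
        gene=gene,
        sample_id=sample,
        cancer_type=ctype,
        protein_change=change,
        **parse_protein_change(change),
    )


@pytest.fixture
def small_catalog():
    """Five records, three samples, two genes, two cancer types."""
    records = [
        make_record("ATM", "S1", "colorectal", "S100F"),
        make_record("ATM", "S1", "colorectal", "Q200*"),
        make_record("ATM", "S2", "endometrial", "S100Y"),
        make_record("ATR", "S2", "endometrial", "E300del"),
        make_record("ATR", "S3", "colorectal", "K400fs"),
    ]
    return MutationCatalog(records=records, cohort_size=10)


@pytest.fixture
def catalog_tsv(tmp_path):
    path = tmp_path / "mutations.tsv"
    path.write_text(
        "gene\tsample_id\tcancer_type\tprotein_change\n"
        "ATM\tS1\tcolorectal\tS100F\n"
        "ATM\tS1\tcolorectal\tQ200*\n"
        "ATM\tS2\tendometrial\tS100Y\n"
        "ATR\tS2\tendometrial\tE300del\n"
        "ATR\tS3\tcolorectal\tK400fs\n"
    )
    return path
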