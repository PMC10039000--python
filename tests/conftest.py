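import pytest

from p53cc import genotyping, reference_data
from p53cc.expression import ExpressionMatrix
from p53cc.pipeline import run_analysis
from p53cc.synthetic_data import paper_shaped_fixture, write_bundle


@pytest.fixture(scope="session")
def paper_bundle():
    """Study-shaped synthetic cohort: 21 types, 67 candidate genes."""
    return paper_shaped_fixture(seed=1)


@pytest.fixture(scope="session")
def bundle_dir(paper_bundle, tmp_path_factory):
    """The bundle written to disk in the pipeline's input formats."""
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(paper_bundle, out)
    return out


@pytest.fixture(scope="session")
def ta_records(bundle_dir):
    return reference_data.load_transactivation_table(bundle_dir / "transactivation.tsv")


@pytest.fixture(scope="session")
def paper_result(paper_bundle, bundle_dir, ta_records):
    """Full pipeline result on the study-shaped cohort (file-parsed inputs)."""
    calls = genotyping.read_maf(bundle_dir / "variants.tsv")
    expr = ExpressionMatrix(values=paper_bundle.expression, unit="FPKM")
    return run_analysis(
        calls, paper_bundle.sample_sheet, expr, ta_records, paper_bundle.pathway_map
    )
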