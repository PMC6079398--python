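import pandas as pd
import pytest
from hypothesis import settings

from sscnet import ExpressionTable, GeneScoreTable, score_table

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_table(rows, a_label="pSGA", b_label="SGA") -> ExpressionTable:
    return ExpressionTable(
        data=pd.DataFrame(rows, columns=["gene", "fpkm_a", "fpkm_b"]),
        condition_a_label=a_label,
        condition_b_label=b_label,
    )


@pytest.fixture
def four_gene_scores() -> GeneScoreTable:
    """The fully hand-computable 4-gene table: a=[1,2,3,4], b=[4,3,2,1].

    By symmetry g1/g4 have avg_percentile 0.625, change_pct 1.2, index
    0.75; g2/g3 have avg_percentile 0.625, change_pct 0.4, index 0.25.
    """
    return score_table(
        make_table([("g1", 1.0, 4.0), ("g2", 2.0, 3.0), ("g3", 3.0, 2.0), ("g4", 4.0, 1.0)])
    )


@pytest.fixture
def fpkm_file(tmp_path):
    def _write(text, name="expr.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
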