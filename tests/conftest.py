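import numpy as np
import pandas as pd
import pytest

from netmarker.expression_io import ExpressionMatrix, SampleAnnotation


def make_expression(values, gene_ids=None, sample_ids=None, groups=None):
    """Build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    ann = None
    if groups is not None:
        ann = SampleAnnotation(groups=pd.Series(list(groups), index=sample_ids))
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        annotation=ann,
    )


@pytest.fixture
def tiny_tsv(tmp_path):
    """3 probes x 2 samples plain TSV."""
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "probe\tsA\tsB\n"
        "p1\t2\t6\n"
        "p2\t4\t2\n"
        "p3\t1.5\t3.25\n"
    )
    return path


@pytest.fixture
def series_matrix_file(tmp_path):
    """Minimal GEO series-matrix dialect fixture (synthetic)."""
    path = tmp_path / "series.txt"
    path.write_text(
        "!Series_title\t\"synthetic fixture\"\n"
        "!Series_platform_id\t\"GPLTEST\"\n"
        "!series_matrix_table_begin\n"
        '"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\n'
        '"p1"\t1.5\t2.5\t3.5\n'
        '"p2"\t4\t5\t6\n'
        "!series_matrix_table_end\n"
        "!Series_end\n"
    )
    return path


@pytest.fixture
def annotation_file(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "sample_id\tgroup\tmmse\n"
        "sA\thealthy\t28\n"
        "sB\tincipient\t25\n"
    )
    return path
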