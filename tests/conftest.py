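import pandas as pd
import pytest

from stresstalk.io import DETable


def make_table(label, rows):
    """rows: iterable of (gene_id, log2fc, adj_p) with adj_p possibly None."""
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "adj_p"])
    return DETable(contrast_label=label, data=df)


@pytest.fixture
def small_table():
    return make_table(
        "toy",
        [
            ("G1", 0.60, 0.01),
            ("G2", 0.585, 0.001),
            ("G3", -1.2, 0.04),
            ("G4", 2.0, None),
            ("G5", 0.1, 0.90),
            ("G6", 1.1, 0.01),
            ("G7", 0.8, 0.01),
        ],
    )


@pytest.fixture
def de_table_file(tmp_path):
    path = tmp_path / "de.tsv"
    path.write_text(
        "gene_id\tlog2fc\tadj_p\n"
        "AT1G01010\t1.5\t0.001\n"
        "AT1G01020\t-0.9\t0.02\n"
        "AT1G01030\t0.2\tNA\n"
    )
    return path


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "terms.gmt"
    path.write_text(
        "T1\thypoxia response\tG1\tG2\tG3\n"
        "T2\tdefense response\tG2\tG4\tG4\tG5\n"
    )
    return path
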