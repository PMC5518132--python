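import numpy as np
import pytest

from pbnpa.screen_io import ScreenCountTable


@pytest.fixture
def tiny_table() -> ScreenCountTable:
    """Four sgRNAs over two genes, hand-sized for exact checks."""
    return ScreenCountTable(
        sgrna_ids=np.array(["sg1", "sg2", "sg3", "sg4"], dtype=object),
        gene_ids=np.array(["A", "A", "B", "B"], dtype=object),
        control=np.array([10, 20, 30, 40]),
        treatment=np.array([20, 10, 90, 40]),
    )


@pytest.fixture
def count_file(tmp_path):
    """A canonical MAGeCK-style count TSV with two replicate pairings."""
    path = tmp_path / "counts.tsv"
    path.write_text(
        "sgRNA\tGene\tctrl1\ttreat1\tctrl2\ttreat2\n"
        "sg1\tA\t10\t20\t12\t18\n"
        "sg2\tA\t20\t10\t22\t12\n"
        "sg3\tB\t30\t90\t28\t85\n"
        "sg4\tB\t40\t40\t41\t39\n"
    )
    return path


def make_table(control, treatment, genes=None) -> ScreenCountTable:
    control = np.asarray(control)
    n = len(control)
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    return ScreenCountTable(
        sgrna_ids=np.array([f"sg{i}" for i in range(n)], dtype=object),
        gene_ids=np.asarray(genes, dtype=object),
        control=control,
        treatment=np.asarray(treatment),
    )
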