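import numpy as np
import pytest

from clue.preprocessing import TemporalMatrix


@pytest.fixture
def toy_matrix() -> TemporalMatrix:
    """Nine sites, four time points, three obvious shape groups."""
    rng = np.random.default_rng(42)
    base = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],  # rising
            [3.0, 2.0, 1.0, 0.0],  # falling
            [0.0, 3.0, 3.0, 0.0],  # transient
        ]
    )
    values = np.repeat(base, 3, axis=0) + rng.normal(0, 0.05, size=(9, 4))
    return TemporalMatrix(
        site_ids=[f"G{i};S{i + 1}" for i in range(9)],
        time_labels=["t0", "t1", "t2", "t3"],
        values=values,
    )


@pytest.fixture
def psp_table(tmp_path):
    """A PhosphoSitePlus-style table with banner lines and mixed species."""
    lines = [
        "PhosphoSitePlus(R) kinase-substrate dataset",
        "",
        "KINASE\tSUBSTRATE\tSUB_ORG\tSUB_MOD_RSD",
        "AKT1\tBAD\thuman\tS136",
        "AKT1\tBAD\thuman\tS136",  # duplicate row
        "AKT1\tTSC2\thuman\tS939",
        "SGK1\tBAD\thuman\tS136",  # multi-kinase site
        "AKT1\tGsk3b\tmouse\tS9",
    ]
    path = tmp_path / "ks.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
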