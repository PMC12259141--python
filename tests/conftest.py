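import numpy as np
import pandas as pd
import pytest

from boolimpl import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with clean low/high structure."""
    data = pd.DataFrame(
        [
            [1.0, 1.2, 3.0, 3.2],
            [3.1, 3.0, 1.1, 0.9],
            [2.0, 2.1, 2.0, 1.9],
        ],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def write_tsv(tmp_path):
    """Write a DataFrame (or raw text) as a TSV file and return the path."""

    def _write(obj, name="matrix.tsv", **kwargs):
        path = tmp_path / name
        if isinstance(obj, str):
            path.write_text(obj)
        else:
            obj.to_csv(path, sep="\t", **kwargs)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
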