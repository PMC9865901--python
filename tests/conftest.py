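import numpy as np
import pandas as pd
import pytest

from pyramidkit.genotype import Bin, BinGenotypeMatrix


def make_matrix(codes: dict[str, list[str]], bins: list[tuple[str, int, int]]
                ) -> BinGenotypeMatrix:
    """Build a BinGenotypeMatrix from {line: codes} and (chrom, start, end) bins."""
    bin_objs = [Bin(*b) for b in bins]
    df = pd.DataFrame.from_dict(codes, orient="index",
                                columns=[b.key for b in bin_objs])
    df.index.name = "line_id"
    return BinGenotypeMatrix(bins=bin_objs, codes=df)


@pytest.fixture
def tiny_matrix():
    """2 lines x 3 bins on one chromosome."""
    return make_matrix(
        {"L1": ["F", "F", "M"], "L2": ["M", "NA", "F"]},
        [("chr1", 1, 100), ("chr1", 101, 200), ("chr1", 201, 300)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230114)
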