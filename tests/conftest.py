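import numpy as np
import pytest

from sweepscan import GenotypeMatrix, PopulationMap


def build_matrix(dosages, positions=None, chrom="chr1", sample_prefix="S"):
    """GenotypeMatrix from a plain nested list of dosages (rows = SNPs)."""
    dos = np.asarray(dosages, dtype=np.int8)
    n, m = dos.shape
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    return GenotypeMatrix(
        chroms=np.array([chrom] * n, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        dosages=dos,
        sample_ids=[f"{sample_prefix}{i}" for i in range(m)],
    )


def split_popmap(matrix, n_focal, focal="NY", reference="Others"):
    """Assign the first n_focal samples to the focal panel, the rest to reference."""
    assignments = {
        s: (focal if i < n_focal else reference)
        for i, s in enumerate(matrix.sample_ids)
    }
    return PopulationMap(assignments, focal_label=focal, reference_label=reference)


@pytest.fixture
def small_matrix():
    # 4 SNPs x 6 samples, one missing call
    return build_matrix(
        [
            [0, 1, 2, 0, 1, 2],
            [0, 0, 0, 2, 2, 2],
            [1, 1, -1, 1, 1, 0],
            [2, 2, 2, 2, 2, 2],
        ],
        positions=[101, 205, 333, 480],
    )


@pytest.fixture
def small_popmap(small_matrix):
    return split_popmap(small_matrix, 3)
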