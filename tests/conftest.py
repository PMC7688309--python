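import numpy as np
import pytest
import scipy.sparse as sp

from screg.io import CellRecord, Peak, PeakMatrix, PeakSet


def make_cells(n, usable_reads=2000, complexity=5000.0, age_group="3yo", cluster="AT2",
               donor_id="D1", sex="F", prefix="BC"):
    return [
        CellRecord(
            barcode=f"{prefix}{i}",
            donor_id=donor_id,
            age_group=age_group,
            sex=sex,
            cluster=cluster,
            usable_reads=usable_reads,
            library_complexity=complexity,
        )
        for i in range(n)
    ]


def make_peaks(n, chrom="chr1", width=400, gap=4000):
    return PeakSet(
        [Peak(chrom, 1000 + i * (width + gap), 1000 + i * (width + gap) + width, f"p{i}")
         for i in range(n)]
    )


def make_matrix(counts, cells=None, peaks=None):
    counts = np.asarray(counts)
    n_peaks, n_cells = counts.shape
    if peaks is None:
        peaks = make_peaks(n_peaks)
    if cells is None:
        cells = make_cells(n_cells)
    return PeakMatrix(sp.csr_matrix(counts), peaks, cells)


@pytest.fixture
def tiny_matrix():
    counts = np.zeros((2, 3), dtype=int)
    counts[0, 0] = 3
    counts[1, 2] = 1
    return make_matrix(counts)
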