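import numpy as np
import pytest

from trapline.tables_io import FrapTrace, IdentificationTable, ProteinRecord


def record(accession, unique_peptides=3, psms=6, gene_symbol=None, ms_score=100.0):
    return ProteinRecord(
        accession=accession,
        gene_symbol=gene_symbol if gene_symbol is not None else f"G{accession}",
        unique_peptides=unique_peptides,
        psms=psms,
        ms_score=ms_score,
    )


def table(records, sample_id="s1", bait="wt", condition="trap", replicate=1):
    return IdentificationTable.from_records(
        records, sample_id=sample_id, bait=bait,
        condition=condition, replicate=replicate,
    )


@pytest.fixture
def small_table():
    return table([record("P1"), record("P2", psms=10), record("P3", psms=2)])


def make_trace(t_half=5.0, ymax=1.0, noise_sd=0.0, times=None, rng=None,
               trace_id="t1", normalized=True):
    if times is None:
        times = np.arange(2.0, 61.0, 2.0)
    y = ymax * times / (t_half + times)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0, noise_sd, times.size)
    if normalized:
        pre, post = 1.0, 0.0
        intensities = y
    else:
        pre, post = 1000.0, 200.0
        intensities = post + (pre - post) * y
    return FrapTrace(
        trace_id=trace_id,
        times=tuple(float(t) for t in times),
        intensities=tuple(float(v) for v in intensities),
        prebleach_value=pre,
        postbleach_value=post,
    )
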