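import io

import numpy as np
import pytest

from nucparticle import (
    LOW_DIGESTION,
    WILDTYPE,
    SizeClassSpec,
    build_histogram,
    build_model,
    make_synthetic_genome,
    read_sam,
    simulate_fragments,
    stratify,
)
from nucparticle.track import BinnedTrack

# Minimal hand-checkable SAM: 3 proper pairs (one on chrII) + 1 unmapped pair.
FIXTURE_SAM = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chrI\tLN:20000
@SQ\tSN:chrII\tLN:15000
p1\t99\tchrI\t1001\t42\t50M\t=\t1101\t150\t*\t*
p1\t147\tchrI\t1101\t42\t50M\t=\t1001\t-150\t*\t*
p2\t99\tchrI\t2001\t42\t50M\t=\t2121\t170\t*\t*
p2\t147\tchrI\t2121\t42\t50M\t=\t2001\t-170\t*\t*
p3\t99\tchrII\t501\t42\t50M\t=\t552\t101\t*\t*
p3\t147\tchrII\t552\t42\t50M\t=\t501\t-101\t*\t*
p4\t77\t*\t0\t0\t*\t*\t0\t0\t*\t*
p4\t141\t*\t0\t0\t*\t*\t0\t0\t*\t*
"""


@pytest.fixture
def fixture_sam_text() -> str:
    return FIXTURE_SAM


@pytest.fixture
def fixture_sam_stream():
    return io.StringIO(FIXTURE_SAM)


def make_track(values, chrom="chr1", bin_width=10, provenance="raw") -> BinnedTrack:
    values = np.asarray(values, dtype=float)
    return BinnedTrack(
        chrom=chrom,
        bin_width=bin_width,
        length_bp=values.size * bin_width,
        values=values,
        provenance=provenance,
    )


@pytest.fixture
def track_factory():
    return make_track


def simulate_to_tracks(
    n_genes=20, condition=WILDTYPE, digestion=LOW_DIGESTION,
    mean_frags=50.0, seed=1, **model_kwargs,
):
    """Full simulate → SAM → ingest → stratify → histogram round trip."""
    chrom_lengths, features = make_synthetic_genome(n_genes=n_genes)
    model = build_model(chrom_lengths, features, **model_kwargs)
    reads = simulate_fragments(model, condition, digestion, mean_frags, seed=seed)
    buf = io.StringIO()
    reads.write_sam(buf)
    buf.seek(0)
    sam = read_sam(buf)
    spec = SizeClassSpec(150)
    midpoints = stratify(sam.records, spec)
    raw = build_histogram(midpoints, sam.chrom_lengths)
    return model, features, reads, raw


@pytest.fixture(scope="session")
def wildtype_run():
    """One wild-type simulation shared by the slower end-to-end tests."""
    import io as _io

    chrom_lengths, features = make_synthetic_genome(n_genes=20)
    model = build_model(chrom_lengths, features)
    reads = simulate_fragments(model, WILDTYPE, LOW_DIGESTION, 50.0, seed=1)
    buf = _io.StringIO()
    reads.write_sam(buf)
    buf.seek(0)
    sam = read_sam(buf)
    midpoints = stratify(sam.records, SizeClassSpec(150))
    raw = build_histogram(midpoints, sam.chrom_lengths)
    return model, features, reads, raw
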