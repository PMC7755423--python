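import pytest

from cdrmatrix import load_property_table
from cdrmatrix.sequence_io import (
    LABEL_NONPOLY,
    LABEL_POLY,
    LOOP_NAMES,
    SequenceRecord,
    encode_repertoire,
)
from cdrmatrix.synthetic_fixtures import FixtureSpec, generate_repertoire

#: Compact fixed-length loop layout used by the recovery fixtures: every loop
#: has a single length so loop positions map to unique matrix columns.
COMPACT_LOOPS = {
    "cdr1l": (4,), "cdr2l": (3,), "cdr3l": (4,),
    "cdr1h": (4,), "cdr2h": (8,), "cdr3h": (6,),
}

#: Variant with a length-10 CDR2H, used by the strong-signal classifier
#: fixture (the charge shift spans the whole loop).
STRONG_SIGNAL_LOOPS = {**COMPACT_LOOPS, "cdr2h": (10,)}
STRONG_SIGNAL_POSITIONS = tuple(range(10))


@pytest.fixture(scope="session")
def table():
    return load_property_table()


def make_records(loops_list, labels, counts=None):
    counts = counts or [0] * len(loops_list)
    return [
        SequenceRecord(
            id=f"r{i}",
            loops=dict(zip(LOOP_NAMES, loops)),
            reactivity_count=counts[i],
            label=labels[i],
        )
        for i, loops in enumerate(loops_list)
    ]


@pytest.fixture
def tiny_matrix():
    """Two records per class, all loops length 3, buffer 1."""
    loops_a = ("CAR", "LHR", "AAA", "CCC", "DDD", "EEE")
    loops_b = ("CAR", "LHR", "AAA", "CCC", "DDD", "FFF")
    records = make_records(
        [loops_a, loops_a, loops_b, loops_b],
        [LABEL_POLY, LABEL_POLY, LABEL_NONPOLY, LABEL_NONPOLY],
    )
    return encode_repertoire(records, buffer_width=1)


@pytest.fixture(scope="session")
def null_repertoire():
    """Signal-free two-class repertoire (compact loops, uniform background)."""
    spec = FixtureSpec(
        n_polyreactive=60, n_nonpolyreactive=60,
        loop_lengths=COMPACT_LOOPS, seed=11,
    )
    records, _ = generate_repertoire(spec)
    return encode_repertoire(records)
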