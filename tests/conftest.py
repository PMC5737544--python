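"""Shared fixtures: synthetic references, guide sets and SAM record builders."""

import pysam
import pytest

import utrdissect as u


@pytest.fixture(scope="session")
def synthetic_ref():
    """Standard 781-nt AT-rich synthetic UTR with 64 planted PAM sites."""
    return u.make_synthetic_utr(seed=11)


@pytest.fixture(scope="session")
def synthetic_guides(synthetic_ref):
    return u.enumerate_guides(synthetic_ref)


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 2000}]}
    )


@pytest.fixture
def make_record(sam_header):
    """Build a mapped AlignedSegment with a given CIGAR and position."""

    def _make(cigar: str, pos: int = 0, name: str = "read1", flag: int = 0):
        rec = pysam.AlignedSegment(sam_header)
        rec.query_name = name
        rec.flag = flag
        rec.reference_id = 0
        rec.reference_start = pos
        rec.mapping_quality = 60
        rec.cigarstring = cigar
        read_len = sum(
            ln for op, ln in rec.cigartuples if op in (0, 1, 4, 7, 8)
        )
        rec.query_sequence = "A" * read_len
        return rec

    return _make


def make_at_background(length: int) -> list:
    """AT-alternating background: no GG/CC, no AATAAA."""
    return list(("AT" * (length // 2 + 1))[:length])
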