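"""Shared fixtures: library profiles and small synthetic datasets."""

from __future__ import annotations

import pytest

from petforge.core_io import LibraryProfile, MappedTagPair, TagAlignment

# the two mate-pair libraries with their printed concordant span ranges
LIB_10K = LibraryProfile("IXT010", 9_600.0, 5_997, 11_961)
LIB_17K = LibraryProfile("IXT011", 17_500.0, 9_318, 22_026)


@pytest.fixture
def lib_10k() -> LibraryProfile:
    return LIB_10K


@pytest.fixture
def lib_17k() -> LibraryProfile:
    return LIB_17K


def make_pair(pair_id, ref1, s1, strand1, ref2, s2, strand2,
              lib="IXT010", tag_len=27) -> MappedTagPair:
    """Terse constructor for mapped pairs in tests."""
    return MappedTagPair(
        str(pair_id), lib,
        TagAlignment(ref1, s1, s1 + tag_len, strand1),
        TagAlignment(ref2, s2, s2 + tag_len, strand2),
    )


def concordant_pair(pair_id, ref, start, span, strand="+", lib="IXT010",
                    tag_len=27) -> MappedTagPair:
    """A geometrically concordant pair covering [start, start+span)."""
    left = (start, "+") if strand == "+" else (start + span - tag_len, "-")
    right = (start + span - tag_len, "+") if strand == "+" else (start, "-")
    if strand == "+":
        return make_pair(pair_id, ref, start, "+", ref,
                         start + span - tag_len, "+", lib, tag_len)
    return make_pair(pair_id, ref, start + span - tag_len, "-", ref,
                     start, "-", lib, tag_len)
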