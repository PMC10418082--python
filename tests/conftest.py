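"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from trnacharge.reference import ReferenceSet, TranscriptRecord
from trnacharge.simulate import DEFAULT_ADAPTERS


def sw_oracle(query: str, ref: str, scheme) -> int:
    """Independent exhaustive local-alignment DP.

    Deliberately written without affine gap states: each cell considers every
    possible gap length explicitly (O(n^3)), with a gap of length L costing
    ``gap_open + gap_extend * (L - 1)``.  Reference N columns score
    ``n_score`` for any query base.
    """
    m, n = len(query), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if ref[j - 1] == "N":
                sub = scheme.n_score
            elif query[i - 1] == ref[j - 1]:
                sub = scheme.match
            else:
                sub = scheme.mismatch
            v = max(0, H[i - 1][j - 1] + sub)
            for g in range(1, j + 1):
                v = max(v, H[i][j - g] - (scheme.gap_open + scheme.gap_extend * (g - 1)))
            for g in range(1, i + 1):
                v = max(v, H[i - g][j] - (scheme.gap_open + scheme.gap_extend * (g - 1)))
            H[i][j] = v
            best = max(best, v)
    return best


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def toy_reference() -> ReferenceSet:
    """Four hand-built CCA-ending transcripts spanning two anticodons."""
    return ReferenceSet(
        [
            TranscriptRecord(
                id="tRNA-Lys-TTT-1-1",
                sequence="GCCCGGATAGCTCAGTCGGTAGAGCATCAGACTTTTAATCTGAGGGTCCAGGGTTCAAGTCCCTGTTCGGGCGCCA",
                amino_acid="Lys",
                anticodon="TTT",
            ),
            TranscriptRecord(
                id="tRNA-Lys-TTT-1-2",
                sequence="GCCCGGATAGCTCAGTCGGTAGAGCATCAGACTTTTAATCTGAGGGTCCAGGGTTCAAGTCCCTGTTCGGGCACCA",
                amino_acid="Lys",
                anticodon="TTT",
            ),
            TranscriptRecord(
                id="tRNA-Ala-AGC-1-1",
                sequence="GGGGGTGTAGCTCAGTGGTAGAGCGCGTGCTTAGCATGCACGAGGTCCTGGGTTCGATCCCCAGCACCTCCACCA",
                amino_acid="Ala",
                anticodon="AGC",
            ),
            TranscriptRecord(
                id="tRNA-His-GTG-1-1",
                sequence="GCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGTGGCCGCAGCAACCTCGGTTCGAATCCGAGTCACGGCACCA",
                amino_acid="His",
                anticodon="GTG",
            ),
        ]
    )


@pytest.fixture(scope="session")
def adapters():
    return list(DEFAULT_ADAPTERS)
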