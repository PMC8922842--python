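"""Shared genetic-code helpers and reproducible RNG substreams.

Translation uses the bacterial/archaeal code (NCBI table 11) throughout;
start-codon recoding is deliberately ignored (internal codons only).
"""

from __future__ import annotations

import zlib

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TABLE11 = unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, with '*' for stop codons (table 11)
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE11.stop_codons)

#: the 61 sense codons in lexicographic order — the fixed dimension ordering
#: for codon-usage-bias vectors
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon``; '*' for stops, 'X' if ambiguous."""
    return CODON_TO_AA.get(codon.upper(), "X")


def locus_rng(seed: int, genome_id: str, position: int) -> np.random.Generator:
    """Generator for one genomic locus, independent of iteration order.

    The substream is keyed on (seed, crc32(genome_id), position) so any
    traversal order of loci reproduces identical draws for a fixed seed.
    """
    key = [int(seed) & 0x7FFFFFFF, zlib.crc32(genome_id.encode()), int(position)]
    return np.random.default_rng(key)
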