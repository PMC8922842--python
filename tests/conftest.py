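"""Shared fixtures: in-memory alignment records and small communities."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from metadiv import simulate as sim


def make_header(genomes: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": g, "LN": L} for g, L in genomes.items()],
        }
    )


def make_aln(
    header: pysam.AlignmentHeader,
    name: str = "read",
    ref: str = "g1",
    start: int = 0,
    cigar: str = "100M",
    seq: str | None = None,
    qual: int = 30,
    nm: int = 0,
    flag: int = 0,
) -> pysam.AlignedSegment:
    """Build an AlignedSegment without touching the filesystem."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = list(header.references).index(ref)
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = cigar
    qlen = a.infer_query_length()
    if seq is None:
        seq = "A" * qlen
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    a.set_tag("NM", nm)
    return a


@pytest.fixture(scope="session")
def header100():
    return make_header({"g1": 1000})


@pytest.fixture(scope="session")
def small_community():
    """Two genomes, two samples, planted SNPs incl. a linked codon pair."""
    spec = sim.CommunitySpec(
        populations=[
            sim.PopulationSpec("genA", 6000, {"s1": 40.0, "s2": 25.0}, n_genes=4),
            sim.PopulationSpec("genB", 5000, {"s1": 15.0, "s2": 50.0}, n_genes=3),
        ],
        seed=11,
    )
    com0 = sim.build_community(spec)
    gene = next(g for g in com0.genes if g.genome_id == "genA" and g.strand == "+")
    from metadiv.variant_calling import codon_genome_positions

    p0, _, p2 = codon_genome_positions(gene, 5)
    ref = com0.genomes["genA"]

    def alt_of(base: str) -> str:
        return {"A": "G", "C": "T", "G": "A", "T": "C"}[base]

    spec.populations[0].snps = [
        sim.SnpPlan(p0, alt_of(ref[p0]), 0.30, link_group="L1"),
        sim.SnpPlan(p2, alt_of(ref[p2]), 0.30, link_group="L1"),
        sim.SnpPlan(700, alt_of(ref[700]), 0.20),
    ]
    return sim.build_community(spec)
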