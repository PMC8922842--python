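"""Read filtering, coverage profiles, population detection, abundance.

Pre-processing turns per-sample alignments into (a) a filtered alignment
set (>= 95% nucleotide identity over the aligned span, >= 30 aligned bp by
default), (b) per-genome coverage profiles, (c) a detection decision per
preset, and (d) a quantile-truncated mean depth used as the raw abundance
of each detected population.

Alignment identity is computed as 1 - NM / (M + I + D) over the CIGAR,
the standard alignment-level identity (the aligned span counts matches,
mismatches, insertions and deletions; soft clips are excluded). Secondary
and supplementary alignments are discarded before any filtering so depth
is never double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

# CIGAR operation codes (pysam numeric encoding)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_EQ, _OP_X = 0, 1, 2, 3, 4, 7, 8
_ALN_SPAN_OPS = frozenset({_OP_M, _OP_I, _OP_D, _OP_EQ, _OP_X})
_REF_DEPTH_OPS = frozenset({_OP_M, _OP_EQ, _OP_X})


@dataclass(frozen=True)
class DetectionPreset:
    """Detection rules for deciding a population is present in a sample.

    ``viral`` and ``fragmented_bacterial`` share the length-switched rule:
    genomes longer than ``long_genome_bp`` are detected when at least
    ``min_breadth_bp`` positions are covered; shorter genomes when at least
    ``min_breadth_frac`` of their length is covered. ``complete_bacterial``
    uses a single breadth fraction (default 20%). Every threshold is
    user-overridable.
    """

    mode: str
    min_id: float = 0.95
    min_read_len: int = 30
    long_genome_bp: int = 5000
    min_breadth_bp: int = 5000
    min_breadth_frac: float = 0.70
    complete_min_breadth_frac: float = 0.20

    _MODES = ("viral", "fragmented_bacterial", "complete_bacterial")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown preset mode {self.mode!r}; expected one of {self._MODES}")

    @classmethod
    def viral(cls, **kw) -> "DetectionPreset":
        return cls("viral", **kw)

    @classmethod
    def fragmented_bacterial(cls, **kw) -> "DetectionPreset":
        return cls("fragmented_bacterial", **kw)

    @classmethod
    def complete_bacterial(cls, **kw) -> "DetectionPreset":
        return cls("complete_bacterial", **kw)


@dataclass
class FilterSummary:
    """Per-sample tally of kept vs removed alignments (output (i))."""

    sample_id: str
    kept: int = 0
    removed_identity: int = 0
    removed_length: int = 0

    @property
    def removed(self) -> int:
        return self.removed_identity + self.removed_length


@dataclass
class CoverageProfile:
    """Per-position read depth of one genome in one sample."""

    genome_id: str
    sample_id: str
    depth: np.ndarray  # int array, length == genome length

    @property
    def length(self) -> int:
        return int(self.depth.size)

    @property
    def breadth_bp(self) -> int:
        return int(np.count_nonzero(self.depth))

    @property
    def breadth_frac(self) -> float:
        return self.breadth_bp / self.length if self.length else 0.0

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.length else 0.0


@dataclass
class AbundanceRecord:
    genome_id: str
    sample_id: str
    raw_abundance: float
    detected: bool


def alignment_span(aln: pysam.AlignedSegment) -> int:
    """Alignment span in bp: matches + mismatches + insertions + deletions."""
    if aln.cigartuples is None:
        raise ValueError(f"read {aln.query_name!r} has no CIGAR")
    return sum(length for op, length in aln.cigartuples if op in _ALN_SPAN_OPS)


def percent_identity(aln: pysam.AlignedSegment) -> float:
    """Fraction identity 1 - NM/span of one alignment.

    Raises ``ValueError`` (naming the read) when the NM tag is absent —
    identity cannot be inferred without an edit distance.
    """
    if not aln.has_tag("NM"):
        raise ValueError(f"read {aln.query_name!r} lacks an NM (edit distance) tag")
    nm = int(aln.get_tag("NM"))
    span = alignment_span(aln)
    if span <= 0:
        raise ValueError(f"read {aln.query_name!r} has a zero-length alignment span")
    return 1.0 - nm / span


def query_aligned_length(aln: pysam.AlignedSegment) -> int:
    """Aligned query bases (soft-clipped bases excluded, insertions included)."""
    if aln.cigartuples is None:
        return 0
    return sum(length for op, length in aln.cigartuples if op in (_OP_M, _OP_I, _OP_EQ, _OP_X))


def filter_reads(
    alignments: Iterable[pysam.AlignedSegment],
    preset: DetectionPreset,
    sample_id: str = "sample",
) -> tuple[list[pysam.AlignedSegment], FilterSummary]:
    """Keep mapped primary alignments passing the identity and length rules.

    Unmapped, secondary and supplementary records are dropped silently
    (they are not part of the filter tally). An input with no mapped reads
    yields an empty output plus a warning, not an error.
    """
    summary = FilterSummary(sample_id=sample_id)
    kept: list[pysam.AlignedSegment] = []
    saw_any = False
    for aln in alignments:
        saw_any = True
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if query_aligned_length(aln) < preset.min_read_len:
            summary.removed_length += 1
            continue
        if percent_identity(aln) < preset.min_id:
            summary.removed_identity += 1
            continue
        summary.kept += 1
        kept.append(aln)
    if saw_any and not kept and summary.removed == 0:
        warnings.warn(f"sample {sample_id!r}: no mapped primary alignments in input")
    return kept, summary


def coverage_profile(
    alignments: Iterable[pysam.AlignedSegment],
    genome_id: str,
    genome_length: int,
    sample_id: str = "sample",
) -> CoverageProfile:
    """Depth per reference position from filtered alignments.

    Only reference-consuming aligned ops (M/=/X) add depth; deleted and
    skipped reference positions (D/N) stay uncovered by that read.
    """
    depth = np.zeros(genome_length, dtype=np.int64)
    for aln in alignments:
        rpos = aln.reference_start
        for op, length in aln.cigartuples:
            if op in _REF_DEPTH_OPS:
                if rpos + length > genome_length:
                    raise ValueError(
                        f"read {aln.query_name!r} extends past the end of "
                        f"{genome_id} (length {genome_length})"
                    )
                depth[rpos : rpos + length] += 1
                rpos += length
            elif op in (_OP_D, _OP_N):
                rpos += length
    return CoverageProfile(genome_id=genome_id, sample_id=sample_id, depth=depth)


def detect(profile: CoverageProfile, preset: DetectionPreset) -> bool:
    """Apply the preset detection rule to one coverage profile."""
    if preset.mode == "complete_bacterial":
        return profile.breadth_frac >= preset.complete_min_breadth_frac
    if profile.length > preset.long_genome_bp:
        return profile.breadth_bp >= preset.min_breadth_bp
    return profile.breadth_frac >= preset.min_breadth_frac


def truncated_mean_abundance(
    profile: CoverageProfile, q_low: float = 0.10, q_high: float = 0.90
) -> float:
    """Mean depth over positions whose depth lies within [P10, P90].

    Quantiles are taken over the per-position depth distribution of the
    whole genome, zeros included, with linear interpolation; retention
    bounds are inclusive. Discarding the tails suppresses abundance skew
    from hypervariable islands (low tail) and conserved regions recruiting
    reads from other populations (high tail). If truncation would discard
    every position the untruncated mean is returned with a warning.
    """
    d = profile.depth.astype(float)
    if d.size == 0:
        return 0.0
    lo, hi = np.quantile(d, [q_low, q_high])
    mask = (d >= lo) & (d <= hi)
    if not mask.any():
        warnings.warn(
            f"{profile.genome_id}/{profile.sample_id}: quantile truncation "
            "discarded every position; falling back to the untruncated mean"
        )
        return float(d.mean())
    return float(d[mask].mean())


def abundance_record(
    profile: CoverageProfile,
    preset: DetectionPreset,
    q_low: float = 0.10,
    q_high: float = 0.90,
) -> AbundanceRecord:
    """Detection decision plus truncated-mean abundance (0 when undetected)."""
    det = detect(profile, preset)
    raw = truncated_mean_abundance(profile, q_low, q_high) if det else 0.0
    return AbundanceRecord(profile.genome_id, profile.sample_id, raw, det)


def read_alignment_file(path: str) -> Iterator[pysam.AlignedSegment]:
    """Stream records from a SAM or BAM file (no index required)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        yield from fh.fetch(until_eof=True)


def reference_lengths(path: str) -> dict[str, int]:
    """Target name -> length from a SAM/BAM header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return dict(zip(fh.references, fh.lengths))
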