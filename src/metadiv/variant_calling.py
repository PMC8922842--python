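"""Pileups, SNP calling, codon context, within-codon linkage, downsampling.

The variant arm works per population genome. A sample is eligible for
microdiversity when the genome is >= 70% covered at >= 10x truncated mean
depth there. Base counts are piled up per position keeping only bases
with PHRED quality >= 20. SNPs are called in two scopes:

* global — per-position counts pooled across all samples; the pooled
  majority base is the consensus, and every other base reaching >= 1% of
  pooled coverage AND >= 4 supporting reads is a true alternate allele
  (both bounds inclusive);
* local — the global SNP positions restricted, per sample, to positions
  where that sample itself shows at least one quality-passing
  non-consensus base.

Genic SNPs get gene, codon index and codon position (strand-aware); a
warning is raised when 1st+2nd codon position SNPs outnumber 3rd
position ones, since synonymous 3rd-position changes should dominate.
The pooled consensus replaces the reference base at every SNP position
before any synonymous/non-synonymous logic runs.

SNPs sharing a codon are tested for linkage from the reads spanning the
codon: a 2x2 table (both alts / alt1 only / alt2 only / neither) feeds a
two-sided Fisher exact test and a phi coefficient; pairs with p < 0.05
are "linked" (phi > 0) or "independent" (phi < 0), anything else is
"ambiguous" and treated as independent downstream.

Finally SNP-bearing loci are downsampled to a uniform depth (default
10x) without replacement — whole codon strings at genic loci, so
within-codon linkage survives the subsampling; single bases elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact

from ._genetics import BASE_INDEX, BASES, locus_rng
from .codon_bias import GeneModel
from .preprocess import CoverageProfile, truncated_mean_abundance

_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_EQ, _OP_X = 0, 1, 2, 3, 4, 7, 8


# ---------------------------------------------------------------------------
# eligibility and pileup


def microdiversity_eligible(
    profile: CoverageProfile, min_breadth: float = 0.70, min_depth: float = 10.0
) -> bool:
    """Enough breadth and depth to call SNPs in this genome/sample pair."""
    return (
        profile.breadth_frac >= min_breadth
        and truncated_mean_abundance(profile) >= min_depth
    )


def pileup(
    alignments: Iterable, genome_length: int, min_base_q: int = 20
) -> np.ndarray:
    """Per-position base counts, shape (genome_length, 4) for A,C,G,T.

    Counts only bases with base quality >= ``min_base_q`` from aligned
    (M/=/X) segments; deletions and reference skips contribute nothing.
    """
    counts = np.zeros((genome_length, 4), dtype=np.int64)
    for aln in alignments:
        seq = aln.query_sequence
        quals = aln.query_qualities
        qpos = 0
        rpos = aln.reference_start
        for op, length in aln.cigartuples:
            if op in (_OP_M, _OP_EQ, _OP_X):
                for k in range(length):
                    if quals is None or quals[qpos + k] >= min_base_q:
                        b = BASE_INDEX.get(seq[qpos + k])
                        if b is not None:
                            counts[rpos + k, b] += 1
                qpos += length
                rpos += length
            elif op in (_OP_I, _OP_S):
                qpos += length
            elif op in (_OP_D, _OP_N):
                rpos += length
    return counts


# ---------------------------------------------------------------------------
# SNP calling


@dataclass
class SnpRecord:
    """A verified polymorphic site."""

    genome_id: str
    position: int  # 0-based
    consensus: str
    alts: dict[str, int]  # alt base -> pooled read count
    pooled_coverage: int
    genic: bool = False
    gene_id: str | None = None
    codon_index: int | None = None
    codon_position: int | None = None  # 1, 2 or 3
    strand: str | None = None


def call_snps_global(
    pooled_counts: np.ndarray,
    genome_id: str,
    min_freq: float = 0.01,
    min_reads: int = 4,
    restrict: set[int] | None = None,
) -> list[SnpRecord]:
    """Call SNPs from counts pooled across samples.

    The consensus is the pooled majority base (ties broken A<C<G<T);
    alternate alleles need pooled frequency >= ``min_freq`` and pooled
    support >= ``min_reads``, both inclusive. ``restrict`` optionally
    limits candidate positions (e.g. sites from an imported VCF).
    """
    snps = []
    covered = np.nonzero(pooled_counts.sum(axis=1) > 0)[0]
    for pos in covered:
        if restrict is not None and int(pos) not in restrict:
            continue
        row = pooled_counts[pos]
        cov = int(row.sum())
        cons_idx = int(np.argmax(row))  # first max => lexicographic tie-break
        alts = {
            BASES[b]: int(row[b])
            for b in range(4)
            if b != cons_idx
            and row[b] >= min_reads
            and row[b] / cov >= min_freq
        }
        if alts:
            snps.append(
                SnpRecord(genome_id, int(pos), BASES[cons_idx], alts, cov)
            )
    return snps


def call_snps_local(
    global_snps: Sequence[SnpRecord], sample_counts: np.ndarray
) -> list[SnpRecord]:
    """Restrict global SNPs to positions with sample-specific variant evidence.

    A global SNP is locally present when the sample has at least one
    quality-passing non-consensus base at the position; positions only
    variable in other samples are dropped.
    """
    local = []
    for snp in global_snps:
        row = sample_counts[snp.position]
        non_cons = int(row.sum()) - int(row[BASE_INDEX[snp.consensus]])
        if non_cons >= 1:
            local.append(snp)
    return local


def assign_codon_context(
    snps: Sequence[SnpRecord], genes: Sequence[GeneModel]
) -> bool:
    """Annotate SNPs with gene/codon fields in place.

    Returns True (and warns) when 1st+2nd codon position SNPs outnumber
    3rd position ones — an excess of potentially non-synonymous changes
    that usually indicates a frame or annotation problem.
    """
    by_genome: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    pos12 = pos3 = 0
    for snp in snps:
        for gene in by_genome.get(snp.genome_id, ()):
            coding_len = 3 * gene.n_codons  # trimmed terminal bases stay non-genic
            if gene.strand == "+":
                if not gene.start <= snp.position < gene.start + coding_len:
                    continue
                offset = snp.position - gene.start
            else:
                if not gene.end - coding_len <= snp.position < gene.end:
                    continue
                offset = (gene.end - 1) - snp.position
            snp.genic = True
            snp.gene_id = gene.gene_id
            snp.codon_index = offset // 3
            snp.codon_position = offset % 3 + 1
            snp.strand = gene.strand
            break
        if snp.genic:
            if snp.codon_position == 3:
                pos3 += 1
            else:
                pos12 += 1
    skew = pos12 > pos3
    if skew:
        warnings.warn(
            f"{pos12} SNPs at codon positions 1-2 exceed {pos3} at position 3; "
            "check gene frames/annotation"
        )
    return skew


def consensus_update(reference: str, snps: Sequence[SnpRecord]) -> str:
    """Replace the reference base with the pooled consensus at SNP positions."""
    seq = list(reference)
    for snp in snps:
        seq[snp.position] = snp.consensus
    return "".join(seq)


# ---------------------------------------------------------------------------
# codon observations and linkage


def codon_genome_positions(gene: GeneModel, codon_index: int) -> tuple[int, int, int]:
    """Ascending genome coordinates of one codon's three bases."""
    if not 0 <= codon_index < gene.n_codons:
        raise IndexError(f"codon {codon_index} outside gene {gene.gene_id}")
    if gene.strand == "+":
        p0 = gene.start + 3 * codon_index
    else:
        p0 = gene.end - 3 * (codon_index + 1)
    return (p0, p0 + 1, p0 + 2)


def extract_codon_observations(
    alignments: Iterable,
    positions: tuple[int, int, int],
    min_base_q: int = 20,
) -> list[str]:
    """Genome-orientation 3-mers from reads fully spanning one codon.

    A read contributes only when all three codon bases are aligned with
    M/=/X ops at quality >= ``min_base_q`` and the read has no indel
    inside the codon.
    """
    p0, _, p2 = positions
    obs = []
    for aln in alignments:
        if aln.reference_start > p0 or aln.reference_end is None or aln.reference_end <= p2:
            continue
        seq = aln.query_sequence
        quals = aln.query_qualities
        bases: dict[int, str] = {}
        broken = False
        qpos = 0
        rpos = aln.reference_start
        for op, length in aln.cigartuples:
            if op in (_OP_M, _OP_EQ, _OP_X):
                lo = max(rpos, p0)
                hi = min(rpos + length, p2 + 1)
                for r in range(lo, hi):
                    k = qpos + (r - rpos)
                    if quals is not None and quals[k] < min_base_q:
                        broken = True
                        break
                    bases[r] = seq[k]
                qpos += length
                rpos += length
            elif op in (_OP_I, _OP_S):
                if op == _OP_I and p0 < rpos <= p2:  # insertion inside codon
                    broken = True
                qpos += length
            elif op in (_OP_D, _OP_N):
                if rpos < p2 + 1 and rpos + length > p0:  # deletion touches codon
                    broken = True
                rpos += length
            if broken:
                break
        if broken or len(bases) != 3:
            continue
        tri = "".join(bases[p] for p in positions)
        if all(b in BASE_INDEX for b in tri):
            obs.append(tri)
    return obs


@dataclass(frozen=True)
class VariantUnit:
    """One alternate allele at one genome position (genome orientation)."""

    position: int
    alt: str


@dataclass
class LinkageResult:
    unit1: VariantUnit
    unit2: VariantUnit
    table: tuple[int, int, int, int]  # both, only1, only2, neither
    fisher_p: float
    phi: float
    classification: str  # linked | independent | ambiguous

    @property
    def effective_independent(self) -> bool:
        """Ambiguous pairs are treated as independent downstream."""
        return self.classification != "linked"


def phi_coefficient(a: int, b: int, c: int, d: int) -> float:
    """phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); NaN on a zero margin."""
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return (a * d - b * c) / np.sqrt(denom)


def linkage_test(
    observations: Sequence[str],
    positions: tuple[int, int, int],
    unit1: VariantUnit,
    unit2: VariantUnit,
    alpha: float = 0.05,
) -> LinkageResult:
    """Fisher/phi classification of two alternate alleles in one codon.

    ``observations`` are genome-orientation codon 3-mers from spanning
    reads; a read carries a unit when its base at the unit's position
    equals the alt allele.
    """
    offsets = {p: i for i, p in enumerate(positions)}
    i1, i2 = offsets[unit1.position], offsets[unit2.position]
    a = b = c = d = 0
    for tri in observations:
        has1 = tri[i1] == unit1.alt
        has2 = tri[i2] == unit2.alt
        if has1 and has2:
            a += 1
        elif has1:
            b += 1
        elif has2:
            c += 1
        else:
            d += 1
    phi = phi_coefficient(a, b, c, d)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    # p can land exactly on alpha up to float error (e.g. table (2,2,0,12)
    # has p = 1/20); p == alpha is not significant
    at_alpha = math.isclose(p, alpha, rel_tol=1e-9, abs_tol=1e-12)
    if np.isnan(phi) or p >= alpha or at_alpha or phi == 0:
        cls = "ambiguous"
    elif phi > 0:
        cls = "linked"
    else:
        cls = "independent"
    return LinkageResult(unit1, unit2, (a, b, c, d), float(p), float(phi), cls)


def codon_variant_units(snps_in_codon: Sequence[SnpRecord]) -> list[VariantUnit]:
    """One unit per (position, alt allele); multi-allelic SNPs yield several."""
    units = []
    for snp in snps_in_codon:
        for alt in sorted(snp.alts):
            units.append(VariantUnit(snp.position, alt))
    return units


def test_codon_linkage(
    snps_in_codon: Sequence[SnpRecord],
    observations: Sequence[str],
    positions: tuple[int, int, int],
    alpha: float = 0.05,
) -> list[LinkageResult]:
    """All pairwise linkage tests between alt alleles at distinct positions."""
    units = codon_variant_units(snps_in_codon)
    results = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            u1, u2 = units[i], units[j]
            if u1.position == u2.position:
                continue  # same-site alts are exclusive by construction
            if not observations:
                continue
            results.append(linkage_test(observations, positions, u1, u2, alpha))
    return results


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values for users who want FDR control across codon tests.

    The default classification applies no multiple-testing correction;
    re-classify with ``adjusted < alpha`` to screen at a target FDR.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# downsampling


def downsample_base_counts(
    row: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw min(target, coverage) bases without replacement from one site."""
    cov = int(row.sum())
    if cov <= target:
        return row.copy()
    return rng.multivariate_hypergeometric(row.astype(np.int64), target)


def downsample_codon_observations(
    observations: Sequence[str], target: int, rng: np.random.Generator
) -> list[str]:
    """Sample min(target, n) whole codon strings without replacement."""
    n = len(observations)
    if n <= target:
        return list(observations)
    idx = rng.choice(n, size=target, replace=False)
    return [observations[i] for i in sorted(idx)]


def downsample_sample(
    sample_counts: np.ndarray,
    snps: Sequence[SnpRecord],
    codon_obs: dict[tuple[str, int], list[str]],
    codon_positions: dict[tuple[str, int], tuple[int, int, int]],
    genome_id: str,
    seed: int,
    target: int = 10,
) -> dict[int, np.ndarray]:
    """Downsampled base counts at every SNP position for one sample.

    Genic loci are resampled as whole codon strings (linkage preserved by
    construction), intergenic loci as bases; loci with no passing
    spanning read fall back to base-level sampling. RNG substreams are
    keyed by (seed, genome, position) so results do not depend on
    iteration order.
    """
    out: dict[int, np.ndarray] = {}
    genic_by_codon: dict[tuple[str, int], list[SnpRecord]] = {}
    for snp in snps:
        if snp.genic and (snp.gene_id, snp.codon_index) in codon_positions:
            genic_by_codon.setdefault((snp.gene_id, snp.codon_index), []).append(snp)
        else:
            rng = locus_rng(seed, genome_id, snp.position)
            out[snp.position] = downsample_base_counts(
                sample_counts[snp.position], target, rng
            )
    for key, codon_snps in genic_by_codon.items():
        positions = codon_positions[key]
        obs = codon_obs.get(key, [])
        if obs:
            rng = locus_rng(seed, genome_id, positions[0])
            chosen = downsample_codon_observations(obs, target, rng)
            for snp in codon_snps:
                offset = positions.index(snp.position)
                row = np.zeros(4, dtype=np.int64)
                for tri in chosen:
                    row[BASE_INDEX[tri[offset]]] += 1
                out[snp.position] = row
        else:
            for snp in codon_snps:
                rng = locus_rng(seed, genome_id, snp.position)
                out[snp.position] = downsample_base_counts(
                    sample_counts[snp.position], target, rng
                )
    return out


# ---------------------------------------------------------------------------
# optional VCF site import


def vcf_candidate_positions(path: str) -> dict[str, set[int]]:
    """Candidate SNV positions per genome from a VCF (v4) site file.

    Only CHROM/POS of SNV records are used; this lets an externally
    produced variant callset gate which positions are considered during
    global SNP calling.
    """
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                continue
            chrom, pos, _, ref, alts = fields[:5]
            if len(ref) != 1:
                continue
            if all(len(a) == 1 and a in "ACGT" for a in alts.split(",")):
                sites.setdefault(chrom, set()).add(int(pos) - 1)
    return sites
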