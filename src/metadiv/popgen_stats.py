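"""Nucleotide diversity, F_ST, linkage-aware pN/pS, and Tajima's D.

All statistics run on downsampled SNP-site base counts. Because a sample
only needs 70% genome breadth to enter the variant arm, some SNP
positions of a population are typically not covered in a given sample;
the estimators therefore divide by an *effective length*
``|G| - (N - n)``, the gene/genome length minus the SNP positions the
sample does not cover (N = total SNP positions, n = covered ones).

theta (expected diversity)     theta = N / (|G| - (N - n))
pi (observed diversity)        pi = (1 / (|G| - (N - n)))
                                    * sum_i sum_{B1 != B2} (x_{i,B1}/c_i) (x_{i,B2}/(c_i - 1))

The inner sum at a site equals the probability that two reads drawn
without replacement disagree — the unbiased per-site heterozygosity
(c^2 - sum_B x_B^2) / (c (c - 1)).

F_ST between two samples keeps the *total* genome length as the common
denominator (SNP coverage differs between samples, so effective lengths
would not be comparable): pi_x and pi_y are within-sample sums divided
by |G|, pi_xy crosses read draws between samples at sites covered in
both, and F_ST = 1 - ((pi_x + pi_y)/2) / pi_xy.

pN/pS follows the expected/observed site-counting convention — every
consensus codon contributes its 9 single-nucleotide mutants to the
expected tallies with equal weight — but the observed variant codons
honor within-codon SNP linkage: a linked SNP pair becomes one joint
double-substitution codon variant (which can flip the amino-acid
outcome entirely) while unlinked/ambiguous SNPs stay separate
single-substitution variants. Both versions are reported.

Tajima's D uses the 1989 constants with S = the gene's SNP-position
count and n = the ceiling of the gene's mean read depth standing in for
the number of sampled sequences; the per-site pi is rescaled by the
effective gene length so the numerator compares like with like.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._genetics import complement, translate_codon
from .variant_calling import LinkageResult, SnpRecord, VariantUnit

__all__ = [
    "effective_length",
    "theta",
    "site_pi_term",
    "pi",
    "fst",
    "FstEntry",
    "expected_site_counts",
    "pn_ps",
    "PnPsResult",
    "tajimas_d",
    "sample_average_pi",
]


def effective_length(length: int, n_total: int, n_covered: int) -> int:
    """|G| - (N - n): length minus SNP positions not covered in the sample."""
    if not 0 <= n_covered <= n_total <= length:
        raise ValueError(f"need 0 <= n ({n_covered}) <= N ({n_total}) <= |G| ({length})")
    eff = length - (n_total - n_covered)
    if eff <= 0:
        raise ValueError("effective length must be positive")
    return eff


def theta(length: int, n_total: int, n_covered: int) -> float:
    """Expected nucleotide diversity: SNP count over effective length."""
    if n_total == 0:
        return 0.0
    return n_total / effective_length(length, n_total, n_covered)


def site_pi_term(row: np.ndarray) -> float:
    """Unbiased heterozygosity of one site: (c^2 - sum x^2) / (c (c-1)).

    Sites with coverage < 2 cannot contribute (two reads are needed for
    a pairwise comparison) and return 0, with a warning at c == 1.
    """
    c = int(np.sum(row))
    if c < 2:
        if c == 1:
            warnings.warn("SNP site with coverage 1 skipped (needs >= 2 reads)")
        return 0.0
    sq = float(np.dot(row, row))
    return (c * c - sq) / (c * (c - 1))


def pi(
    site_counts: Iterable[np.ndarray], length: int, n_total: int, n_covered: int
) -> float:
    """Observed nucleotide diversity over a gene or genome."""
    if n_total == 0:
        return 0.0
    total = sum(site_pi_term(np.asarray(row)) for row in site_counts)
    return total / effective_length(length, n_total, n_covered)


@dataclass
class FstEntry:
    genome_id: str
    sample_x: str
    sample_y: str
    pi_x: float
    pi_y: float
    pi_xy: float
    fst: float  # NaN when pi_xy == 0


def _cross_site_term(row_x: np.ndarray, row_y: np.ndarray) -> float:
    """P(two reads, one from each sample, disagree) at one site."""
    cx = float(np.sum(row_x))
    cy = float(np.sum(row_y))
    if cx == 0 or cy == 0:
        return 0.0
    agree = float(np.dot(row_x, row_y))
    return 1.0 - agree / (cx * cy)


def fst(
    genome_id: str,
    sample_x: str,
    sample_y: str,
    counts_x: Mapping[int, np.ndarray],
    counts_y: Mapping[int, np.ndarray],
    genome_length: int,
) -> FstEntry:
    """Fixation index between two samples over one genome.

    ``counts_x``/``counts_y`` map SNP position -> downsampled base-count
    rows for each sample. Within-sample diversities use the whole-genome
    denominator; the between term runs over SNP sites covered in both
    samples. F_ST is NaN when there is no between-sample diversity.
    """
    covered_x = {p for p, r in counts_x.items() if np.sum(r) > 0}
    covered_y = {p for p, r in counts_y.items() if np.sum(r) > 0}
    both = covered_x & covered_y
    pi_x = sum(site_pi_term(counts_x[p]) for p in covered_x) / genome_length
    pi_y = sum(site_pi_term(counts_y[p]) for p in covered_y) / genome_length
    pi_xy = sum(_cross_site_term(counts_x[p], counts_y[p]) for p in both) / genome_length
    if pi_xy == 0:
        value = math.nan
    else:
        value = 1.0 - ((pi_x + pi_y) / 2.0) / pi_xy
    return FstEntry(genome_id, sample_x, sample_y, pi_x, pi_y, pi_xy, value)


# ---------------------------------------------------------------------------
# pN/pS


def _is_nonsynonymous(ref_codon: str, mut_codon: str) -> bool:
    """Amino-acid change (including to/from stop) counts as non-synonymous."""
    return translate_codon(ref_codon) != translate_codon(mut_codon)


def expected_site_counts(cds: str) -> tuple[float, float]:
    """(N_exp, S_exp): non-synonymous vs synonymous single-nt mutants.

    Every codon of the coding sequence contributes its 9 single-nucleotide
    mutants with equal weight; codons with ambiguous bases are skipped.
    Only the N_exp:S_exp ratio matters downstream, so the raw mutant
    tallies are returned unscaled.
    """
    n_exp = s_exp = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if translate_codon(codon) == "X":
            continue
        for j in range(3):
            for b in "ACGT":
                if b == codon[j]:
                    continue
                mut = codon[:j] + b + codon[j + 1 :]
                if _is_nonsynonymous(codon, mut):
                    n_exp += 1
                else:
                    s_exp += 1
    return float(n_exp), float(s_exp)


@dataclass
class PnPsResult:
    gene_id: str
    n_exp: float
    s_exp: float
    n_obs_linked: int
    s_obs_linked: int
    n_obs_unlinked: int
    s_obs_unlinked: int
    pn_ps_linked: float  # NaN when no synonymous observation
    pn_ps_unlinked: float
    positive_selection_candidate: bool  # N_obs > 0 while S_obs == 0 (linked)


def _cds_unit(snp: SnpRecord, alt: str) -> tuple[int, int, str]:
    """(codon_index, offset in codon, alt base in CDS orientation)."""
    offset = snp.codon_position - 1
    cds_alt = complement(alt) if snp.strand == "-" else alt
    return (snp.codon_index, offset, cds_alt)


def _classify_variants(
    cds: str, variant_groups: Iterable[Sequence[tuple[int, int, str]]]
) -> tuple[int, int]:
    """Count (non-synonymous, synonymous) variant codons.

    Each group is a set of substitutions applied jointly to one codon to
    form a single variant codon; groups spanning several codons are
    split per codon.
    """
    n_obs = s_obs = 0
    for group in variant_groups:
        by_codon: dict[int, list[tuple[int, str]]] = {}
        for codon_index, offset, alt in group:
            by_codon.setdefault(codon_index, []).append((offset, alt))
        for codon_index, subs in by_codon.items():
            ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
            if len(ref_codon) < 3 or translate_codon(ref_codon) == "X":
                continue
            mut = list(ref_codon)
            for offset, alt in subs:
                mut[offset] = alt
            if _is_nonsynonymous(ref_codon, "".join(mut)):
                n_obs += 1
            else:
                s_obs += 1
    return n_obs, s_obs


def pn_ps(
    gene_id: str,
    consensus_cds: str,
    snps_in_gene: Sequence[SnpRecord],
    linkage_results: Sequence[LinkageResult] = (),
) -> PnPsResult:
    """Linkage-aware and linkage-blind pN/pS for one gene.

    Without linkage every alternate allele is a separate
    single-substitution codon variant. With linkage, alt alleles whose
    pairwise tests came back "linked" are merged (transitively) into one
    joint variant codon — two linked SNPs in a codon produce the double
    mutant, not two singles — while ambiguous pairs stay independent.
    """
    unit_to_cds: dict[VariantUnit, tuple[int, int, str]] = {}
    for snp in snps_in_gene:
        if snp.codon_index is None:
            continue
        for alt in sorted(snp.alts):
            unit_to_cds[VariantUnit(snp.position, alt)] = _cds_unit(snp, alt)

    singles = [[u] for u in unit_to_cds.values()]
    n_unl, s_unl = _classify_variants(consensus_cds, singles)

    # union-find over linked pairs
    parent: dict[VariantUnit, VariantUnit] = {u: u for u in unit_to_cds}

    def find(u: VariantUnit) -> VariantUnit:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for res in linkage_results:
        if res.classification == "linked" and res.unit1 in parent and res.unit2 in parent:
            parent[find(res.unit1)] = find(res.unit2)

    components: dict[VariantUnit, list[tuple[int, int, str]]] = {}
    for u, cds_unit in unit_to_cds.items():
        components.setdefault(find(u), []).append(cds_unit)
    n_lnk, s_lnk = _classify_variants(consensus_cds, list(components.values()))

    n_exp, s_exp = expected_site_counts(consensus_cds)

    def ratio(n_obs: int, s_obs: int) -> float:
        if s_obs == 0 or s_exp == 0 or n_exp == 0:
            return math.nan
        return (n_obs / n_exp) / (s_obs / s_exp)

    return PnPsResult(
        gene_id=gene_id,
        n_exp=n_exp,
        s_exp=s_exp,
        n_obs_linked=n_lnk,
        s_obs_linked=s_lnk,
        n_obs_unlinked=n_unl,
        s_obs_unlinked=s_unl,
        pn_ps_linked=ratio(n_lnk, s_lnk),
        pn_ps_unlinked=ratio(n_unl, s_unl),
        positive_selection_candidate=(s_lnk == 0 and n_lnk > 0),
    )


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(pi_total: float, n_segregating: int, n_seq: int) -> float:
    """Tajima's 1989 D from total pairwise diversity and segregating sites.

    ``pi_total`` is the per-site pi multiplied by the effective gene
    length; ``n_seq`` is the ceiling mean read depth over the gene.
    Undefined (NaN) for fewer than 4 sequences or no segregating sites.
    """
    S = int(n_segregating)
    n = int(n_seq)
    if S < 1 or n < 4:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# subsample-averaged pi


def sample_average_pi(
    values: Sequence[float], k: int, reps: int, seed: int
) -> float:
    """Mean over ``reps`` draws of the mean pi of ``k`` populations.

    Populations are sampled without replacement within each repetition;
    requires at least ``k`` eligible populations.
    """
    values = np.asarray(values, dtype=float)
    if values.size < k:
        raise ValueError(f"need at least k={k} populations, have {values.size}")
    rng = np.random.default_rng(seed)
    means = [float(rng.choice(values, size=k, replace=False).mean()) for _ in range(reps)]
    return float(np.mean(means))
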