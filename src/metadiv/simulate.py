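"""Deterministic synthetic metagenomic communities with known truth.

Generates population genomes, planted protein-coding genes, and
per-sample reads emitted as valid coordinate-sorted SAM (correct CIGAR,
NM and MD against the reference) with planted per-genome depths, SNP
allele frequencies and within-codon linkage. Reads are written at their
true coordinates, so downstream analyses exercise the pipeline's own
logic rather than a mapper's. Truth tables record the planted depths,
allele frequencies and expected linkage classes.

Linkage is planted through groups: members of a normal group co-occur on
the same template molecule (expected class "linked"); members of an
*exclusive* group never co-occur (at most one alt per molecule,
expected class "independent").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._genetics import BASES, revcomp
from .codon_bias import GeneModel

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)


@dataclass
class SnpPlan:
    """One planted alternate allele at a genome position (0-based).

    ``freq`` is either a single target frequency for every sample, or a
    per-sample mapping (values may then be 0 or 1, e.g. to plant a fixed
    between-sample difference for F_ST fixtures).
    """

    position: int
    alt: str
    freq: float | dict[str, float]
    link_group: str | None = None
    exclusive: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.freq, dict):
            if not all(0.0 <= f <= 1.0 for f in self.freq.values()):
                raise ValueError("per-sample SNP frequencies must be in [0,1]")
        elif not 0.0 < self.freq < 1.0:
            raise ValueError(f"SNP frequency must be in (0,1), got {self.freq}")
        if self.alt not in BASES:
            raise ValueError(f"alt allele must be one of {BASES}")

    def freq_in(self, sample: str) -> float:
        return self.freq.get(sample, 0.0) if isinstance(self.freq, dict) else self.freq


@dataclass
class PopulationSpec:
    genome_id: str
    length: int
    depth: dict[str, float]  # sample -> target (plateau) depth
    gc: float = 0.5
    n_genes: int = 0
    gene_len: int = 300  # incl. start and stop codon; multiple of 3
    snps: list[SnpPlan] = field(default_factory=list)
    genome_seq: str | None = None  # pre-built sequence (overrides length/gc)
    genes: list[GeneModel] | None = None


@dataclass
class CommunitySpec:
    populations: list[PopulationSpec]
    read_len: int = 150
    error_rate: float = 0.0
    base_quality: int = 30
    seed: int = 0
    dirty_errors: bool = False  # allow errors near planted SNPs


@dataclass
class SimRead:
    name: str
    genome_id: str
    start: int
    seq: str


@dataclass
class Community:
    spec: CommunitySpec
    genomes: dict[str, str]
    genes: list[GeneModel]
    reads: dict[str, list[SimRead]]  # sample -> reads (coordinate-sorted)
    library_sizes: dict[str, int]
    truth: dict[str, pd.DataFrame]


def make_genome(length: int, gc: float, seed: int) -> str:
    """I.i.d. random genome at the requested GC fraction; seed-reproducible."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def plant_genes(
    genome: str, n: int, gene_len: int, seed: int, genome_id: str = "genome"
) -> tuple[list[GeneModel], str]:
    """Overwrite ``n`` disjoint intervals with frame-clean ORFs.

    Each gene is ATG + random non-stop codons + TAA, alternating strand;
    on the '-' strand the reverse complement is inserted so the coding
    sequence reads correctly 5'->3'. Raises when the genome cannot hold
    the requested genes without overlap.
    """
    if gene_len % 3:
        raise ValueError("gene_len must be a multiple of 3")
    L = len(genome)
    gap = 30
    if n * (gene_len + gap) > L:
        raise ValueError(f"cannot place {n} genes of {gene_len} bp in {L} bp")
    rng = np.random.default_rng(seed)
    slot = L // n
    seq = list(genome)
    genes = []
    for i in range(n):
        start = i * slot + int(rng.integers(0, max(1, slot - gene_len - gap)))
        end = start + gene_len
        n_inner = gene_len // 3 - 2
        inner = "".join(rng.choice(_NONSTOP_CODONS, size=n_inner))
        cds = "ATG" + inner + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        insert = cds if strand == "+" else revcomp(cds)
        seq[start:end] = insert
        genes.append(GeneModel(f"{genome_id}_g{i + 1}", genome_id, start, end, strand, cds))
    return genes, "".join(seq)


def _md_and_nm(ref: str, read: str) -> tuple[str, int]:
    """MD tag and NM edit distance for an ungapped alignment."""
    md = []
    run = 0
    nm = 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def _simulate_population_sample(
    pspec: PopulationSpec,
    genome: str,
    sample: str,
    depth: float,
    read_len: int,
    error_rate: float,
    dirty: bool,
    rng: np.random.Generator,
) -> list[SimRead]:
    L = len(genome)
    if read_len > L:
        raise ValueError(f"read length {read_len} exceeds genome {pspec.genome_id} ({L} bp)")
    n_positions = L - read_len + 1
    n_reads = int(round(depth * n_positions / read_len))
    starts = np.sort(rng.integers(0, n_positions, size=n_reads))

    singles = [s for s in pspec.snps if s.link_group is None]
    groups: dict[str, list[SnpPlan]] = {}
    for s in pspec.snps:
        if s.link_group is not None:
            groups.setdefault(s.link_group, []).append(s)
    protected = set()
    if not dirty:
        for s in pspec.snps:
            protected.update(range(s.position - 2, s.position + 3))

    reads = []
    for i, start in enumerate(starts):
        end = start + read_len
        seq = list(genome[start:end])

        for s in singles:
            if start <= s.position < end and rng.random() < s.freq_in(sample):
                seq[s.position - start] = s.alt
        for members in groups.values():
            covered = [m for m in members if start <= m.position < end]
            if not covered:
                continue
            if members[0].exclusive:
                u = rng.random()
                acc = 0.0
                for m in members:
                    acc += m.freq_in(sample)
                    if u < acc:
                        if start <= m.position < end:
                            seq[m.position - start] = m.alt
                        break
            else:
                if rng.random() < members[0].freq_in(sample):
                    for m in covered:
                        seq[m.position - start] = m.alt

        if error_rate > 0:
            errs = np.nonzero(rng.random(read_len) < error_rate)[0]
            for k in errs:
                if (start + k) in protected:
                    continue
                cur = seq[k]
                seq[k] = rng.choice([b for b in BASES if b != cur])

        reads.append(
            SimRead(f"{sample}.{pspec.genome_id}.{i}", pspec.genome_id, int(start), "".join(seq))
        )
    return reads


def build_community(spec: CommunitySpec) -> Community:
    """Materialize genomes, genes and per-sample reads from a spec."""
    root = np.random.SeedSequence(spec.seed)
    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    snp_rows = []
    link_rows = []

    for idx, pspec in enumerate(spec.populations):
        gseed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        if pspec.genome_seq is not None:
            genome = pspec.genome_seq
            pgenes = list(pspec.genes or [])
        else:
            genome = make_genome(pspec.length, pspec.gc, gseed)
            if pspec.n_genes:
                pgenes, genome = plant_genes(
                    genome, pspec.n_genes, pspec.gene_len, gseed + 1, pspec.genome_id
                )
            else:
                pgenes = []
        genomes[pspec.genome_id] = genome
        genes.extend(pgenes)

        for s in pspec.snps:
            if not 0 <= s.position < len(genome):
                raise ValueError(
                    f"SNP at {s.position} outside genome {pspec.genome_id} "
                    f"(length {len(genome)})"
                )
            ref = genome[s.position]
            if s.alt == ref:
                raise ValueError(
                    f"planted alt {s.alt} equals reference base at "
                    f"{pspec.genome_id}:{s.position}"
                )
            snp_rows.append(
                dict(
                    genome=pspec.genome_id, position=s.position, ref=ref,
                    alt=s.alt, freq=s.freq, link_group=s.link_group or "",
                    exclusive=s.exclusive,
                )
            )
        bygrp: dict[str, list[SnpPlan]] = {}
        for s in pspec.snps:
            if s.link_group:
                bygrp.setdefault(s.link_group, []).append(s)
        for gid, members in bygrp.items():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    link_rows.append(
                        dict(
                            genome=pspec.genome_id,
                            pos1=members[i].position, alt1=members[i].alt,
                            pos2=members[j].position, alt2=members[j].alt,
                            expected=("independent" if members[i].exclusive else "linked"),
                        )
                    )

    samples = sorted({s for p in spec.populations for s in p.depth})
    reads: dict[str, list[SimRead]] = {s: [] for s in samples}
    abundance_rows = []
    for pspec in spec.populations:
        for sample in samples:
            depth = pspec.depth.get(sample, 0.0)
            abundance_rows.append(
                dict(genome=pspec.genome_id, sample=sample, depth=depth)
            )
            if depth <= 0:
                continue
            rng = np.random.default_rng(
                [spec.seed & 0x7FFFFFFF, hash_str(pspec.genome_id), hash_str(sample)]
            )
            reads[sample].extend(
                _simulate_population_sample(
                    pspec, genomes[pspec.genome_id], sample, depth,
                    spec.read_len, spec.error_rate, spec.dirty_errors, rng,
                )
            )
    order = {g: i for i, g in enumerate(genomes)}
    for sample in samples:
        reads[sample].sort(key=lambda r: (order[r.genome_id], r.start))

    truth = {
        "abundance": pd.DataFrame(abundance_rows),
        "snps": pd.DataFrame(
            snp_rows,
            columns=["genome", "position", "ref", "alt", "freq", "link_group", "exclusive"],
        ),
        "linkage": pd.DataFrame(
            link_rows, columns=["genome", "pos1", "alt1", "pos2", "alt2", "expected"]
        ),
    }
    library_sizes = {s: len(reads[s]) for s in samples}
    return Community(spec, genomes, genes, reads, library_sizes, truth)


def hash_str(s: str) -> int:
    """Stable small hash for RNG keying (crc32, avoids PYTHONHASHSEED)."""
    import zlib

    return zlib.crc32(s.encode())


def sam_header(genomes: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": g, "LN": len(seq)} for g, seq in genomes.items()],
        }
    )


def write_sam(
    community: Community, sample: str, path: str | Path, base_quality: int | None = None
) -> None:
    """Write one sample's reads as coordinate-sorted SAM with NM/MD tags."""
    bq = base_quality if base_quality is not None else community.spec.base_quality
    header = sam_header(community.genomes)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in community.reads[sample]:
            ref = community.genomes[read.genome_id]
            md, nm = _md_and_nm(ref[read.start : read.start + len(read.seq)], read.seq)
            a = pysam.AlignedSegment(header)
            a.query_name = read.name
            a.query_sequence = read.seq
            a.flag = 0
            a.reference_id = list(community.genomes).index(read.genome_id)
            a.reference_start = read.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.seq)}M"
            a.query_qualities = pysam.qualitystring_to_array(chr(bq + 33) * len(read.seq))
            a.set_tag("NM", nm)
            a.set_tag("MD", md)
            out.write(a)


def write_community(community: Community, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, per-sample SAM, library sizes and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genomes.fasta"
    with open(fasta, "w") as fh:
        for gid, seq in community.genomes.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["fasta"] = fasta

    gff = outdir / "genes.gff"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in community.genes:
            fh.write(
                f"{g.genome_id}\tsim\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}\n"
            )
    paths["gff"] = gff

    for sample in community.reads:
        sam = outdir / f"{sample}.sam"
        write_sam(community, sample, sam)
        paths[f"sam:{sample}"] = sam

    libs = outdir / "library_sizes.tsv"
    pd.Series(community.library_sizes, name="reads").rename_axis("sample").to_csv(
        libs, sep="\t"
    )
    paths["library_sizes"] = libs

    for name, df in community.truth.items():
        p = outdir / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth:{name}"] = p
    return paths
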