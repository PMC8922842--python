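"""Gene models, per-gene codon-usage bias, and outlier-gene detection.

Genes with codon usage far from their genome's average often mark recent
horizontal transfer, distinct temporal regulation, or high expression.
For every gene we compute, per amino acid present in the gene, the
fraction each synonymous codon contributes to that amino acid's codon
count (a 61-dimensional within-amino-acid bias vector). The genome
average is the per-dimension mean over the genes observing that amino
acid, distances are Euclidean over the dimensions whose amino acid the
gene actually uses, and genes beyond the Tukey upper fence
(Q3 + 1.5 IQR of the genome's distances) are flagged as outliers.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._genetics import CODON_TO_AA, SENSE_CODONS, revcomp, translate_codon

_CODON_DIM = {c: i for i, c in enumerate(SENSE_CODONS)}
_AA_DIMS: dict[str, list[int]] = {}
for _c, _i in _CODON_DIM.items():
    _AA_DIMS.setdefault(CODON_TO_AA[_c], []).append(_i)


@dataclass
class GeneModel:
    """A protein-coding gene on one genome.

    ``start``/``end`` are 0-based half-open genome coordinates; ``cds`` is
    the coding sequence read 5'->3' (reverse-complemented for '-' strand
    genes) and trimmed to a whole number of codons.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    cds: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        overhang = len(self.cds) % 3
        if overhang:
            warnings.warn(
                f"gene {self.gene_id}: length {len(self.cds)} not a multiple "
                f"of 3; trimming {overhang} nt incomplete terminal codon"
            )
            self.cds = self.cds[: len(self.cds) - overhang]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]

    @classmethod
    def from_interval(
        cls, gene_id: str, genome_id: str, genome_seq: str, start: int, end: int, strand: str
    ) -> "GeneModel":
        seq = genome_seq[start:end].upper()
        if strand == "-":
            seq = revcomp(seq)
        return cls(gene_id, genome_id, start, end, strand, seq)


@dataclass
class CodonBiasVector:
    gene_id: str
    values: np.ndarray  # 61-dim within-amino-acid codon fractions
    observed_aas: frozenset[str]
    skipped_codons: int = 0


@dataclass
class OutlierCall:
    gene_id: str
    genome_id: str
    distance: float
    threshold: float
    is_outlier: bool


# ---------------------------------------------------------------------------
# gene loading


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_genes_gff(gff_path: str | Path, genome_seqs: dict[str, str]) -> list[GeneModel]:
    """Parse CDS features from a GFF3 file against loaded genome sequences."""
    genes: list[GeneModel] = []
    counter = 0
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] not in ("CDS", "gene"):
            continue
        genome_id, ftype = fields[0], fields[2]
        if ftype == "gene":  # prefer CDS rows when both are present
            continue
        start = int(fields[3]) - 1  # GFF is 1-based inclusive
        end = int(fields[4])
        strand = fields[6]
        attrs = _parse_gff_attributes(fields[8])
        counter += 1
        gene_id = attrs.get("ID", f"{genome_id}_gene{counter}")
        if genome_id not in genome_seqs:
            raise KeyError(f"GFF references unknown genome {genome_id!r}")
        genes.append(
            GeneModel.from_interval(gene_id, genome_id, genome_seqs[genome_id], start, end, strand)
        )
    return genes


def load_genes_ffn(ffn_path: str | Path) -> list[GeneModel]:
    """Parse a prodigal-style gene FASTA with ``# start # end # strand`` headers.

    Headers look like ``>genome_1_3 # 301 # 900 # 1 # ...`` with 1-based
    inclusive coordinates and strand 1/-1; the genome id is the gene id
    with its final ``_<n>`` index stripped.
    """
    genes = []
    for rec in SeqIO.parse(str(ffn_path), "fasta"):
        parts = rec.description.split("#")
        if len(parts) < 4:
            raise ValueError(f"cannot parse coordinates from header {rec.description!r}")
        start = int(parts[1]) - 1
        end = int(parts[2])
        strand = "+" if int(parts[3]) >= 0 else "-"
        gene_id = rec.id
        genome_id = gene_id.rsplit("_", 1)[0]
        # FFN records are already strand-corrected 5'->3' coding sequences
        cds = str(rec.seq).upper()
        genes.append(GeneModel(gene_id, genome_id, start, end, strand, cds))
    return genes


def call_genes_prodigal(fasta_path: str | Path) -> list[GeneModel]:
    """Invoke prodigal in metagenome mode and parse its GFF output."""
    exe = shutil.which("prodigal")
    if exe is None:
        raise RuntimeError(
            "no gene annotation supplied and the 'prodigal' executable is not "
            "on PATH; provide a GFF3/FFN annotation or install prodigal"
        )
    genome_seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    with tempfile.TemporaryDirectory() as tmp:
        gff = Path(tmp) / "genes.gff"
        subprocess.run(
            [exe, "-i", str(fasta_path), "-f", "gff", "-o", str(gff), "-p", "meta", "-q"],
            check=True,
            capture_output=True,
        )
        return load_genes_gff(gff, genome_seqs)


def load_or_call_genes(
    fasta_path: str | Path,
    gff_path: str | Path | None = None,
    ffn_path: str | Path | None = None,
) -> list[GeneModel]:
    """Use supplied annotations when given, otherwise call genes externally."""
    if gff_path is not None:
        genome_seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
        return load_genes_gff(gff_path, genome_seqs)
    if ffn_path is not None:
        return load_genes_ffn(ffn_path)
    return call_genes_prodigal(fasta_path)


# ---------------------------------------------------------------------------
# bias vectors and outliers


def codon_bias_vector(gene: GeneModel) -> CodonBiasVector:
    """Within-amino-acid codon fractions for one gene.

    Stop codons are excluded; codons containing ambiguous bases are
    skipped and tallied. For every amino acid present, its synonymous
    codon fractions sum to 1.
    """
    counts = np.zeros(len(SENSE_CODONS))
    skipped = 0
    for codon in gene.codons():
        dim = _CODON_DIM.get(codon)
        if dim is None:
            if translate_codon(codon) != "*":
                skipped += 1
            continue
        counts[dim] += 1
    values = np.zeros_like(counts)
    observed = set()
    for aa, dims in _AA_DIMS.items():
        aa_total = counts[dims].sum()
        if aa_total > 0:
            observed.add(aa)
            values[dims] = counts[dims] / aa_total
    return CodonBiasVector(gene.gene_id, values, frozenset(observed), skipped)


def outlier_genes(vectors: list[CodonBiasVector], genome_id: str = "") -> list[OutlierCall]:
    """Flag genes whose bias is beyond Q3 + 1.5 IQR of the genome's distances.

    The genome-average vector is the per-dimension mean over genes that
    observe the amino acid; each gene's distance is computed only over
    dimensions whose amino acid that gene observes, so short genes are
    not penalized for amino acids they simply lack. Fewer than 4 genes
    make the fence meaningless: an empty call list is returned.
    """
    if len(vectors) < 4:
        warnings.warn(
            f"genome {genome_id or '?'}: {len(vectors)} gene(s) < 4; skipping outlier detection"
        )
        return []
    dim_sums = np.zeros(len(SENSE_CODONS))
    dim_ns = np.zeros(len(SENSE_CODONS))
    for v in vectors:
        for aa in v.observed_aas:
            dims = _AA_DIMS[aa]
            dim_sums[dims] += v.values[dims]
            dim_ns[dims] += 1
    with np.errstate(invalid="ignore"):
        avg = np.where(dim_ns > 0, dim_sums / np.maximum(dim_ns, 1), 0.0)

    distances = []
    for v in vectors:
        dims = [d for aa in v.observed_aas for d in _AA_DIMS[aa]]
        diff = v.values[dims] - avg[dims]
        distances.append(float(np.sqrt((diff * diff).sum())))
    distances = np.asarray(distances)
    q1, q3 = np.percentile(distances, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return [
        OutlierCall(v.gene_id, genome_id, d, fence, bool(d > fence))
        for v, d in zip(vectors, distances)
    ]
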