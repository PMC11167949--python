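"""Gene assignment and functional-effect classification of SNPs.

Each SNP is assigned to every gene whose span, extended by an
upstream/downstream margin (default 1000 bp, the conventional ``-ud 1000``),
covers its position; a SNP hitting no extended span is intergenic.  Within a
gene, one effect class is chosen by fixed precedence:

    stop_gained > missense > synonymous > splice_region
    > five_prime_utr / three_prime_utr > intron > upstream / downstream

Coding effects are computed on the coding strand from the longest-CDS
transcript; the splice region covers 1-8 bp into an intron and the last 3
exonic bases flanking an exon/intron junction.  Coordinates follow GFF3:
1-based, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

EFFECT_PRECEDENCE = (
    "stop_gained",
    "missense",
    "synonymous",
    "splice_region",
    "five_prime_utr",
    "three_prime_utr",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {e: i for i, e in enumerate(EFFECT_PRECEDENCE)}

SPLICE_INTRON_BP = 8  # 1-2 bp = donor/acceptor, 3-8 bp = extended splice region
SPLICE_EXON_BP = 3


class AnnotationConsistencyError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # sorted, 1-based inclusive
    cds: list[tuple[int, int]]  # sorted, 1-based inclusive

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def longest_transcript(self) -> Transcript | None:
        """Transcript with the longest total CDS (deterministic tie-break)."""
        coding = [t for t in self.transcripts if t.cds]
        if not coding:
            return None
        return max(coding, key=lambda t: (t.cds_length, t.transcript_id))


class GeneIndex:
    """Interval index over gene spans extended by +- ``ud`` bp."""

    def __init__(self, genes: Iterable[GeneModel], ud: int = 1000):
        self.ud = ud
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.genes[g.gene_id] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # intervaltree is half-open; gene span [start, end] 1-based
            tree.addi(max(1, g.start - ud), g.end + ud + 1, g.gene_id)

    def query(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos))
        return [self.genes[g] for g in hits]

    def gene_spans(self) -> pd.DataFrame:
        rows = [
            (g.gene_id, g.chrom, g.start, g.end, g.strand)
            for g in self.genes.values()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _validate(gene: GeneModel) -> None:
    for t in gene.transcripts:
        for cs, ce in t.cds:
            if not any(es <= cs and ce <= ee for es, ee in t.exons):
                raise AnnotationConsistencyError(
                    f"CDS {cs}-{ce} outside exons of transcript {t.transcript_id}"
                )


def build_gene_index(gff3_path, ud: int = 1000) -> GeneIndex:
    """Load GFF3 gene->mRNA->exon/CDS models into a queryable index."""
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for gf in db.features_of_type("gene"):
        gene = GeneModel(
            gene_id=gf.id, chrom=gf.seqid, strand=gf.strand, start=gf.start, end=gf.end
        )
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted(
                (f.start, f.end) for f in db.children(tf, featuretype="exon")
            )
            cds = sorted((f.start, f.end) for f in db.children(tf, featuretype="CDS"))
            gene.transcripts.append(Transcript(tf.id, exons, cds))
        _validate(gene)
        genes.append(gene)
    return GeneIndex(genes, ud=ud)


def _coding_effect(pos: int, ref: str, alt: str, tr: Transcript, strand: str, fasta):
    """(effect, codon_change) for a position inside a CDS segment."""
    chrom_seq = fasta
    offset = 0  # genomic-order offset within the concatenated CDS
    for cs, ce in tr.cds:
        if cs <= pos <= ce:
            offset += pos - cs
            break
        offset += ce - cs + 1
    cds_seq = "".join(str(chrom_seq[cs - 1 : ce]) for cs, ce in tr.cds).upper()
    if cds_seq[offset].upper() != ref.upper():
        raise ReferenceMismatchError(
            f"reference base {cds_seq[offset]!r} != VCF REF {ref!r} at CDS offset {offset}"
        )
    if strand == "+":
        coding, coff, calt = cds_seq, offset, alt.upper()
    else:
        coding = str(Seq(cds_seq).reverse_complement())
        coff = len(cds_seq) - 1 - offset
        calt = str(Seq(alt.upper()).complement())
    codon_i, within = divmod(coff, 3)
    ref_codon = coding[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:  # trailing incomplete codon
        return "synonymous", None
    alt_codon = ref_codon[:within] + calt + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    change = f"{ref_codon}/{alt_codon}({aa_ref}/{aa_alt})"
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained", change
    if aa_alt != aa_ref:
        return "missense", change
    return "synonymous", change


def _junction_distances(pos: int, exons: Sequence[tuple[int, int]]):
    """(exonic_bp_to_junction, intronic_bp_to_junction); None when n/a.

    Exonic distance counts 1 at the junction-adjacent exon base; intronic
    distance counts 1 at the first intronic base.  Gene-terminal exon edges
    are not junctions.
    """
    exonic = None
    intronic = None
    for i, (es, ee) in enumerate(exons):
        if es <= pos <= ee:
            cands = []
            if i > 0:
                cands.append(pos - es + 1)  # distance to acceptor side
            if i < len(exons) - 1:
                cands.append(ee - pos + 1)  # distance to donor side
            exonic = min(cands) if cands else None
            return exonic, None
    for (_s, prev_end), (next_start, _e) in zip(exons, exons[1:]):
        if prev_end < pos < next_start:
            intronic = min(pos - prev_end, next_start - pos)
            return None, intronic
    return None, None


def classify_effect(
    chrom: str, pos: int, ref: str, alt: str, gene: GeneModel, fasta_chrom
) -> tuple[str, str | None]:
    """Effect class (and codon change for coding effects) of a SNP in one gene.

    ``fasta_chrom`` is the pyfaidx record (or any sliceable sequence) for the
    gene's chromosome.  The SNP must lie within the gene's extended span.
    """
    if pos < gene.start or pos > gene.end:
        before = pos < gene.start
        if gene.strand == "+":
            return ("upstream" if before else "downstream"), None
        return ("downstream" if before else "upstream"), None

    tr = gene.longest_transcript()
    if tr is None:
        return "intron", None

    in_cds = any(cs <= pos <= ce for cs, ce in tr.cds)
    if in_cds:
        return _coding_effect(pos, ref, alt, tr, gene.strand, fasta_chrom)

    exonic_d, intronic_d = _junction_distances(pos, tr.exons)
    in_exon = any(es <= pos <= ee for es, ee in tr.exons)
    if not in_exon:
        if intronic_d is not None and intronic_d <= SPLICE_INTRON_BP:
            return "splice_region", None
        return "intron", None
    if exonic_d is not None and exonic_d <= SPLICE_EXON_BP:
        return "splice_region", None
    # exonic, non-CDS: UTR side relative to the coding strand
    cds_min = min(cs for cs, _ in tr.cds)
    cds_max = max(ce for _, ce in tr.cds)
    if pos < cds_min:
        return ("five_prime_utr" if gene.strand == "+" else "three_prime_utr"), None
    if pos > cds_max:
        return ("three_prime_utr" if gene.strand == "+" else "five_prime_utr"), None
    return "intron", None  # unreachable for consistent models


def annotate_sites(
    sites: pd.DataFrame, index: GeneIndex, fasta_path
) -> pd.DataFrame:
    """Annotate classified SNPs (columns chrom, pos, and the VCF ref/alt).

    ``sites`` needs columns chrom, pos, ref, alt (extra columns pass through).
    Adds gene_ids (comma-joined, empty for intergenic), effect (the highest
    precedence class over all hit genes) and codon_change.
    """
    fasta = Fasta(str(fasta_path))
    gene_col, eff_col, codon_col = [], [], []
    for row in sites.itertuples(index=False):
        hits = index.query(row.chrom, row.pos)
        if not hits:
            gene_col.append("")
            eff_col.append("intergenic")
            codon_col.append(None)
            continue
        best = ("intergenic", None)
        for gene in hits:
            eff = classify_effect(
                row.chrom, row.pos, row.ref, row.alt, gene, fasta[row.chrom]
            )
            if _RANK[eff[0]] < _RANK[best[0]]:
                best = eff
        gene_col.append(",".join(g.gene_id for g in hits))
        eff_col.append(best[0])
        codon_col.append(best[1])
    out = sites.copy()
    out["gene_ids"] = gene_col
    out["effect"] = eff_col
    out["codon_change"] = codon_col
    return out


def aggregate_candidate_genes(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-gene SNP counts by category and effect class.

    A SNP hitting several genes increments each of them (multi-assignment);
    the union of genes over all categories is the candidate gene set.
    """
    rows = []
    for row in annotated.itertuples(index=False):
        if not row.gene_ids:
            continue
        for gid in row.gene_ids.split(","):
            rows.append((gid, row.category, row.effect))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "category", "effect", "n_snps"])
    df = pd.DataFrame(rows, columns=["gene_id", "category", "effect"])
    return (
        df.groupby(["gene_id", "category", "effect"])
        .size()
        .rename("n_snps")
        .reset_index()
        .sort_values(["gene_id", "category", "effect"])
        .reset_index(drop=True)
    )
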