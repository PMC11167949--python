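import numpy as np
import pandas as pd
import pytest

from divscreen import annotate
from divscreen.annotate import (
    AnnotationConsistencyError,
    GeneModel,
    ReferenceMismatchError,
    Transcript,
    aggregate_candidate_genes,
    build_gene_index,
    classify_effect,
)

RNG = np.random.default_rng(123)


def _random_bases(n, rng=RNG):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def plus_gene_genome(cds_codons=None):
    """Genome with one + strand gene at 1001..1470 (two exons, UTRs, intron).

    Layout: 30 bp 5' UTR, CDS[0:90], 200 bp intron, CDS[90:210], 30 bp 3' UTR.
    Default CDS: ATG TCA then GCT repeats, TAA stop.
    """
    if cds_codons is None:
        cds_codons = ["ATG", "TCA"] + ["GCT"] * 67 + ["TAA"]
    cds = "".join(cds_codons)
    assert len(cds) == 210
    seq = (
        _random_bases(1000)
        + _random_bases(30)
        + cds[:90]
        + _random_bases(200)
        + cds[90:]
        + _random_bases(30)
        + _random_bases(1000)
    )
    gene = GeneModel(
        "geneP",
        "1",
        "+",
        1001,
        1470,
        [Transcript("geneP.t1", [(1001, 1120), (1321, 1470)], [(1031, 1120), (1321, 1440)])],
    )
    return seq, gene


class TestGeneIndex:
    def _write(self, tmp_path, lines):
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n" + "".join(lines))
        return gff

    def _gene_lines(self, gid, start, end, strand="+"):
        tid = gid + ".t1"
        return [
            f"1\tx\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n",
            f"1\tx\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}\n",
            f"1\tx\texon\t{start}\t{end}\t.\t{strand}\t.\tID={tid}.e1;Parent={tid}\n",
            f"1\tx\tCDS\t{start}\t{start+89}\t.\t{strand}\t0\tID={tid}.c1;Parent={tid}\n",
        ]

    def test_extended_span_includes_500bp_upstream(self, tmp_path):
        gff = self._write(tmp_path, self._gene_lines("g1", 2000, 2899))
        idx = build_gene_index(gff, ud=1000)
        assert [g.gene_id for g in idx.query("1", 1500)] == ["g1"]

    def test_beyond_margin_excluded(self, tmp_path):
        gff = self._write(tmp_path, self._gene_lines("g1", 2000, 2899))
        idx = build_gene_index(gff, ud=1000)
        assert idx.query("1", 999) == []
        assert [g.gene_id for g in idx.query("1", 1000)] == ["g1"]
        assert idx.query("1", 3900) == []

    def test_overlapping_genes_both_returned(self, tmp_path):
        gff = self._write(
            tmp_path,
            self._gene_lines("g1", 2000, 2899) + self._gene_lines("g2", 2500, 3399, "-"),
        )
        idx = build_gene_index(gff, ud=0)
        assert [g.gene_id for g in idx.query("1", 2600)] == ["g1", "g2"]

    def test_cds_outside_exon_rejected(self, tmp_path):
        lines = self._gene_lines("g1", 2000, 2899)
        lines[3] = "1\tx\tCDS\t1500\t1589\t.\t+\t0\tID=g1.t1.c1;Parent=g1.t1\n"
        gff = self._write(tmp_path, lines)
        with pytest.raises(AnnotationConsistencyError):
            build_gene_index(gff)


class TestEffects:
    def test_synonymous_third_position(self):
        seq, gene = plus_gene_genome()
        # codon 3 (GCT) occupies CDS offsets 6-8 -> genomic 1037..1039
        assert seq[1038] == "T"
        eff, change = classify_effect("1", 1039, "T", "C", gene, seq)
        assert eff == "synonymous" and "GCT/GCC" in change and "(A/A)" in change

    def test_missense_in_start_codon(self):
        seq, gene = plus_gene_genome()
        eff, change = classify_effect("1", 1033, "G", "A", gene, seq)
        assert eff == "missense" and "(M/I)" in change

    def test_stop_gained(self):
        seq, gene = plus_gene_genome()
        # TCA codon at CDS offsets 3-5 -> genomic 1034..1036; C->A gives TAA
        eff, change = classify_effect("1", 1035, "C", "A", gene, seq)
        assert eff == "stop_gained" and "(S/*)" in change

    def test_splice_region_boundaries_match_distance_rule(self):
        seq, gene = plus_gene_genome()
        exons = gene.transcripts[0].exons
        for pos in range(1121, 1321):
            eff, _ = classify_effect("1", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "C", gene, seq)
            dist = min(pos - 1120, 1321 - pos)  # brute-force distance into intron
            assert eff == ("splice_region" if dist <= 8 else "intron"), pos

    def test_utr_and_flank_classes(self):
        seq, gene = plus_gene_genome()
        ref = lambda p: seq[p - 1]
        alt = lambda p: "A" if ref(p) != "A" else "C"
        assert classify_effect("1", 1010, ref(1010), alt(1010), gene, seq)[0] == "five_prime_utr"
        assert classify_effect("1", 1450, ref(1450), alt(1450), gene, seq)[0] == "three_prime_utr"
        assert classify_effect("1", 901, ref(901), alt(901), gene, seq)[0] == "upstream"
        assert classify_effect("1", 1770, ref(1770), alt(1770), gene, seq)[0] == "downstream"

    def test_exonic_splice_region_in_utr_exon(self):
        # first exon is fully non-coding; its 3' edge abuts the intron
        seq = _random_bases(400)
        gene = GeneModel(
            "gU", "1", "+", 1, 300,
            [Transcript("gU.t1", [(1, 100), (201, 300)], [(231, 290)])],
        )
        for pos, want in [(98, "splice_region"), (100, "splice_region"), (95, "five_prime_utr")]:
            ref = seq[pos - 1]
            eff, _ = classify_effect("1", pos, ref, "A" if ref != "A" else "C", gene, seq)
            assert eff == want, pos

    def test_reference_mismatch_raises(self):
        seq, gene = plus_gene_genome()
        wrong = "A" if seq[1038] != "A" else "C"
        with pytest.raises(ReferenceMismatchError):
            classify_effect("1", 1039, wrong, "G", gene, seq)

    def test_strand_symmetry(self):
        seq, gene = plus_gene_genome()
        L = len(seq)
        rc = _revcomp(seq)
        mirror = lambda p: L + 1 - p
        tr = gene.transcripts[0]
        gene_rc = GeneModel(
            gene.gene_id, "1", "-", mirror(gene.end), mirror(gene.start),
            [
                Transcript(
                    tr.transcript_id,
                    sorted((mirror(e), mirror(s)) for s, e in tr.exons),
                    sorted((mirror(e), mirror(s)) for s, e in tr.cds),
                )
            ],
        )
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(5)
        for pos in [1033, 1035, 1039, 1010, 1125, 1250, 1450, 901, 1770]:
            ref = seq[pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
            if alt == ref:
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            eff_fwd, _ = classify_effect("1", pos, ref, alt, gene, seq)
            eff_rev, _ = classify_effect(
                "1", mirror(pos), ref.translate(comp), alt.translate(comp), gene_rc, rc
            )
            assert eff_fwd == eff_rev, pos


class TestAggregation:
    def _annotated(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "category", "gene_ids", "effect"]
        )

    def test_multi_gene_hit_increments_both(self):
        df = self._annotated([("1", 10, "A_SPECIFIC", "g1,g2", "intron")])
        agg = aggregate_candidate_genes(df)
        assert set(agg.gene_id) == {"g1", "g2"}
        assert (agg.n_snps == 1).all()

    def test_empty_input_empty_table(self):
        assert aggregate_candidate_genes(self._annotated([])).empty

    def test_counts_match_recount(self):
        rows = [
            ("1", 1, "A_SPECIFIC", "g1", "intron"),
            ("1", 2, "A_SPECIFIC", "g1", "missense"),
            ("1", 3, "B_PREDOMINANT", "g1,g2", "intron"),
            ("1", 4, "A_SPECIFIC", "", "intergenic"),
        ]
        agg = aggregate_candidate_genes(self._annotated(rows))
        assert agg.n_snps.sum() == 4  # 3 single hits + 1 double, intergenic skipped
        g1 = agg[agg.gene_id == "g1"]
        assert g1.n_snps.sum() == 3


def test_file_based_annotation_roundtrip(tmp_path):
    """annotate_sites on a written FASTA/GFF3 agrees with direct classification."""
    seq, gene = plus_gene_genome()
    (tmp_path / "ref.fa").write_text(">1\n" + "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60)) + "\n")
    tid = "geneP.t1"
    gff = ["##gff-version 3\n", f"1\tx\tgene\t1001\t1470\t.\t+\t.\tID=geneP\n",
           f"1\tx\tmRNA\t1001\t1470\t.\t+\t.\tID={tid};Parent=geneP\n"]
    for i, (s, e) in enumerate(gene.transcripts[0].exons, 1):
        gff.append(f"1\tx\texon\t{s}\t{e}\t.\t+\t.\tID={tid}.e{i};Parent={tid}\n")
    for i, (s, e) in enumerate(gene.transcripts[0].cds, 1):
        gff.append(f"1\tx\tCDS\t{s}\t{e}\t.\t+\t0\tID={tid}.c{i};Parent={tid}\n")
    (tmp_path / "g.gff3").write_text("".join(gff))
    idx = build_gene_index(tmp_path / "g.gff3", ud=200)
    sites = pd.DataFrame(
        {
            "chrom": ["1"] * 3,
            "pos": [1039, 1035, 50],
            "ref": [seq[1038], seq[1034], seq[49]],
            "alt": ["C", "A", "A" if seq[49] != "A" else "C"],
            "category": ["A_SPECIFIC"] * 3,
        }
    )
    out = annotate.annotate_sites(sites, idx, tmp_path / "ref.fa")
    assert list(out.effect) == ["synonymous", "stop_gained", "intergenic"]
    assert out.gene_ids.tolist() == ["geneP", "geneP", ""]
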