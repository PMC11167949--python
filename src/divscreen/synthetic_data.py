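"""Two-population synthetic cohorts with ground truth.

Generates a multi-sample VCF, reference FASTA, GFF3 gene models, a
sample->population table and a truth TSV for a configurable two-population
cohort.  Genotypes are drawn under Hardy-Weinberg within each population
(binomial(2, p) per diploid); a configurable fraction of sites is planted as
population-specific (focal ALT frequency in [0.5, 1], zero in the other
population) or population-predominant (focal frequency in [0.5, 1], other
frequency in (0, focal - 0.5]), and one genomic region can carry a planted
selective-sweep footprint (target-population diversity scaled down, pushing
frequencies toward fixation).  Everything is reproducible byte-for-byte from
the seed.

Two sampling modes exist: ``"binomial"`` draws genotypes from the true
frequencies (sampling noise included); ``"exact"`` constructs genotypes whose
allele counts hit the planted frequencies exactly, which guarantees that the
downstream classifier recovers every planted category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import popfreq

SPACING = 7  # minimum distance between simulated SNPs; > cluster window (5)
BASES = np.array(list("ACGT"))
PASSING_INFO = "QD=25.00;MQ=60.00;FS=1.000;MQRankSum=0.000;ReadPosRankSum=0.000"
PASSING_QUAL = "100"

_STOP = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the screened cohort: 44 + 29 diploid individuals, planted
    category fractions close to the observed genome-wide proportions of
    specific/predominant SNPs, and a U-shaped Beta baseline for shared
    neutral allele frequencies.
    """

    n_pop_a: int = 44
    n_pop_b: int = 29
    n_sites: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 5_000_000, "2": 5_000_000}
    )
    af_beta: tuple[float, float] = (0.5, 0.5)
    frac_specific_a: float = 0.05
    frac_predominant_a: float = 0.08
    frac_specific_b: float = 0.0025
    frac_predominant_b: float = 0.035
    missing_rate: float = 0.02
    sweep_region: tuple[str, int, int, str] | None = None  # (chrom, start, end, "A"|"B")
    sweep_diversity_factor: float = 0.1
    n_genes: int = 40
    sampling: str = "binomial"  # or "exact"
    frac_filter_fail: float = 0.0
    max_missing: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_specific_a,
            self.frac_predominant_a,
            self.frac_specific_b,
            self.frac_predominant_b,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ConfigError("category fractions must be >= 0 and sum to <= 1")
        if not 0.0 <= self.missing_rate < 0.10:
            raise ConfigError("missing_rate must lie in [0, 0.10)")
        if self.sampling not in ("binomial", "exact"):
            raise ConfigError("sampling must be 'binomial' or 'exact'")
        if self.sweep_region is not None:
            chrom, start, end, target = self.sweep_region
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"sweep region chromosome {chrom!r} not simulated")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ConfigError("sweep region outside chromosome bounds")
            if target not in ("A", "B"):
                raise ConfigError("sweep target population must be 'A' or 'B'")
            if not 0.0 < self.sweep_diversity_factor < 1.0:
                raise ConfigError("sweep_diversity_factor must lie in (0, 1)")


@dataclass(frozen=True)
class CohortPaths:
    vcf: Path
    fasta: Path
    gff3: Path
    truth: Path
    pops: Path


def sweep_adjusted_frequency(
    p: float, diversity_factor: float, fix_alt: bool | None = None
) -> float:
    """Frequency with heterozygosity scaled to diversity_factor x baseline.

    Solves p'(1-p') = f * p(1-p), taking the root near 1 when the ALT allele
    fixes and the root near 0 when REF fixes; f -> 0 drives the site to
    fixation or loss.  ``fix_alt`` names the fixing allele (the one carried
    by the swept haplotype); by default the nearer boundary is used.
    """
    disc = max(0.0, 1.0 - 4.0 * diversity_factor * p * (1.0 - p))
    root = math.sqrt(disc)
    if fix_alt is None:
        fix_alt = p >= 0.5
    return (1.0 + root) / 2.0 if fix_alt else (1.0 - root) / 2.0


def plant_sweep_region(
    genotype_counts: np.ndarray,
    chroms: Sequence[str],
    positions: np.ndarray,
    region: tuple[str, int, int] | None,
    target_indices: np.ndarray,
    diversity_factor: float,
    rng: np.random.Generator,
    true_freqs: np.ndarray | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> np.ndarray:
    """Overwrite target-population genotypes inside a region with a sweep.

    ``genotype_counts`` is (n_sites, n_samples) of ALT-allele dosages (0/1/2).
    Frequencies of in-region sites are pushed toward the nearer fixation
    boundary so the target population's expected heterozygosity is scaled by
    ``diversity_factor``; target genotypes are redrawn from the new
    frequencies.  Sites outside the region (or all sites if ``region`` is
    None) are untouched.  Returns a modified copy.
    """
    if region is None:
        return genotype_counts
    chrom, start, end = region[:3]
    if chrom_lengths is not None:
        if chrom not in chrom_lengths or not (0 <= start < end <= chrom_lengths[chrom]):
            raise ConfigError("sweep region outside chromosome bounds")
    out = genotype_counts.copy()
    chroms = np.asarray(chroms, dtype=object)
    in_region = (chroms == chrom) & (positions > start) & (positions <= end)
    idx = np.nonzero(in_region)[0]
    for i in idx:
        if true_freqs is not None:
            p = float(true_freqs[i])
        else:
            p = float(out[i, target_indices].sum()) / (2 * len(target_indices))
        p_new = sweep_adjusted_frequency(
            p, diversity_factor, fix_alt=bool(rng.random() < p)
        )
        out[i, target_indices] = rng.binomial(2, p_new, size=len(target_indices))
    return out


def _allocate_positions(cfg: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Site chromosomes and positions, spaced >= SPACING bp, sorted."""
    total = sum(cfg.chrom_lengths.values())
    chrom_names = list(cfg.chrom_lengths)
    counts = {}
    assigned = 0
    for i, ch in enumerate(chrom_names):
        if i == len(chrom_names) - 1:
            counts[ch] = cfg.n_sites - assigned
        else:
            counts[ch] = int(round(cfg.n_sites * cfg.chrom_lengths[ch] / total))
            assigned += counts[ch]
    chroms, positions = [], []
    for ch in chrom_names:
        n = counts[ch]
        slots = (cfg.chrom_lengths[ch] - 1) // SPACING
        if n > slots:
            raise ConfigError(f"chromosome {ch} too short for {n} spaced sites")
        chosen = np.sort(rng.choice(slots, size=n, replace=False))
        pos = chosen * SPACING + 1
        chroms += [ch] * n
        positions.append(pos)
    return np.array(chroms, dtype=object), np.concatenate(positions)


def _plant_frequencies(cfg: SimulationConfig, rng, n_sites, eligible: np.ndarray):
    """Assign per-site true ALT frequencies and planted categories.

    Returns (af_a, af_b, planned) where ``planned`` holds the intended
    category string per site ("NEUTRAL" for unplanted sites).  In exact mode
    the frequencies are drawn on the grid achievable by the sample sizes so
    that emitted allele counts reproduce them exactly.
    """
    na, nb = 2 * cfg.n_pop_a, 2 * cfg.n_pop_b
    p0 = rng.beta(cfg.af_beta[0], cfg.af_beta[1], size=n_sites)
    if cfg.sampling == "exact":
        af_a = np.round(p0 * na) / na
        af_b = np.round(p0 * nb) / nb
    else:
        af_a = p0.copy()
        af_b = p0.copy()
    planned = np.full(n_sites, "NEUTRAL", dtype="<U13")

    pool = np.nonzero(eligible)[0]
    pool = rng.permutation(pool)
    cursor = 0

    def take(frac):
        nonlocal cursor
        k = int(round(frac * n_sites))
        chosen = pool[cursor : cursor + k]
        cursor += k
        return chosen

    def draw_focal(n):
        return 0.5 + rng.uniform(0.0, 0.5, size=n)

    # specific: focal in [0.5, 1], other exactly 0
    for cat, frac, focal_n, other_n, a_is_focal in (
        ("A_SPECIFIC", cfg.frac_specific_a, na, nb, True),
        ("B_SPECIFIC", cfg.frac_specific_b, nb, na, False),
    ):
        idx = take(frac)
        if cfg.sampling == "exact":
            k = rng.integers(focal_n // 2 + focal_n % 2, focal_n + 1, size=len(idx))
            focal = k / focal_n
        else:
            focal = draw_focal(len(idx))
        (af_a if a_is_focal else af_b)[idx] = focal
        (af_b if a_is_focal else af_a)[idx] = 0.0
        planned[idx] = cat

    # predominant: focal in [0.5, 1], other in (0, focal - 0.5], dAF >= 0.5
    for cat, frac, focal_n, other_n, a_is_focal in (
        ("A_PREDOMINANT", cfg.frac_predominant_a, na, nb, True),
        ("B_PREDOMINANT", cfg.frac_predominant_b, nb, na, False),
    ):
        idx = take(frac)
        if cfg.sampling == "exact":
            # smallest focal count leaving room for >= 1 other-pop allele
            kmin = int(math.ceil(focal_n / 2 + focal_n / other_n))
            k_focal = rng.integers(kmin, focal_n + 1, size=len(idx))
            focal = k_focal / focal_n
            other = np.empty(len(idx))
            for j, kf in enumerate(k_focal):
                kmax = (other_n * (2 * kf - focal_n)) // (2 * focal_n)
                if kf == focal_n:  # other must stay strictly below 0.5
                    kmax = min(kmax, (other_n - 1) // 2)
                other[j] = rng.integers(1, kmax + 1) / other_n
        else:
            focal = draw_focal(len(idx))
            u = rng.uniform(0.0, 1.0, size=len(idx))
            u[u == 0.0] = 0.5
            other = (focal - 0.5) * u
            zero = other == 0.0  # focal drawn exactly 0.5
            if zero.any():
                focal[zero] = 0.75
                other[zero] = 0.125
        (af_a if a_is_focal else af_b)[idx] = focal
        (af_b if a_is_focal else af_a)[idx] = other
        planned[idx] = cat

    return af_a, af_b, planned


def _draw_counts(af: np.ndarray, n_dip: int, mode: str, rng) -> np.ndarray:
    """(n_sites, n_dip) ALT dosage matrix for one population."""
    if mode == "binomial":
        return rng.binomial(2, af[:, None], size=(len(af), n_dip)).astype(np.int8)
    out = np.empty((len(af), n_dip), dtype=np.int8)
    n_alleles = 2 * n_dip
    for i, p in enumerate(af):
        k = int(round(p * n_alleles))
        alleles = np.zeros(n_alleles, dtype=np.int8)
        alleles[:k] = 1
        out[i] = rng.permutation(alleles).reshape(n_dip, 2).sum(axis=1)
    return out


def _gene_layout(cfg: SimulationConfig, rng):
    """Non-overlapping two-exon gene models alternating strands.

    Each gene: 30 bp 5' UTR, 90 bp CDS, 200 bp intron, 120 bp CDS (incl. the
    stop codon), 30 bp 3' UTR; total span 470 bp, CDS length 210 (div. by 3).
    Returns a list of dicts with genomic coordinates (1-based inclusive).
    """
    span = 470
    genes = []
    chrom_names = list(cfg.chrom_lengths)
    per_chrom = {ch: 0 for ch in chrom_names}
    for g in range(cfg.n_genes):
        per_chrom[chrom_names[g % len(chrom_names)]] += 1
    gid = 0
    for ch in chrom_names:
        n = per_chrom[ch]
        if n == 0:
            continue
        length = cfg.chrom_lengths[ch]
        stride = max(span + 1000, (length - 2000) // max(n, 1))
        if stride * (n - 1) + span + 1000 > length:
            raise ConfigError(f"chromosome {ch} too short for {n} genes")
        for j in range(n):
            gid += 1
            start = 1001 + j * stride  # 1-based genomic start of the gene
            strand = "+" if gid % 2 else "-"
            genes.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": ch,
                    "strand": strand,
                    "start": start,
                    "end": start + span - 1,
                }
            )
    return genes


def _gene_segments(gene: dict, rng):
    """Plus-strand layout offsets, mirrored for minus-strand genes.

    Returns (exons, cds, segment_sequence) with exon/CDS coordinates 1-based
    inclusive in genome space and the 470-bp genomic sequence of the gene.
    """
    # plus-strand layout, offsets within the 470-bp span (0-based, half-open)
    exon_off = [(0, 120), (320, 470)]
    cds_off = [(30, 120), (320, 440)]
    cds_len = sum(e - s for s, e in cds_off)  # 210
    codons = ["ATG"] + [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=cds_len // 3 - 2)
    ] + ["TAA"]
    cds_seq = "".join(codons)
    utr5 = "".join(BASES[rng.integers(0, 4, size=30)])
    utr3 = "".join(BASES[rng.integers(0, 4, size=30)])
    intron = "".join(BASES[rng.integers(0, 4, size=200)])
    plus_seq = utr5 + cds_seq[:90] + intron + cds_seq[90:] + utr3
    span = len(plus_seq)
    if gene["strand"] == "+":
        seq = plus_seq
        exons = [(gene["start"] + s, gene["start"] + e - 1) for s, e in exon_off]
        cds = [(gene["start"] + s, gene["start"] + e - 1) for s, e in cds_off]
    else:
        seq = plus_seq.translate(_COMPLEMENT)[::-1]
        exons = sorted(
            (gene["start"] + span - e, gene["start"] + span - s - 1) for s, e in exon_off
        )
        cds = sorted(
            (gene["start"] + span - e, gene["start"] + span - s - 1) for s, e in cds_off
        )
    return sorted(exons), sorted(cds), seq


def _write_fasta(path: Path, seqs: dict[str, np.ndarray]) -> None:
    with path.open("w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = "".join(arr)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def _write_gff3(path: Path, genes: list[dict]) -> None:
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g["gene_id"]
            base = f"{g['chrom']}\tdivscreen\t"
            tail = f"\t.\t{g['strand']}\t"
            fh.write(
                f"{base}gene\t{g['start']}\t{g['end']}{tail}.\tID={gid}\n"
            )
            tid = gid + ".t1"
            fh.write(
                f"{base}mRNA\t{g['start']}\t{g['end']}{tail}.\tID={tid};Parent={gid}\n"
            )
            for i, (s, e) in enumerate(g["exons"], 1):
                fh.write(
                    f"{base}exon\t{s}\t{e}{tail}.\tID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (s, e) in enumerate(g["cds"], 1):
                fh.write(
                    f"{base}CDS\t{s}\t{e}{tail}0\tID={tid}.cds{i};Parent={tid}\n"
                )


FAIL_INFO = {
    "qd": "QD=1.50;MQ=60.00;FS=1.000;MQRankSum=0.000;ReadPosRankSum=0.000",
    "mq": "QD=25.00;MQ=30.00;FS=1.000;MQRankSum=0.000;ReadPosRankSum=0.000",
    "fs": "QD=25.00;MQ=60.00;FS=75.000;MQRankSum=0.000;ReadPosRankSum=0.000",
    "mq_rank_sum": "QD=25.00;MQ=60.00;FS=1.000;MQRankSum=-13.000;ReadPosRankSum=0.000",
    "read_pos_rank_sum": "QD=25.00;MQ=60.00;FS=1.000;MQRankSum=0.000;ReadPosRankSum=-9.000",
}


def simulate_cohort(config: SimulationConfig, out_dir) -> CohortPaths:
    """Generate VCF + FASTA + GFF3 + truth + population table for one cohort.

    Deterministic in ``config.seed``: identical configs produce byte-identical
    outputs.  The truth TSV records, per site, the planted ALT allele
    frequencies in both populations and the category implied by the
    classification rules (NEUTRAL when none applies).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    chroms, positions = _allocate_positions(config, rng)
    n_sites = len(positions)

    if config.sweep_region is not None:
        s_chrom, s_start, s_end, s_target = config.sweep_region
        in_sweep = (chroms == s_chrom) & (positions > s_start) & (positions <= s_end)
    else:
        in_sweep = np.zeros(n_sites, dtype=bool)

    af_a, af_b, planned = _plant_frequencies(config, rng, n_sites, ~in_sweep)

    if config.sweep_region is not None:
        # emulate a hard sweep: one haplotype fixes, so at each site the
        # fixing allele is drawn with probability equal to its frequency
        target_af = af_a if s_target == "A" else af_b
        for i in np.nonzero(in_sweep)[0]:
            p = float(target_af[i])
            target_af[i] = sweep_adjusted_frequency(
                p, config.sweep_diversity_factor, fix_alt=bool(rng.random() < p)
            )
        if config.sampling == "exact":
            n_t = 2 * (config.n_pop_a if s_target == "A" else config.n_pop_b)
            target_af[in_sweep] = np.round(target_af[in_sweep] * n_t) / n_t

    # truth categories implied by the true frequencies
    if config.sampling == "exact":
        na, nb = 2 * config.n_pop_a, 2 * config.n_pop_b
        cat_alt, _ = popfreq.classify_counts(
            np.round(af_a * na).astype(np.int64),
            np.full(n_sites, na, dtype=np.int64),
            np.round(af_b * nb).astype(np.int64),
            np.full(n_sites, nb, dtype=np.int64),
        )
        categories = cat_alt
    else:
        categories = np.array(
            [popfreq.classify_pair(a, b) for a, b in zip(af_a, af_b)], dtype="<U13"
        )
    categories = np.where(categories == "NONE", "NEUTRAL", categories)

    ga = _draw_counts(af_a, config.n_pop_a, config.sampling, rng)
    gb = _draw_counts(af_b, config.n_pop_b, config.sampling, rng)
    counts = np.concatenate([ga, gb], axis=1)
    n_samples = counts.shape[1]

    # per-genotype missingness, capped so every site survives the 10% filter
    missing = np.zeros_like(counts, dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random(counts.shape) < config.missing_rate
        cap = int(math.floor(config.max_missing * n_samples))
        for i in np.nonzero(missing.sum(axis=1) > cap)[0]:
            hit = np.nonzero(missing[i])[0]
            keep = rng.choice(hit, size=cap, replace=False)
            missing[i] = False
            missing[i, keep] = True

    # reference genome with embedded gene models, then REF/ALT per site
    seqs = {
        ch: BASES[rng.integers(0, 4, size=length)].copy()
        for ch, length in config.chrom_lengths.items()
    }
    genes = _gene_layout(config, rng)
    for g in genes:
        exons, cds, seg = _gene_segments(g, rng)
        g["exons"], g["cds"] = exons, cds
        seqs[g["chrom"]][g["start"] - 1 : g["end"]] = list(seg)

    ref = np.empty(n_sites, dtype="<U1")
    alt = np.empty(n_sites, dtype="<U1")
    base_idx = {b: i for i, b in enumerate(BASES)}
    shifts = rng.integers(1, 4, size=n_sites)
    for i in range(n_sites):
        r = seqs[chroms[i]][positions[i] - 1]
        ref[i] = r
        alt[i] = BASES[(base_idx[r] + shifts[i]) % 4]

    sample_names = [f"A{i+1:03d}" for i in range(config.n_pop_a)] + [
        f"B{i+1:03d}" for i in range(config.n_pop_b)
    ]

    # deliberately failing INFO records, if requested
    fail_cause = np.full(n_sites, "", dtype=object)
    if config.frac_filter_fail > 0:
        n_fail = int(round(config.frac_filter_fail * n_sites))
        idx = rng.choice(n_sites, size=n_fail, replace=False)
        causes = list(FAIL_INFO)
        for j, i in enumerate(np.sort(idx)):
            fail_cause[i] = causes[j % len(causes)]

    paths = CohortPaths(
        vcf=out / "cohort.vcf",
        fasta=out / "reference.fa",
        gff3=out / "genes.gff3",
        truth=out / "truth.tsv",
        pops=out / "populations.tsv",
    )
    _write_fasta(paths.fasta, seqs)
    _write_gff3(paths.gff3, genes)

    gt_lookup = np.array(["0/0", "0/1", "1/1", "./."])
    with paths.vcf.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch, length in config.chrom_lengths.items():
            fh.write(f"##contig=<ID={ch},length={length}>\n")
        for key in ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum"):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        order = np.lexsort((positions, chroms.astype(str)))
        for i in order:
            gt_idx = counts[i].astype(np.int64).copy()
            gt_idx[missing[i]] = 3
            info = FAIL_INFO[fail_cause[i]] if fail_cause[i] else PASSING_INFO
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\t{ref[i]}\t{alt[i]}\t"
                f"{PASSING_QUAL}\t.\t{info}\tGT\t"
                + "\t".join(gt_lookup[gt_idx])
                + "\n"
            )

    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "planted_allele": "ALT",
            "planted_category": categories,
            "true_af_a": af_a,
            "true_af_b": af_b,
        }
    ).sort_values(["chrom", "pos"], kind="stable")
    truth.to_csv(paths.truth, sep="\t", index=False, float_format="%.10g")

    with paths.pops.open("w") as fh:
        fh.write("sample\tpopulation\n")
        for s in sample_names:
            fh.write(f"{s}\t{'A' if s.startswith('A') else 'B'}\n")

    return paths


def simulate_filter_fixture(out_path, seed: int = 0, n_records: int = 500):
    """VCF fixture with planted violations of every site filter.

    Returns (path, truth DataFrame) where truth holds one row per record with
    its position and the planted first-cause label ("pass" for clean
    records).  Cluster pairs are spaced 3 bp apart; all other records are 20
    bp apart so no accidental clusters arise.  The cohort has 4 samples, so a
    single missing genotype (25%) violates the 10% missingness bound.
    """
    rng = np.random.default_rng(seed)
    plan_cycle = [
        "pass",
        "qd",
        "pass",
        "mq",
        "fs",
        "pass",
        "qual",
        "mq_rank_sum",
        "read_pos_rank_sum",
        "pass",
        "cluster",  # expands to two records 3 bp apart
        "multiallelic",
        "missingness",
        "pass_boundary",  # QD=2.0, FS=60.0 exactly: must pass
    ]
    records = []
    truth_rows = []
    pos = 100
    i = 0
    while len(truth_rows) < n_records:
        kind = plan_cycle[i % len(plan_cycle)]
        i += 1
        base_gts = ["0/0", "0/1", "1/1", "0/1"]
        if kind == "cluster":
            if n_records - len(truth_rows) < 2:
                kind = "pass"
            else:
                for p in (pos, pos + 3):
                    records.append((p, "A", "C", PASSING_QUAL, PASSING_INFO, base_gts))
                    truth_rows.append((p, "cluster"))
                pos += 20
                continue
        info = PASSING_INFO
        qual = PASSING_QUAL
        alt = "C"
        gts = list(base_gts)
        cause = kind
        if kind in FAIL_INFO:
            info = FAIL_INFO[kind]
        elif kind == "qual":
            qual = "20"
        elif kind == "multiallelic":
            alt = "C,G"
        elif kind == "missingness":
            gts[rng.integers(0, 4)] = "./."
        elif kind == "pass_boundary":
            info = "QD=2.00;MQ=40.00;FS=60.000;MQRankSum=-12.50;ReadPosRankSum=-8.00"
            cause = "pass"
        else:
            cause = "pass"
        records.append((pos, "A", alt, qual, info, gts))
        truth_rows.append((pos, cause))
        pos += 20

    out_path = Path(out_path)
    with out_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={pos + 1000}>\n")
        for key in ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum"):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\n")
        for p, ref_b, alt_b, qual, info, gts in records:
            fh.write(
                f"1\t{p}\t.\t{ref_b}\t{alt_b}\t{qual}\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )
    truth = pd.DataFrame(truth_rows, columns=["pos", "expected"])
    return out_path, truth
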