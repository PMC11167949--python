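"""VCF streaming and site-level filtering.

Reproduces a GATK-style hard-filter stage on called SNPs: INFO-metric bounds
(QD < 2.0, MQ < 40.0, FS > 60.0, QUAL < 30.0, MQRankSum < -12.5,
ReadPosRankSum < -8.0 all fail), a SNP-cluster filter (>= 2 SNPs within any
5-bp window are all removed), and a biallelic + <= 10% sample-missingness
requirement.  An absent INFO metric never fails its rule - upstream callers
only emit rank-sum metrics when they are computable.

Filters are accounted by *first cause* in a fixed order (the order above,
then cluster, multiallelic, missingness), so the per-rule failure counts plus
the passing count always equal the number of input SNP records.  Indels and
other non-SNP records are skipped and counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from cyvcf2 import VCF

#: (report key, INFO key, comparison, bound); fail when comparison holds.
HARD_FILTER_RULES: tuple[tuple[str, str, str, float], ...] = (
    ("qd", "QD", "lt", 2.0),
    ("mq", "MQ", "lt", 40.0),
    ("fs", "FS", "gt", 60.0),
    ("qual", "QUAL", "lt", 30.0),
    ("mq_rank_sum", "MQRankSum", "lt", -12.5),
    ("read_pos_rank_sum", "ReadPosRankSum", "lt", -8.0),
)

FILTER_ORDER = tuple(r[0] for r in HARD_FILTER_RULES) + (
    "cluster",
    "multiallelic",
    "missingness",
)


@dataclass
class VariantSite:
    """One SNP record: alleles, filter metrics and per-sample genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None
    info: dict[str, float]
    genotypes: np.ndarray  # (n_samples, 2); 0=REF, 1=ALT, -1=missing
    n_alt_alleles: int = 1  # >1 marks a multiallelic record

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1")
        if self.ref == self.alt:
            raise ValueError("REF and ALT alleles identical")

    @property
    def missing_fraction(self) -> float:
        """Fraction of samples with any missing allele (half-calls count)."""
        g = self.genotypes
        if g.shape[0] == 0:
            return 0.0
        return float((g < 0).any(axis=1).sum()) / g.shape[0]


@dataclass
class FilterReport:
    """First-cause failure accounting for one filtering run."""

    total: int = 0
    passing: int = 0
    failed: dict[str, int] = field(default_factory=lambda: {k: 0 for k in FILTER_ORDER})
    skipped_non_snp: int = 0

    def check_conservation(self) -> None:
        if self.passing + sum(self.failed.values()) != self.total:
            raise AssertionError(
                f"filter accounting broken: {self.passing} passing + "
                f"{sum(self.failed.values())} failing != {self.total} total"
            )

    def to_frame(self):
        import pandas as pd

        rows = [("total_snp_records", self.total), ("passing", self.passing)]
        rows += [(f"fail_{k}", v) for k, v in self.failed.items()]
        rows.append(("skipped_non_snp", self.skipped_non_snp))
        return pd.DataFrame(rows, columns=["metric", "count"])


class VcfParseError(ValueError):
    pass


def _site_from_variant(v) -> VariantSite:
    gts = np.asarray([g[:2] for g in v.genotypes], dtype=np.int16)
    if gts.size == 0:
        gts = gts.reshape(0, 2)
    # half-calls: any missing allele marks the sample fully missing
    half = (gts < 0).any(axis=1)
    gts[half] = -1
    info = {}
    for _, key, _, _ in HARD_FILTER_RULES:
        if key == "QUAL":
            continue
        val = v.INFO.get(key)
        if val is not None:
            try:
                info[key] = float(val)
            except (TypeError, ValueError) as exc:
                raise VcfParseError(
                    f"malformed INFO {key}={val!r} at {v.CHROM}:{v.POS}"
                ) from exc
    return VariantSite(
        chrom=v.CHROM,
        pos=v.POS,
        ref=v.REF,
        alt=v.ALT[0] if v.ALT else ".",
        qual=v.QUAL,
        info=info,
        genotypes=gts,
        n_alt_alleles=len(v.ALT),
    )


def _is_snp_record(v) -> bool:
    return len(v.REF) == 1 and len(v.ALT) >= 1 and all(len(a) == 1 for a in v.ALT)


def read_sites(vcf_path, with_samples: bool = False) -> Iterator:
    """Yield VariantSite for each SNP record (optionally with header samples)."""
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    try:
        for v in vcf:
            if not _is_snp_record(v):
                continue
            site = _site_from_variant(v)
            yield (site, samples) if with_samples else site
    finally:
        vcf.close()


def apply_hard_filters(
    site: VariantSite, rules: Sequence[tuple[str, str, str, float]] = HARD_FILTER_RULES
) -> tuple[bool, str | None]:
    """Evaluate the INFO/QUAL hard filters; returns (passed, first failing rule).

    A metric absent from INFO passes its rule; comparisons are strict, so e.g.
    QD = 2.0 or FS = 60.0 exactly both pass.
    """
    for key, info_key, op, bound in rules:
        value = site.qual if info_key == "QUAL" else site.info.get(info_key)
        if value is None:
            continue
        if (op == "lt" and value < bound) or (op == "gt" and value > bound):
            return False, key
    return True, None


def cluster_positions(
    positions: Sequence[int], cluster_size: int = 2, window_bp: int = 5
) -> set[int]:
    """Positions that fall in any ``window_bp``-base window holding >=
    ``cluster_size`` SNPs (all members of an offending cluster are removed).

    ``positions`` must be sorted; with the defaults, two SNPs <= 4 bp apart
    (both inside one 5-consecutive-base window) are both discarded.
    """
    pos = list(positions)
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be sorted")
    bad: set[int] = set()
    k = cluster_size - 1
    for i in range(len(pos) - k):
        if pos[i + k] - pos[i] <= window_bp - 1:
            bad.update(pos[i : i + k + 1])
    return bad


def apply_cluster_filter(
    positions: Sequence[int], cluster_size: int = 2, window_bp: int = 5
) -> list[int]:
    """Surviving positions after removing clustered SNPs (one chromosome)."""
    bad = cluster_positions(positions, cluster_size, window_bp)
    return [p for p in positions if p not in bad]


def apply_missingness_and_biallelic(
    site: VariantSite, max_missing: float = 0.10
) -> tuple[bool, str | None]:
    """Fail multiallelic records and records with > ``max_missing`` sample
    missingness (a sample with any missing allele counts as missing once)."""
    if site.n_alt_alleles > 1:
        return False, "multiallelic"
    if site.missing_fraction > max_missing:
        return False, "missingness"
    return True, None


def filter_vcf(
    vcf_in,
    vcf_out,
    cluster_size: int = 2,
    cluster_window_bp: int = 5,
    max_missing: float = 0.10,
    rules: Sequence[tuple[str, str, str, float]] = HARD_FILTER_RULES,
) -> FilterReport:
    """Apply all site filters to a VCF, writing the passing records.

    Two streaming passes: the first collects SNP positions per chromosome for
    cluster detection (all SNP records participate, mirroring cluster flagging
    before other filters thin the site list); the second applies the rules in
    first-cause order and writes survivors.  The output is position-sorted
    whenever the input is and re-filtering it removes nothing.
    """
    vcf_in, vcf_out = str(vcf_in), str(vcf_out)
    per_chrom: dict[str, list[int]] = {}
    vcf = VCF(vcf_in)
    for v in vcf:
        if _is_snp_record(v):
            per_chrom.setdefault(v.CHROM, []).append(v.POS)
    vcf.close()
    clustered = {
        chrom: cluster_positions(pos, cluster_size, cluster_window_bp)
        for chrom, pos in per_chrom.items()
    }

    report = FilterReport()
    vcf = VCF(vcf_in)
    out_path = Path(vcf_out)
    with out_path.open("w") as out:
        out.write(vcf.raw_header)
        for v in vcf:
            if not _is_snp_record(v):
                report.skipped_non_snp += 1
                continue
            report.total += 1
            site = _site_from_variant(v)
            ok, cause = apply_hard_filters(site, rules)
            if ok and site.pos in clustered.get(site.chrom, ()):
                ok, cause = False, "cluster"
            if ok:
                ok, cause = apply_missingness_and_biallelic(site, max_missing)
            if ok:
                report.passing += 1
                out.write(str(v).rstrip("\n") + "\n")
            else:
                report.failed[cause] += 1
    vcf.close()
    report.check_conservation()
    return report
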