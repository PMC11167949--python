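"""Per-population allele frequencies and specific/predominant SNP classification.

The screen compares an allele's frequency between a focal population and the
other population.  An allele is *specific* to the focal population when its
frequency there is at least the cutoff (default 0.50) and exactly zero in the
other population; it is *predominant* when its focal frequency is at least the
cutoff, its frequency in the other population is below the cutoff but nonzero,
and the absolute frequency difference |dAF| is at least the cutoff.  The two
categories are disjoint by construction.

The 0.50 cutoff comes from the one-locus quantitative-genetics population mean

    mu = a*(p - q) + 2*p*q*d

with additive effect ``a``, dominance deviation ``d`` and allele frequencies
``p`` (increasing allele) and ``q = 1 - p``: the frequency at which ``mu``
crosses the mid-parent value is p* = 0.5 for d = 0 and p* = 1 - sqrt(2)/2
(about 0.29, commonly rounded to 0.30) for complete dominance d = a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("A_SPECIFIC", "A_PREDOMINANT", "B_SPECIFIC", "B_PREDOMINANT", "NONE")

#: AF / dAF histogram bin edges; bins are [0.5,0.6), ..., [0.9,1.0] with the
#: last bin closed so fully fixed alleles land in the top bin.
HIST_EDGES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class PopulationSpec:
    """A named population and its ordered sample identifiers."""

    name: str
    samples: tuple[str, ...]

    def indices_in(self, header_samples: Sequence[str]) -> np.ndarray:
        """Column indices of this population's samples in a VCF header."""
        lookup = {s: i for i, s in enumerate(header_samples)}
        missing = [s for s in self.samples if s not in lookup]
        if missing:
            raise KeyError(
                f"samples of population {self.name!r} absent from VCF header: "
                f"{missing[:5]}"
            )
        return np.array([lookup[s] for s in self.samples], dtype=int)


@dataclass(frozen=True)
class SiteFrequency:
    """One allele's frequency at one site in both populations.

    Frequencies are computed over called alleles only; ``called_a``/``called_b``
    are the non-missing allele denominators.
    """

    chrom: str
    pos: int
    allele: str  # "REF" or "ALT"
    af_a: float
    af_b: float
    called_a: int
    called_b: int


@dataclass(frozen=True)
class QuantGenParams:
    """One-locus model parameters: additive effect, dominance, allele freq."""

    additive_effect: float
    dominance_deviation: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency p={self.p} outside [0, 1]")


def population_mean(params: QuantGenParams) -> float:
    """Population mean mu = a*(p - q) + 2*p*q*d with q = 1 - p."""
    a, d, p = params.additive_effect, params.dominance_deviation, params.p
    q = 1.0 - p
    return a * (p - q) + 2.0 * p * q * d


def threshold_frequency(d_over_a: float) -> float:
    """Smallest allele frequency p* at which the population mean exceeds zero.

    Solves a*(2p - 1) + 2p(1-p)*d = 0 for p in [0, 1] with r = d/a, i.e. the
    root of -2r p^2 + (2 + 2r) p - 1 = 0.  r = 0 gives exactly 0.5; r = 1
    gives 1 - sqrt(2)/2 ~ 0.2929 (often rounded to 0.30).

    Parameters
    ----------
    d_over_a : dominance ratio d/a, in [0, 1] (no overdominance).
    """
    r = float(d_over_a)
    if r < 0:
        raise ValueError("d_over_a must be >= 0")
    if r == 0.0:
        return 0.5
    disc = (2.0 + 2.0 * r) ** 2 - 8.0 * r
    if disc < 0:
        raise ValueError("no root in [0, 1] for d_over_a=%r" % r)
    root = ((2.0 + 2.0 * r) - math.sqrt(disc)) / (4.0 * r)
    if not 0.0 <= root <= 1.0:
        raise ValueError("no root in [0, 1] for d_over_a=%r" % r)
    return root


def allele_frequency(
    genotypes: np.ndarray, pop_indices: np.ndarray, allele: str = "ALT"
) -> tuple[float, int]:
    """Frequency of REF or ALT over called alleles in one population.

    Parameters
    ----------
    genotypes : (n_samples, 2) int array; 0=REF, 1=ALT, -1=missing.  A sample
        with any missing allele is treated as fully missing.
    pop_indices : column indices of the population's samples.
    allele : "REF" or "ALT".

    Returns
    -------
    (frequency, called_allele_count); frequency is NaN when no alleles are
    called (the site is then excluded from classification).
    """
    g = np.asarray(genotypes)[pop_indices]
    called = (g >= 0).all(axis=1)
    n_alleles = 2 * int(called.sum())
    if n_alleles == 0:
        return float("nan"), 0
    alt = int(g[called].sum())
    count = alt if allele == "ALT" else n_alleles - alt
    return count / n_alleles, n_alleles


def classify_allele(af_focal: float, af_other: float, threshold: float = 0.5) -> str:
    """Category of one allele for one focal population, from frequencies.

    Returns "SPECIFIC", "PREDOMINANT" or "NONE".  Comparisons follow the
    screen's definitions: af_focal >= threshold (inclusive), af_other <
    threshold (strict), specific requires af_other exactly zero, predominant
    requires |dAF| >= threshold (inclusive) and af_other > 0.
    """
    if af_focal >= threshold and af_other < threshold:
        if af_other == 0.0:
            return "SPECIFIC"
        if abs(af_focal - af_other) >= threshold:
            return "PREDOMINANT"
    return "NONE"


def classify_pair(af_a: float, af_b: float, threshold: float = 0.5) -> str:
    """Category of one allele given its frequencies in populations A and B.

    Evaluates both focal populations (they are mutually exclusive for one
    allele) and returns one of ``CATEGORIES``.
    """
    cat = classify_allele(af_a, af_b, threshold)
    if cat != "NONE":
        return "A_" + cat
    cat = classify_allele(af_b, af_a, threshold)
    if cat != "NONE":
        return "B_" + cat
    return "NONE"


def classify_counts(
    alt_a: np.ndarray,
    tot_a: np.ndarray,
    alt_b: np.ndarray,
    tot_b: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised classification of the ALT and REF alleles from allele counts.

    Integer counts allow exact cutoff comparisons (e.g. dAF >= 0.5 becomes
    2*(alt_a*tot_b - alt_b*tot_a) >= tot_a*tot_b for threshold 0.5), which a
    float division would occasionally misjudge at the boundary.  Only
    threshold = 0.5 uses the exact integer path; other thresholds fall back to
    float comparisons.

    Returns
    -------
    (alt_categories, ref_categories) : arrays of category strings; sites with a
    zero denominator in either population get "NONE" for both alleles (they
    are excluded upstream).
    """
    alt_a = np.asarray(alt_a, dtype=np.int64)
    tot_a = np.asarray(tot_a, dtype=np.int64)
    alt_b = np.asarray(alt_b, dtype=np.int64)
    tot_b = np.asarray(tot_b, dtype=np.int64)
    usable = (tot_a > 0) & (tot_b > 0)

    def _cats(ca, cb):
        # ca, cb: counts of the evaluated allele in pops A and B
        if threshold == 0.5:
            ge_a = 2 * ca >= tot_a  # af_a >= 1/2
            lt_b = 2 * cb < tot_b  # af_b < 1/2
            ge_b = 2 * cb >= tot_b
            lt_a = 2 * ca < tot_a
            delta_ge = 2 * np.abs(ca * tot_b - cb * tot_a) >= tot_a * tot_b
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                fa = np.where(tot_a > 0, ca / np.maximum(tot_a, 1), np.nan)
                fb = np.where(tot_b > 0, cb / np.maximum(tot_b, 1), np.nan)
            ge_a, lt_b = fa >= threshold, fb < threshold
            ge_b, lt_a = fb >= threshold, fa < threshold
            delta_ge = np.abs(fa - fb) >= threshold
        zero_b = cb == 0
        zero_a = ca == 0
        out = np.full(ca.shape, "NONE", dtype="<U13")
        a_focal = usable & ge_a & lt_b
        out[a_focal & zero_b] = "A_SPECIFIC"
        out[a_focal & ~zero_b & delta_ge] = "A_PREDOMINANT"
        b_focal = usable & ge_b & lt_a
        out[b_focal & zero_a] = "B_SPECIFIC"
        out[b_focal & ~zero_a & delta_ge] = "B_PREDOMINANT"
        return out

    return _cats(alt_a, alt_b), _cats(tot_a - alt_a, tot_b - alt_b)


def classify_vcf(
    vcf_path,
    pop_a: PopulationSpec,
    pop_b: PopulationSpec,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify every biallelic SNP in a (filtered) VCF.

    Returns a DataFrame with one row per classified allele (category != NONE):
    columns chrom, pos, allele, category, af_a, af_b, delta_af, fixed.  Sites
    where either population has no called allele are skipped; their count is
    in ``df.attrs["n_excluded_no_calls"]`` and the total number of evaluated
    sites in ``df.attrs["n_sites"]``.
    """
    from .variant_io import read_sites  # local import to avoid cycle

    chroms: list[str] = []
    poss: list[int] = []
    counts: list[tuple[int, int, int, int]] = []
    n_excluded = 0
    samples = None
    idx_a = idx_b = None
    for site, hdr_samples in read_sites(vcf_path, with_samples=True):
        if samples is None:
            samples = hdr_samples
            idx_a = pop_a.indices_in(samples)
            idx_b = pop_b.indices_in(samples)
        g = site.genotypes
        ga, gb = g[idx_a], g[idx_b]
        ca = (ga >= 0).all(axis=1)
        cb = (gb >= 0).all(axis=1)
        tot_a, tot_b = 2 * int(ca.sum()), 2 * int(cb.sum())
        if tot_a == 0 or tot_b == 0:
            n_excluded += 1
            continue
        chroms.append(site.chrom)
        poss.append(site.pos)
        counts.append((int(ga[ca].sum()), tot_a, int(gb[cb].sum()), tot_b))

    if counts:
        arr = np.array(counts, dtype=np.int64)
        alt_a, tot_a, alt_b, tot_b = arr.T
    else:
        alt_a = tot_a = alt_b = tot_b = np.zeros(0, dtype=np.int64)
    cat_alt, cat_ref = classify_counts(alt_a, tot_a, alt_b, tot_b, threshold)

    rows = []
    for allele, cats, ca_arr, cb_arr in (
        ("ALT", cat_alt, alt_a, alt_b),
        ("REF", cat_ref, tot_a - alt_a, tot_b - alt_b),
    ):
        hit = np.nonzero(cats != "NONE")[0]
        for i in hit:
            fa = ca_arr[i] / tot_a[i]
            fb = cb_arr[i] / tot_b[i]
            focal = fa if cats[i].startswith("A_") else fb
            rows.append(
                (
                    chroms[i],
                    poss[i],
                    allele,
                    cats[i],
                    fa,
                    fb,
                    abs(fa - fb),
                    focal == 1.0,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "allele", "category", "af_a", "af_b", "delta_af", "fixed"],
    )
    df = df.sort_values(["chrom", "pos", "allele"]).reset_index(drop=True)
    df.attrs["n_sites"] = len(chroms)
    df.attrs["n_excluded_no_calls"] = n_excluded
    return df


def _bin_index(x: float) -> int:
    """Histogram bin index for x in [0.5, 1.0]; last bin is closed."""
    idx = int(math.floor(x * 10.0 + 1e-9)) - 5
    return min(max(idx, 0), 4)


def delta_af_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-category focal-AF and dAF histograms plus fixation counts.

    Bins are [0.5,0.6), [0.6,0.7), [0.7,0.8), [0.8,0.9), [0.9,1.0]; an allele
    at frequency exactly 1.0 falls in the top bin and is additionally counted
    as fixed.  Returns a tidy DataFrame with columns category, statistic
    ("focal_af" or "delta_af"), bin, count, plus one "fixed" row per category.
    """
    rows = []
    labels = [f"[{HIST_EDGES[i]:.1f},{HIST_EDGES[i+1]:.1f})" for i in range(4)]
    labels.append("[0.9,1.0]")
    for category, sub in classified.groupby("category", sort=True):
        focal = np.where(
            sub["category"].str.startswith("A_"), sub["af_a"], sub["af_b"]
        )
        for stat, values in (("focal_af", focal), ("delta_af", sub["delta_af"].to_numpy())):
            binned = np.zeros(5, dtype=int)
            for v in values:
                binned[_bin_index(float(v))] += 1
            for lab, c in zip(labels, binned):
                rows.append((category, stat, lab, int(c)))
        rows.append((category, "fixed", "af=1.0", int((focal == 1.0).sum())))
    return pd.DataFrame(rows, columns=["category", "statistic", "bin", "count"])
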