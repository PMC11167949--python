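"""Sliding-window FST / nucleotide-diversity selective-sweep scan.

Per-site Weir & Cockerham (1984) variance components (a, b, c) are computed
for the two populations from called genotype counts; the window statistic is
the "weighted" ratio-of-sums estimate sum(a) / sum(a+b+c), the convention of
VCFtools' windowed FST.  Nucleotide diversity is the per-bp average pairwise
difference, summed over variant sites as 2*c_ref*c_alt / (n*(n-1)) with n the
called allele count, and divided by the window length.  Windows are half-open
[start, start+window) anchored at 0 with a fixed step; trailing partial
windows are kept and normalised over their true length.

Candidate sweep regions are windows at or above the empirical top-quantile
thresholds of *both* FST and the diversity ratio pi_b/pi_a (elevated when
diversity is lost in population A); genes overlapping a candidate window by
at least 1 bp form the putatively-selected-gene (PSG) set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .popfreq import PopulationSpec
from .variant_io import read_sites

DEFAULT_WINDOW = 50_000
DEFAULT_STEP = 10_000


@dataclass(frozen=True)
class GenotypeCounts:
    """Called-genotype summary for one population at one site."""

    n: int  # called diploid individuals
    alt: int  # ALT allele count among called alleles
    het: int  # heterozygous individuals

    @property
    def p(self) -> float:
        return self.alt / (2 * self.n)

    @property
    def h(self) -> float:
        return self.het / self.n


def site_fst_components(counts_a: GenotypeCounts, counts_b: GenotypeCounts):
    """Weir & Cockerham (1984) two-population variance components (a, b, c).

    Requires at least one called diploid per population and more than one
    overall (n_bar > 1); returns None when the components are undefined.
    The per-site estimator is theta = a / (a + b + c).
    """
    n1, n2 = counts_a.n, counts_b.n
    if n1 < 1 or n2 < 1:
        return None
    nbar = (n1 + n2) / 2.0
    if nbar <= 1.0:
        return None
    nsum = n1 + n2
    nc = nsum - (n1 * n1 + n2 * n2) / nsum  # r - 1 = 1
    p1, p2 = counts_a.p, counts_b.p
    h1, h2 = counts_a.h, counts_b.h
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / nsum
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 / 2.0 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def weighted_fst(components: Iterable[tuple[float, float, float]]) -> float:
    """Ratio-of-sums window FST: sum(a) / sum(a+b+c); NaN when undefined."""
    sa = sabc = 0.0
    n = 0
    for a, b, c in components:
        sa += a
        sabc += a + b + c
        n += 1
    if n == 0 or sabc == 0.0:
        return float("nan")
    return sa / sabc


def site_pi_numerator(c_ref: int, c_alt: int) -> float:
    """Average pairwise difference at one site: 2*c_ref*c_alt / (n*(n-1))."""
    n = c_ref + c_alt
    if n < 2:
        return 0.0
    return 2.0 * c_ref * c_alt / (n * (n - 1))


@dataclass
class _SiteArrays:
    chrom: np.ndarray
    pos: np.ndarray
    n_a: np.ndarray
    alt_a: np.ndarray
    het_a: np.ndarray
    n_b: np.ndarray
    alt_b: np.ndarray
    het_b: np.ndarray


def _collect_site_arrays(vcf_path, pop_a: PopulationSpec, pop_b: PopulationSpec) -> _SiteArrays:
    rows = []
    chroms = []
    idx_a = idx_b = None
    for site, samples in read_sites(vcf_path, with_samples=True):
        if idx_a is None:
            idx_a = pop_a.indices_in(samples)
            idx_b = pop_b.indices_in(samples)
        g = site.genotypes
        out = []
        for idx in (idx_a, idx_b):
            gp = g[idx]
            called = (gp >= 0).all(axis=1)
            gc = gp[called]
            out += [len(gc), int(gc.sum()), int((gc[:, 0] != gc[:, 1]).sum())]
        rows.append([site.pos] + out)
        chroms.append(site.chrom)
    arr = np.array(rows, dtype=np.int64) if rows else np.zeros((0, 7), dtype=np.int64)
    return _SiteArrays(
        chrom=np.array(chroms, dtype=object),
        pos=arr[:, 0],
        n_a=arr[:, 1],
        alt_a=arr[:, 2],
        het_a=arr[:, 3],
        n_b=arr[:, 4],
        alt_b=arr[:, 5],
        het_b=arr[:, 6],
    )


def _site_components_vec(s: _SiteArrays):
    """Vectorised WC84 components; returns (a, b, c, usable mask)."""
    n1 = s.n_a.astype(float)
    n2 = s.n_b.astype(float)
    usable = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) / 2.0 > 1.0)
    n1s, n2s = np.maximum(n1, 1), np.maximum(n2, 1)
    nsum = n1s + n2s
    nbar = nsum / 2.0
    nc = nsum - (n1s**2 + n2s**2) / nsum
    p1 = s.alt_a / (2 * n1s)
    p2 = s.alt_b / (2 * n2s)
    h1 = s.het_a / n1s
    h2 = s.het_b / n2s
    pbar = (n1s * p1 + n2s * p2) / nsum
    s2 = (n1s * (p1 - pbar) ** 2 + n2s * (p2 - pbar) ** 2) / nbar
    hbar = (n1s * h1 + n2s * h2) / nsum
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    return a, b, c, usable


def window_starts(chrom_length: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP):
    """0-based window start coordinates tiling one chromosome."""
    return np.arange(0, chrom_length, step, dtype=np.int64)


def scan_windows(
    vcf_path,
    pop_a: PopulationSpec,
    pop_b: PopulationSpec,
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Windowed weighted FST and per-population pi over a whole VCF.

    Returns one row per window: chrom, start, end (half-open), n_sites, fst,
    pi_a, pi_b, pi_ratio (pi_b / pi_a, NaN when pi_a == 0 or the window is
    empty).  Every variant site contributes to each of the (up to
    ceil(window/step)) windows covering it.
    """
    s = _collect_site_arrays(vcf_path, pop_a, pop_b)
    a, b, c, usable = _site_components_vec(s)
    abc = a + b + c
    pi_num_a = np.array(
        [site_pi_numerator(int(t - x), int(x)) for t, x in zip(2 * s.n_a, s.alt_a)]
    )
    pi_num_b = np.array(
        [site_pi_numerator(int(t - x), int(x)) for t, x in zip(2 * s.n_b, s.alt_b)]
    )

    frames = []
    n_overlap = -(-window // step)  # ceil
    for chrom, length in chrom_lengths.items():
        starts = window_starts(length, window, step)
        ends = np.minimum(starts + window, length)
        nwin = len(starts)
        acc = {
            k: np.zeros(nwin)
            for k in ("sum_a", "sum_abc", "pi_a", "pi_b")
        }
        nsites = np.zeros(nwin, dtype=np.int64)
        on_chrom = s.chrom == chrom
        x = s.pos[on_chrom] - 1  # 0-based site coordinate
        ua = usable[on_chrom]
        ca, cabc = a[on_chrom], abc[on_chrom]
        pna, pnb = pi_num_a[on_chrom], pi_num_b[on_chrom]
        for j in range(n_overlap):
            k = x // step - j
            ok = (k >= 0) & (k < nwin) & (x - k * step < window)
            ki = k[ok]
            nsites += np.bincount(ki, minlength=nwin)
            np.add.at(acc["sum_a"], ki[ua[ok]], ca[ok][ua[ok]])
            np.add.at(acc["sum_abc"], ki[ua[ok]], cabc[ok][ua[ok]])
            np.add.at(acc["pi_a"], ki, pna[ok])
            np.add.at(acc["pi_b"], ki, pnb[ok])
        length_bp = (ends - starts).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(acc["sum_abc"] != 0.0, acc["sum_a"] / acc["sum_abc"], np.nan)
            pi_a = acc["pi_a"] / length_bp
            pi_b = acc["pi_b"] / length_bp
            pi_ratio = np.where(pi_a > 0.0, pi_b / pi_a, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_sites": nsites,
                    "fst": fst,
                    "pi_a": pi_a,
                    "pi_b": pi_b,
                    "pi_ratio": pi_ratio,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _nearest_rank_threshold(values: np.ndarray, quantile: float) -> float:
    """Threshold so that the top (1-quantile) share of m values are >= it.

    Nearest-rank convention: with k = m - floor(quantile * m) top windows,
    the threshold is the k-th largest value; ties at the threshold are kept
    by the >= comparison downstream.
    """
    v = np.sort(values)
    m = len(v)
    k = m - int(np.floor(quantile * m + 1e-9))
    k = max(k, 1)
    return float(v[m - k])


def select_top_windows(windows: pd.DataFrame, quantile: float = 0.95) -> pd.DataFrame:
    """Flag windows in the joint top (1-quantile) tail of FST and pi-ratio.

    Thresholds are empirical nearest-rank quantiles computed independently
    over windows with a non-missing value of each statistic; a window is a
    candidate iff it meets or exceeds both.  Adds boolean columns top_fst,
    top_ratio, candidate and stores the thresholds in ``df.attrs``.
    """
    out = windows.copy()
    fst_vals = out["fst"].dropna().to_numpy()
    ratio_vals = out["pi_ratio"].dropna().to_numpy()
    if min(len(fst_vals), len(ratio_vals)) < 20:
        warnings.warn("fewer than 20 usable windows: quantile thresholds unstable")
    thr_fst = _nearest_rank_threshold(fst_vals, quantile) if len(fst_vals) else np.nan
    thr_ratio = (
        _nearest_rank_threshold(ratio_vals, quantile) if len(ratio_vals) else np.nan
    )
    out["top_fst"] = out["fst"] >= thr_fst
    out["top_ratio"] = out["pi_ratio"] >= thr_ratio
    out["candidate"] = out["top_fst"] & out["top_ratio"]
    out.attrs["fst_threshold"] = thr_fst
    out.attrs["pi_ratio_threshold"] = thr_ratio
    return out


def windows_to_genes(candidates: pd.DataFrame, gene_spans: pd.DataFrame) -> list[str]:
    """Genes whose span overlaps any candidate window by >= 1 bp.

    ``gene_spans`` needs columns gene_id, chrom, start, end with 1-based
    inclusive gene coordinates (as in GFF3); windows are 0-based half-open.
    """
    hits: set[str] = set()
    cand = candidates[candidates["candidate"]] if "candidate" in candidates else candidates
    for chrom, sub in cand.groupby("chrom"):
        genes = gene_spans[gene_spans["chrom"] == chrom]
        if genes.empty or sub.empty:
            continue
        g0 = genes["start"].to_numpy() - 1  # 0-based inclusive start
        g1 = genes["end"].to_numpy()  # 0-based exclusive end
        for start, end in zip(sub["start"], sub["end"]):
            ov = (g0 < end) & (g1 > start)
            hits.update(genes["gene_id"].to_numpy()[ov])
    return sorted(hits)
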