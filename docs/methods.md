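# Methods

## Screen definition and rule conventions

The screen classifies one allele at one biallelic SNP from its frequencies in
two populations, computed over called alleles only (a sample with any missing
allele is excluded from the denominator once). Comparisons are taken
literally from the rule definitions: the focal-frequency cutoff is inclusive
(*p*<sub>focal</sub> ≥ 0.50), the other-population bound is strict
(*p*<sub>other</sub> < 0.50), ΔAF ≥ 0.50 is inclusive, and "absent in the
other population" is tested as an exact zero of the called-allele count, not
as a small float. In the pipeline path the comparisons are done on integer
allele counts (e.g. ΔAF ≥ ½ becomes 2·(c_A·n_B − c_B·n_A) ≥ n_A·n_B), which
avoids float boundary misjudgements such as 0.7 − 0.2 evaluating just below
0.5; the float API (`classify_pair`) exists for grid-style use.

Both REF and ALT alleles are evaluated for both focal populations
(orientation-free reading). A consequence worth knowing: the complement of
an A-specific or A-predominant allele generally satisfies the B-predominant
rule (its B frequency is ≥ 0.5 and the ΔAF is unchanged), so per-population
summaries count strongly divergent sites in both populations' lists. Within
one focal population a site contributes at most one allele, and specific /
predominant are disjoint by construction, so per-population totals decompose
exactly into specific + predominant.

Sites where either population has zero called alleles are excluded and
counted (`attrs["n_excluded_no_calls"]`).

### Quantitative-genetics cutoff

`threshold_frequency(d_over_a)` returns the root of a(2p − 1) + 2p(1 − p)d
= 0 in [0, 1] in closed form: exactly 0.5 for d = 0 and 1 − √2/2 ≈ 0.2929
for d = α. The latter is conventionally rounded to 0.30; the implementation
returns the exact root. The domain is restricted to 0 ≤ d/α ≤ 1 (no
overdominance), where the mean is monotone in p and the root unique.

## Filters

Hard-filter bounds (QD < 2.0, MQ < 40.0, FS > 60.0, QUAL < 30.0, MQRankSum <
−12.5, ReadPosRankSum < −8.0) fail a site only when the metric is present —
callers emit rank-sum metrics only when computable, so absence is not
evidence of failure. All bounds are strict: QD = 2.0 or FS = 60.0 exactly
pass. The cluster rule removes *every* member of any group of ≥ 2 SNPs
falling in a 5-consecutive-bp window (two SNPs ≤ 4 bp apart), matching
cluster-flagging semantics rather than keep-first. Cluster membership is
computed over all SNP records on a chromosome, before the other filters thin
the list; because removal can only shrink clusters, filtering is idempotent.
Missingness is per sample (half-calls count the sample as missing) with a
10% bound, and only biallelic SNPs survive; indels are skipped and counted
separately. Failures are accounted by first cause in a fixed order (the six
metric rules, then cluster, multiallelic, missingness), so per-cause counts
plus survivors always reconstruct the input total. The order affects only
the accounting, never the surviving set.

## FST, π and the window scan

Per-site Weir & Cockerham (1984) variance components (a, b, c) for two
populations use the allele frequency, sample size and observed heterozygote
share of each population's called genotypes; the window statistic is the
weighted (ratio-of-sums) estimate Σa / Σ(a + b + c), the convention of
VCFtools' windowed estimator. Negative per-window values are retained — they
carry information about the null spread and fall below any top-quantile
threshold anyway. Sites need ≥ 1 called diploid in each population (and an
overall mean sample size > 1) to contribute; π uses whatever calls exist per
population independently, adding 2·c_ref·c_alt/(n(n−1)) per site and
dividing by window length.

Windows are half-open [k·10000, k·10000 + 50000) anchored at zero;
final partial windows are kept and normalised over their true length (end
handling is not pinned down by the screen's description; keeping partial
windows avoids discarding chromosome ends). Thresholds for "top 5%" use the
nearest-rank order statistic computed independently for FST and the π-ratio
over windows with defined values: with m windows, the k = m − ⌊0.95·m⌋
largest values are the top set and the threshold is its smallest member;
ties at the threshold are included (≥), so with all-equal values every
window is a candidate. Windows with π_A = 0 have an undefined ratio and are
excluded from the ratio quantile. Fewer than 20 usable windows triggers an
instability warning. Genes overlap candidates on a ≥ 1 bp rule, with GFF3's
1-based inclusive gene coordinates converted to half-open at the module
boundary.

## Annotation

Gene models come from GFF3 (gene → mRNA/transcript → exon/CDS); a CDS
segment outside its transcript's exons raises a consistency error naming the
transcript. Queries extend gene spans by ±1000 bp (the common "-ud 1000"
convention). Effect precedence is total and fixed: stop_gained > missense >
synonymous > splice_region > 5'/3' UTR > intron > upstream/downstream;
intergenic applies exactly when no extended span covers the SNP. The splice
region is 1–8 bp into an intron (1–2 bp being the donor/acceptor
dinucleotides, reported under the same class) and the last 3 exonic bases at
an exon/intron junction; gene-terminal exon edges are not junctions. Coding
changes are computed on the coding strand (reverse complement for − strand)
from the longest-CDS transcript of each gene, giving one deterministic
answer when transcripts disagree; codon and amino-acid change are reported
for coding effects only. A SNP hitting several extended spans is annotated
to all genes (multi-assignment, as gene-total bookkeeping expects) with the
single highest-precedence effect across genes. A mutated stop codon is
reported as missense (no stop_lost class is distinguished); positions inside
genes lacking any CDS fall back to intron, a limitation that does not arise
with the generator's models, which always carry a CDS.

## Synthetic cohorts

The generator emulates the screened study's regime: 44 + 29 diploids,
~20,000 biallelic SNPs over 2 × 5 Mb by default, genotypes drawn under
Hardy–Weinberg within each population (binomial(2, p) per diploid — no LD,
no coalescent realism). Neutral sites share one frequency between
populations, drawn from a symmetric Beta(0.5, 0.5) (a U-shaped stand-in for
a folded frequency spectrum; the spectrum of non-divergent sites is
configurable because no empirical null is prescribed). Planted fractions
default to roughly the observed genome-wide shares (5% A-specific, 8%
A-predominant, 0.25% B-specific, 3.5% B-predominant). Specific sites draw
the focal frequency uniformly on [0.5, 1] with the other population at
exactly 0; predominant sites draw focal uniformly on [0.5, 1] and the other
frequency uniformly on (0, focal − 0.5], spanning each category's whole
definition region. Positions are spaced ≥ 7 bp so the cluster filter never
fires accidentally (a dedicated fixture generator plants clustered sites and
every other filter violation for filter tests). INFO metrics are written at
passing constants (QD=25, MQ=60, FS=1, QUAL=100) unless a failing fraction
is requested. Per-genotype missingness (default 2%, must stay below 10%) is
capped per site at ⌊0.10·n⌋ missing samples so the emitted VCF always
survives its own missingness filter, which makes the "emitted VCF passes its
own filters" invariant strict rather than probabilistic.

Two sampling modes: `binomial` (noise included) and `exact`, which draws
planted frequencies on the grid achievable with the fixed sample sizes and
constructs genotypes hitting those counts exactly — the classifier then
recovers every planted category, which pins down classifier correctness
independently of sampling noise. Because planting is uniform down to the
inclusive 0.50 boundaries, binomial sampling necessarily loses part of the
boundary-adjacent mass (a site with true focal AF or ΔAF at the cutoff falls
below it with probability ≈ ½); measured per-category recall at this sample
size is ~0.81, and this is a property of the study conditions, not of the
classifier (exact-mode recall is 100%).

The sweep footprint scales the target population's per-site heterozygosity
inside the region to `diversity_factor` × baseline (default 0.1) by solving
p′(1 − p′) = f·p(1 − p); the fixing allele is drawn with probability equal
to its frequency, emulating which allele the swept haplotype carries. This
both reduces π by the factor and elevates FST against the other population
(always pushing to the nearer boundary would reduce π without creating
divergence). Sweep-region sites are excluded from category planting so the
truth table's category ↔ frequency consistency holds everywhere; their
truth categories are recomputed from the post-sweep frequencies.

What passing synthetic tests do **not** show about real data: no linkage
disequilibrium or haplotype structure (so haplotype-based statistics are out
of scope), no allele-frequency correlation between populations beyond the
shared-baseline construction, no sequencing-error or depth model behind the
INFO metrics, and tiny idealised gene models. The benchmark validates rule
implementations and detection machinery, not population-genetic realism.

## Problem sizes and numerics

Tests and the benchmark script run the full pipeline at 2 chromosomes × 5 Mb
with ~20,000 sites (about 20 s end to end), with unit oracles at ≤ 10-site
windows; estimator-vs-oracle agreement is asserted at 1e−10, the
quantitative-genetics root at 1e−9 (closed form vs 80-step bisection), and
percentage cells at exact two-decimal half-up reproduction. Histogram bins
[0.5, 0.6) … [0.9, 1.0] are left-closed with the top bin closed (fixed
alleles land in the top bin and are counted separately); bin assignment adds
1e−9 before flooring so representable fractions like 3/5 fall in the bin
their exact value belongs to. All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical configurations produce
byte-identical outputs.
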