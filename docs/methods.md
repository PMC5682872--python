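# Methods

## Design and model

The package analyses a replicate-free two-strain × two-condition
RNA-Seq design: one sequencing library each for `WT_ctrl`, `WT_Cd`,
`pmk1_ctrl` and `pmk1_Cd`. Because each condition is represented by a
single library, differential expression is assessed with the exact
Poisson library-pair test rather than a dispersion-estimating GLM:
conditioned on a gene's count *x* in the first library, the count *y*
in the second follows the negative-binomial law

p(k | x) = f^k (x+k)! / (x! k! (1+f)^(x+k+1)),  f = N₂/N₁,

which assumes (i) counts are Poisson around a per-gene rate, (ii) the
rate per mapped read is equal in both libraries under the null, and
(iii) library sizes N₁, N₂ are known constants. The model has no
between-replicate variance component; biological variability beyond
Poisson noise (overdispersion) makes the test anti-conservative, which
the simulator can demonstrate via its negative-binomial option.

Tails are evaluated in closed form: with q = N₁/(N₁+N₂), the lower
tail Σ_{k≤y} p(k|x) equals the regularized incomplete beta function
I_q(x+1, y+1); the upper tail is 1 − lower + p(y|x). The two-sided
p-value is min(1, 2·min(lower, upper)), the observed point counted in
both tails so up- and downregulation are treated symmetrically. This
evaluation is exact to ~1e-14 against direct extended-precision term
summation on the grid x, y ≤ 200 (tested).

One caveat is worth recording: the test conditions on the first
library's count, and that conditioning is not label-symmetric. With
equal library sizes, p(x=3, y=7) = 0.34375 while p(x=7, y=3) =
0.2265625. The package always conditions on the contrast's numerator
library, so results are well-defined and reproducible; the exact
identity that does hold pointwise, N₂·p(y|x; N₁,N₂) = N₁·p(x|y; N₂,N₁),
is asserted in the tests.

Multiple testing is controlled per contrast (not globally) with
Benjamini–Hochberg; a gene is a DEG when q < `fdr_threshold`. No
expression floor or fold-change filter is applied by default — FDR is
the only criterion — though a fold-change floor is available.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `fdr_threshold` | 0.005 | probability | DEG call threshold of the analysis |
| `kog_alpha` | 0.001 | probability | category-deviation significance (0.05 selectable) |
| `strong_log2fc_cutoff` | 2 | log₂ units | "strong" response magnitude (4-fold) |
| `strong_diff_cutoff` | 1 | log₂ units | required WT-vs-mutant separation (2-fold) |
| `rpkm_pseudocount` | 0.1 | RPKM | stabilises fold changes of near-zero genes; never enters the test |
| `upstream_window_bp` / `downstream_window_bp` | 2000 | bp | motif windows around codons; 4000 bp default for the upstream-only scan |
| `change_metric` | `rpkm_difference` | — | signed linear change; `log2_fold_change` selectable |

The pseudocount is added to both sides of the RPKM ratio only, so it
never changes the sign of a fold change when both RPKMs are positive,
and the significance test sees raw counts.

## Fold-change summaries

Mean log₂ fold changes per direction are computed on the antilog
scale: the arithmetic mean of the linear fold changes of up-DEGs (or
of the inverse fold changes of down-DEGs) is taken first and then
log₂-transformed. Ratios (up/down counts, |mean up|/|mean down|) are
reported as undefined markers, never infinities, when a denominator is
empty. Genes with zero counts in both libraries carry no signal and
are excluded from summaries.

## KOG category deviation

DEGs carrying a KOG letter are tallied per category and direction; a
category's (up, down) split is tested against the contrast-wide
proportions of all KOG-identified DEGs with a 1-df chi-square
goodness-of-fit statistic, no continuity correction. The reference
ratio includes the category itself, which is why this is a
goodness-of-fit test against fixed proportions rather than a 2×2
contingency test; for categories that are small relative to the
totals the two coincide closely. Expectations below 5 set a low-count
flag; a one-sided background (U = 0 or D = 0) marks the row
untestable. Multi-letter KOG codes count a gene once per letter (a
strict single-letter mode is available), and the tally totals U and D
use the same convention so column sums remain exact.

## Target-set analysis

The alignment universe is the union of DEGs from the two stress
contrasts. Overlap genes are assigned a signed expression change per
strain — by default the linear RPKM difference (stressed minus
control), since the analysis operates on absolute changes and only
displays them logarithmically; log₂ fold change is selectable and the
choice is recorded in output metadata. The overlap splits into group A
(change larger in WT), group C (larger in the mutant) and exact ties,
which are excluded from both groups under the strict inequalities.

Two Mann–Whitney comparisons follow: "levels" (WT changes over A vs.
mutant changes over C) and "deltas" (the positive between-strain
differences of A vs. those of C, positive by construction of the
split). The rank test is exact by full enumeration of rank assignments
when both samples have ≤ 8 observations and the pooled data are
tie-free. The asymptotic path uses the normal approximation refined by
the symmetric Edgeworth fourth-cumulant term (excess kurtosis
γ₂ = −(6/5)(m²+n²+mn+m+n)/(mn(m+n+1)); skewness is zero), with a
half-count continuity correction per tail and clamping of the expansion
into [0, 1] in the far tails. The plain continuity-corrected normal
approximation errs by up to 0.011 against the exact two-sided p at the
8-vs-8 switchover; the Edgeworth refinement reduces that worst case to
below 6e-4, keeping the exact/asymptotic seam invisible at the stated
0.01 level. With ties present, the standard tie-corrected normal
approximation is used instead.

## Motif scanning

Matching is exact degenerate-consensus (fuzznuc-style): an IUPAC
pattern position accepts exactly its expansion letters; a hard-masked
sequence `N` is accepted only by pattern letter N; soft-masked bases
are uppercased first. Overlapping matches are all reported.
Minus-strand sites are found by scanning the forward sequence for the
reverse complement of the pattern; a palindromic pattern reports each
interval once.

Windows are codon-anchored in gene orientation: `upstream` is the
fixed-length window 5′ of the first base of the start codon,
`intragenic` runs from start codon through stop codon inclusive
(introns included; a gene-span mode exists), `downstream` is the
fixed-length window 3′ of the stop codon. Minus-strand genes are
handled by reverse complementation, so "upstream" is always 5′. Each
extracted window is scanned independently; a site straddling a window
boundary is therefore counted in no window, matching the behaviour of
scanning extracted regions with a pattern searcher. Windows running
off a contig are clipped with a warning. In the pooled count table,
DBE and DAE counts form a single DAF-16 column group; the upstream-only
promoter scan (default 4 kb) keeps them separate and resolves strands.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, at the study's own scale by default: 20 000 genes, four
libraries of 10⁷ mapped reads, log-normal baseline expression (median
10 RPKM, log-sd 1.5) and transcript lengths (median 1.5 kb), a fifth
of genes cadmium-responsive with 70 % upregulated (planted |log₂FC|
centred on 3), and 60 % of responders biased toward the wild type by
1.5 log₂ units — numbers chosen to mirror the observed DEG counts,
up/down ratios and strain asymmetry of the real design. Counts are
Poisson around RPKM-implied means (negative binomial with variance
m + d·m² when overdispersion d > 0, to probe the test's failure mode).
Target sets draw a configurable fraction of members from the WT-biased
responder pool. Because the planted fold changes are asymmetric, the
simulated column sums differ from the true depths; bundles therefore
carry the configured library sizes in an explicit override row so that
re-reading a bundle does not import composition bias.

The genome builder places a configurable subset of genes (default 300,
on 3 contigs) in blocks of upstream window + intragenic span +
downstream window with spacers; random background DNA is then
sanitised: every spontaneous occurrence of a configured motif is
destroyed by single-base edits restricted to non-planted positions,
instances are planted at recorded positions/strands/windows with a
minimum 3-bp background gap (which guarantees every spurious junction
match retains an editable base), and a final re-scan must reproduce
the planted match set exactly or generation fails. Edit order is
deterministic, so bundles are byte-identical across processes for a
given seed. One seed drives all sub-generators through spawned child
streams.

What the simulator does *not* emulate: biological replicate variance,
GC/length biases, mapping ambiguity, isoform structure, intron/UTR
architecture (genes are contiguous codon-to-codon blocks), realistic
motif clustering, or correlated gene programs. Passing tests therefore
demonstrate correctness of the statistical machinery on data satisfying
the model's assumptions, not robustness to violations of them — except
where the overdispersion option deliberately violates the Poisson
assumption.

## Numerical and design choices

* Count-test tails via `scipy.special.betainc` (log-space pmf via
  `gammaln`); no term summation anywhere in the analysis path, so
  accuracy is uniform in the counts.
* BH adjustment delegates to `statsmodels`; chi-square tails to
  `scipy.stats.chi2.sf`.
* Coordinates are 0-based half-open internally, BED on disk; 1-based
  inclusive input accepted behind an explicit reader flag.
* Replicate columns, if a user has them, are pooled by summation
  (`CountTable.merge_replicates`) before testing, since the pair test
  is defined for one library per side.
* The pipeline recomputes every stage on each run rather than caching
  by digest — at this scale a full run takes seconds, and the manifest
  still records SHA-256 digests of all inputs and outputs for
  provenance and byte-identity checks. Report determinism excludes
  only the manifest's timestamps.
* Acceptance-style checks run at desk scale (e.g. 20 000-gene null
  calibration, 2 000-gene planted recovery, 300-gene genome truth),
  sizes chosen so the full suite completes in well under a minute
  while keeping Monte-Carlo error far below the asserted tolerances.

## Known limitations

* No replicate-aware dispersion modelling; the exact pair test is
  anti-conservative under biological overdispersion.
* Transcript length is a single per-gene number; isoform choice is the
  data preparer's responsibility.
* Whether a promoter scan should treat near-consensus ("degenerate")
  motif variants as matches is format-dependent; the scanner matches
  the exact degenerate consensus only.
* The KOG deviation test treats genes as independent observations;
  co-regulated gene families inflate the statistic.
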