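# stressdeg

Count-based differential expression and regulatory-motif analysis for
paired-library stress RNA-Seq designs, built around the *C. elegans*
cadmium-stress setting: a wild-type strain and a *pmk-1* (p38 MAPK)
knockout, each sequenced once under control conditions and once under
acute CdCl₂ stress.

It is aimed at researchers who have gene-level read counts from a
replicate-free two-strain × two-condition design and want the classic
exact-test analysis stack for it: per-contrast differentially expressed
genes (DEGs), functional-category enrichment, regulator-target overlap
statistics, and transcription-factor binding-motif counts around genes —
plus a fully seeded synthetic-data generator so every stage can be
validated against planted ground truth without any external downloads.

## The statistical core

**Expression units.** Reads per kilobase of transcript per million
mapped reads,

```
RPKM = x / ((L / 10^3) · (N / 10^6))
```

for count *x*, transcript length *L* (bp) and library size *N*.

**Differential expression** between two single libraries uses the exact
Poisson library-pair test (Audic–Claverie). Conditioned on a gene's
count *x* in library 1, the count in library 2 follows

```
p(k | x) = f^k (x + k)! / ( x! k! (1 + f)^(x + k + 1) ),    f = N₂/N₁ ,
```

a negative-binomial law whose tails the package evaluates in closed form
through the regularized incomplete beta function:
`lower = I_q(x+1, y+1)` with `q = N₁/(N₁+N₂)`. The two-sided p-value is
`min(1, 2·min(lower, upper))` with the observed count included in both
tails. Per contrast, p-values are converted to q-values with the
Benjamini–Hochberg step-up procedure and genes with **q < 0.005** are
called DEGs.

Four canonical contrasts cover the design: two stress-specific
(`WT_Cd vs WT_ctrl`, `pmk1_Cd vs pmk1_ctrl`; "up" = higher under
cadmium) and two strain-specific (`WT_ctrl vs pmk1_ctrl`,
`WT_Cd vs pmk1_Cd`; "up" = higher in the wild type).

**Downstream analyses.**

* *Contrast summaries* — up/down DEG counts, their ratio R, and mean
  log₂ fold changes computed on the antilog scale (linear fold changes
  averaged, then log₂-transformed).
* *Strong DEGs* — DEGs with |log₂FC| > 2 in a stress contrast whose
  WT and mutant log₂ fold changes differ by more than 1.
* *KOG enrichment* — DEGs carrying one of the 25 KOG functional-category
  letters are tallied per category and direction; each category's
  up/down split is tested against the contrast-wide split with a 1-df
  chi-square goodness-of-fit test (χ² = Σ(obs−exp)²/exp).
* *Target-set analysis* — stress DEGs are intersected with published
  regulator target lists (SKN-1, DAF-16 class I/II, chaperones, ABC
  transporters), split by which strain shows the larger signed
  expression change (RPKM difference by default), and the groups are
  compared with Mann–Whitney rank-sum tests (exact by enumeration for
  small tie-free samples; Edgeworth-refined normal approximation
  otherwise).
* *Motif scanning* — fuzznuc-style exact IUPAC degenerate-consensus
  matching of the SKN-1 site `RTCAT`, the DAF-16 binding element
  `TRTTTAC` (DBE) and the DAF-16 associated element `CTTATCA` (DAE) on
  both strands of three codon-anchored windows per gene: 2 kb upstream
  of the start codon, the start-through-stop intragenic span, and 2 kb
  downstream of the stop codon.

## Worked example

Simulate a seeded bundle (counts, annotation, target sets, genome with
planted motifs, ground truth) and run the full analysis:

```python
from stressdeg.simulate import (SimulationConfig, GenomeSpec,
                                TargetSetSpec, simulate_bundle)
from stressdeg.io import AnalysisConfig
from stressdeg.pipeline import run_all

cfg = SimulationConfig(
    n_genes=2000, genome=GenomeSpec(n_genes=30),
    target_set_specs=(TargetSetSpec("SKN1_targets", 150, 0.7),
                      TargetSetSpec("DAF16_targets", 180, 0.6, ("I", "II"))),
    rng_seed=1,
)
paths = simulate_bundle(cfg, "demo/bundle")
run_all(AnalysisConfig(rng_seed=1), paths["counts"], paths["annotation"],
        "demo/out", paths["genome"], paths["genes_bed"], paths["sets_dir"])
print(open("demo/out/report.txt").read())
```

prints

```
stressdeg 0.1.0 analysis report

contrast WT_Cd_vs_WT_ctrl: 299 up / 97 down DEGs, R = 3.082
contrast pmk1_Cd_vs_pmk1_ctrl: 262 up / 95 down DEGs, R = 2.758
contrast WT_ctrl_vs_pmk1_ctrl: 0 up / 0 down DEGs
contrast WT_Cd_vs_pmk1_Cd: 195 up / 161 down DEGs, R = 1.211
strong DEGs (stress contrasts): 338
KOG WT_Cd_vs_WT_ctrl: U=204 D=56, 0 deviating categories at alpha=0.001
...
target set DAF16_targets: overlap 111 (A=83, C=27, ties=1), levels p=0
target set SKN1_targets: overlap 112 (A=85, C=26, ties=1), levels p=0
motif counts: 30 genes, SKN-1 total 142, DAF-16 total 151
```

Reading the output: about a fifth of the simulated genes respond to
cadmium with upregulation dominating (R ≈ 3 in the wild-type stress
contrast), the control-vs-control strain contrast is null as planted,
and the target sets — enriched for genes with WT-biased responses —
split asymmetrically (group A ≫ group C) with rank-test p-values that
underflow at this separation. `demo/out/` also holds the per-gene
contrast tables, the KOG tables, per-set target tables and the motif
count table as TSV, plus `manifest.json` with SHA-256 digests of every
input and output.

The same stages are available as subcommands of the `stressdeg`
command-line tool (`simulate`, `deg`, `kog`, `targets`, `motifs`,
`report`).

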