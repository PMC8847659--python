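# ubistrat

Analysis toolkit for a two-gene **SKP2-ubiquitination signature** in breast
cancer, built around discrete copy-number (CN) calls.

SKP2 is the substrate-recognition subunit of the SCF E3 ubiquitin ligase and
an oncoprotein: it marks the CDK inhibitors p27/p21 for degradation. SKP2 is
itself ubiquitinated by APC/C^FZR1 and deubiquitinated by USP10/USP13. The
signature compares the cBioPortal-style CN level (−2 … 2) of **FZR1** with
that of a deubiquitinase (**USP10** by default):

| group        | rule             | expected SKP2 | expected p27 |
|--------------|------------------|---------------|--------------|
| high         | FZR1 > USP10     | low           | high         |
| intermediate | FZR1 = USP10     | intermediate  | intermediate |
| low          | FZR1 < USP10     | high          | low          |

The package implements, from first principles where the statistic is the
point of the analysis:

* **stratify** — CN and expression-median signature classifiers, IHC subtype
  assignment (luminal = ER+; HER2 = HER2+/ER−/PR−; TNBC = triple negative);
* **proxy validation** — one-way ANOVA / t tests on p27, an empirical-Bayes
  moderated-t differential-expression stage (method-of-moments prior on the
  per-gene variances), Benjamini–Hochberg FDR, and the Spearman concordance
  between the signature's high/low LFC vector and the SKP2-CN LFC vector;
* **clinical association** — Kaplan–Meier curves, k-group log-rank test,
  chi-square tests against stage/grade, and a negative-binomial (NB2) GLM
  for positive-lymph-node counts (IRLS for β alternating with Newton ML for
  the dispersion θ, Wald z tests);
* **drug repurposing** — bidirectional Kolmogorov–Smirnov connectivity
  scores of ranked perturbation profiles against an up/down query signature,
  permutation p-values, and ln-IC50 ANOVA/t comparisons;
* **synthetic cohorts** — a generator that emulates the statistical
  structure of public breast-cancer cohorts (CN marginals, subtype mixture,
  group-dependent p27/survival/stage/grade effects, NB node counts, a
  latent SKP2-driven expression factor, planted reversing drugs) so the
  whole pipeline is testable without any download.

## Worked example

```sh
ubistrat simulate --seed 4 --out sim
ubistrat stratify --cohort sim/cohort.tsv --out stratified.tsv
ubistrat run --cohort sim/cohort.tsv --expr sim/expression.tsv --seed 4 --out results
```

`results/survival_bygroup.tsv` from that run contains

```
subtype	n	chi2	df	p	note
aggregate	963	21.69337883749732	1	3.1989351012999875e-06
luminal	721	25.451016384894302	1	4.5375853339163297e-07
HER2	67	3.6763085636102137	1	0.05519091466638419
TNBC	163	0.03235647550333169	1	0.8572475163246498
other	12	0.2464199448019324	1	0.6196072623446176
```

read: among luminal patients classified high vs low, overall survival
differs (log-rank χ² ≈ 25.5, p ≈ 4.5 × 10⁻⁷ — the generator plants a
low-vs-high hazard ratio of 1.8 in luminal patients only), while the HER2
and TNBC strata show no signal, as designed. `nodes_nbfit.tsv` likewise
shows positive intermediate/low coefficients against the high-group
baseline in the luminal stratum, and `concordance.tsv` a positive Spearman
ρ between the two SKP2 differential-expression contrasts.

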