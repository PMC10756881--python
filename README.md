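# antwound

Quantitative analysis pipeline for wound-care experiments in ants —
built around the finding that *Megaponera analis* workers diagnose
infected wounds and treat them with antimicrobial metapleural-gland (MG)
secretions. The package is aimed at researchers who want to re-run or
adapt the study's statistical machinery on their own tabular data (qPCR
Cq tables, ASV count tables, survival tables, behavioral event logs,
OD600 plate readings, iBAQ protein tables, CHC profiles), and at
methodologists who want a tested, seedable reference implementation of
each step. It starts downstream of read processing and spectral search:
every input is a plain TSV/CSV.

## What it computes

- **qPCR bacterial load** — relative load ΔCq = 2^(Cq_host − Cq_target)
  normalized to the host 28S gene; absolute 16S copies
  n = E^(intercept − Cq) with the amplification efficiency
  E = 10^(−1/slope) estimated from a serial-dilution standard curve
  (default intercept 38.23; per-primer efficiencies 1.86 / 2.00 / 1.87);
  pairwise fold-change contrasts with Welch tests and Holm–Bonferroni
  correction.
- **Microbiome** — prevalence filtering (≥1% relative abundance in ≥5
  samples), absolute-abundance scaling (ASV proportion × total 16S
  copies), genus aggregation, per-genus two-sided permutation t-tests
  (10,000 permutations, Holm within timepoint), and one-factor PERMANOVA
  (pseudo-F, R²) on Bray–Curtis dissimilarities.
- **Survival** — Kaplan–Meier product-limit curves over the 36-h
  observation window, 36-h cumulative mortality, and pairwise hazard
  contrasts from colony-stratified Cox proportional-hazards fits (Wald z,
  Holm across pairs).
- **Behavior** — 24-h care-event logs binned into 144 ten-minute
  intervals; per-group care probability fitted by a penalized cubic
  B-spline logistic smoother (GCV-selected λ, pointwise 95% Wald bands on
  the link scale); detection of intervals where infected ants receive
  significantly more care; the MG-care fraction (43/411 → 10.5%) and the
  Welch contrast of care-bout durations (85 ± 53 s vs 53 ± 36 s).
- **Growth inhibition** — logistic fits
  N(t) = K / (1 + ((K − N0)/N0) e^(−rt)) of OD600 curves, and percent
  reduction of the intrinsic growth rate r with a Mann–Whitney U test.
- **Secretome** — the compartment-enrichment filter cascade on iBAQ
  tables: atrium presence → atrium-only hits → ≥1.5-fold
  atrium-vs-hemolymph enrichment; percent-of-total-iBAQ abundances.
- **CHC profiles** — compound-class fractions (alkanes, alkenes,
  alkadienes, methyl-branched), profile-level PERMANOVA, per-class
  ANOVA + Tukey contrasts.
- **Synthetic data** — seeded generators (`antwound.synthgen`) producing
  every input type with the study's designs and printed effect sizes as
  defaults, so the full pipeline runs with no downloads.

## Worked example

`examples/` holds one narrative script per capability. Running the whole
pipeline on synthetic inputs:

```bash
antwound all --seed 7 --out run/
cat run/summary.md
```

prints (seed 7):

```
- qPCR: infected/sterile load ratio at 11 h = 99.7x
- Microbiome PERMANOVA (treatment): F = 49.37, R2 = 0.57, p = 0.001
- 36-h mortality [infected_isolation]: 91.7%
- 36-h mortality [infected_nest]: 16.7%
- MG care fraction: 8/90 = 8.9%
- Care durations: MG 89±38 s vs plain 52±32 s (p = 0.0313)
- Elevated-care intervals (infected > sterile): 10.0-12.2 h
- Growth inhibition by MG secretion: 29.6% (Mann-Whitney U = 54, p = 0.0004)
- Secretome hits: 19 (8 atrium-only, 11 enriched)
- CHC PERMANOVA at late timepoint: F = 4.79, R2 = 0.18, p = 0.001
```

Reading it: infected wounds carry ~100× the bacterial load of sterile
wounds by 11 h and the treatment explains 57% of community-level
dissimilarity; untreated infected ants mostly die within 36 h while
nestmate care keeps mortality low; care is concentrated on infected
individuals around hours 10–12; MG secretions cut the pathogen's
intrinsic growth rate by ~30%; and the compartment filter recovers the
planted set of gland-secreted proteins. Per-group and per-genus tables
are written next to `summary.md`, with a `manifest.json` hashing every
output (reruns with the same seed are byte-identical).

Each stage is also importable directly — see `examples/*.py` — and
runnable standalone on its TSV inputs via the `antwound` subcommands
(`simulate`, `qpcr`, `survival`, `all`).

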