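# ceprobe

Automated processing of RNA chemical probing data resolved by capillary
electrophoresis (CE): exclusion of reverse-transcriptase strong-stop
artifacts, box-plot normalization of SHAPE/DMS reactivities onto the
standard uniform scale, replicate averaging, statistical comparison of
experiments, visualization, and output compatible with reactivity-driven
RNA secondary structure prediction.

## Who this is for

SHAPE and DMS probing read out RNA structure: a flexibility- or
pairing-sensitive reagent modifies accessible nucleotides, reverse
transcription stops at the adducts, and CE quantifies the resulting cDNA
fragments as per-nucleotide peak areas (a treated "reaction" channel and an
untreated "background" channel, typically processed upstream by ShapeFinder
or QuShape). Before those reactivities can constrain a folding algorithm,
two quality-control steps are needed: removing *RT strong-stops* —
premature terminations not caused by an adduct (e.g. pre-existing cleavage)
— and normalizing the background-subtracted signal to a scale comparable
across RNAs. Both are traditionally done by hand; `ceprobe` automates them
and adds replicate averaging, statistics and plots.

## The method

**Strong-stop exclusion.** With `mean_bg` the average background peak area
of the experiment (computed once, over all non-missing positions), position
*i* is excluded when the first of these fires:

1. reactivity(*i*) < 0;
2. bg(*i*) ≥ 5 · mean_bg;
3. rx(*i*) − bg(*i*) < 0.35 · mean_bg **and** bg(*i*) ≥ mean_bg.

A manual mode instead takes user-selected positions plus a negative-value
policy (keep / set to 0 / mark as no data) with a configurable threshold.

**Box-plot normalization.** Over the included reactivities *V* (n = |V|):
Q1, Q3 are the quartiles (linear interpolation), UP = Q3 + 1.5·IQR; values
above UP are outliers, capped at 10 % of n (n > 100) or 5 % (n ≤ 100); the
*effective maximum* is the mean of the top 8 % of non-outlier values; every
included value is divided by it. Normalized values near 0 indicate
constrained nucleotides; ≥ 0.85 flexible ones (bar plots use
black/orange/red bins at 0.4 and 0.85).

**Replicates and statistics.** 1–15 replicates are averaged per nucleotide
(mean ± sample SD, missing skipped). For 2–5 experiments, a Shapiro-Wilk
test per sample and a Bartlett test across samples run first; if any sample
departs from normality, a two-sided Mann-Whitney (2 experiments) or
Kruskal-Wallis (3–5) location test follows.

## Worked example

Simulate three replicates of a 120-nt experiment with three planted
strong-stops (one per kind), then run the full pipeline:

```
$ ceprobe simulate --length 120 --seed 7 --stops 12:neg,40:highbg,77:lowdiff \
      --replicates 3 --outdir sim
wrote 3 replicate(s), 3 planted stop(s), seed 7

$ ceprobe run sim/synthetic_seed7_rep*.txt --outdir out
wrote results for 3 replicate(s) to out
```

`out/synthetic_seed7_rep0.exclusions.tsv` shows each planted artifact was
caught, with the criterion and triggering values:

```
position  reason               reactivity  bg_area  rx_area  mean_bg
12        NEGATIVE_REACTIVITY  -21.048     72.279   51.231   90.233
40        HIGH_BACKGROUND      45.576      601.769  647.345  90.233
77        LOW_DIFFERENCE       18.155      119.609  137.764  90.233
```

(position 40's background is 601.8 ≈ 6.7 × the 90.2 average, criterion 2;
position 77's difference 18.2 < 0.35 × 90.2 = 31.6 with an above-average
background, criterion 3). `out/averaged.shape` is the two-column restraint
file of averaged normalized reactivities, `-999` marking excluded data:

```
1       0.465
2       0.259
3       1.060
...
12      -999
```

Comparing two replicates statistically:

```
$ ceprobe compare out/synthetic_seed7_rep0.shape out/synthetic_seed7_rep1.shape --outdir cmp
Statistical comparison of 2 experiments (alpha = 0.05)

Normality (Shapiro-Wilk):
  synthetic_seed7_rep0: p = 6.508707679669099e-06 -> departs from normal
  synthetic_seed7_rep1: p = 7.818661428207496e-06 -> departs from normal

Variance homogeneity (Bartlett): p = 0.9629033428074494 -> equal variances

Location test: Mann-Whitney U test (two-sided), p = 0.9545637102105118
```

Reactivity profiles are right-skewed (most nucleotides unreactive), so the
nonparametric branch runs; the high Mann-Whitney p-value confirms the two
replicates share one reactivity distribution. The same commands also write
the XLSX report (raw / normalized / averaged sheets with color-tagged
values) and the bar, step, comparative-step, box and violin plots (PNG or
EPS). With an RNAstructure installation, `ceprobe fold` feeds the `.shape`
restraints to its `Fold` executable and returns the dot-bracket structure.

Everything is also available as a library — see `ceprobe.strongstop`,
`ceprobe.normalize`, `ceprobe.replicates`, `ceprobe.stats_compare`,
`ceprobe.viz`, `ceprobe.structure_adapter` and the deterministic generator
`ceprobe.synthetic`.

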