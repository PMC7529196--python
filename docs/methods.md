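# Methods

This note records the model behind `ceprobe`, the conventions and numerical
choices that had to be fixed where the field's informal descriptions leave
latitude, and what the synthetic-data generator does and does not emulate.

## Data model

The pipeline starts at the peak-area table produced by an
electropherogram-analysis tool (ShapeFinder or QuShape): per nucleotide, a
reaction-channel peak area `rx`, a background-channel peak area `bg` (both
arbitrary fluorescence units) and an absolute reactivity. When the table
carries no reactivity column, reactivity is taken as `rx − bg`, signed so
that adduct signal above background is positive. Coordinates are 1-based
and never re-indexed. Records with unparseable numeric fields are kept and
flagged missing rather than dropped, so row counts are preserved end to
end; missing data propagate as the `-999` no-data code in `.shape` output.

Sequence validation, when a sequence is supplied, checks that it is RNA
(DNA `T` accepted and converted) and at least as long as the highest probed
position. Base identity against the table's base column is reported as a
warning, not an error: CE tables routinely carry sequencing-ladder offsets,
and the length check is the contract that downstream folding needs.

## Strong-stop exclusion

The automated classifier evaluates, in fixed order, (1) negative
reactivity, (2) background at least five times the experiment-average
background, (3) reaction-minus-background difference below 35 % of that
average while the background is at or above it. Choices pinned here:

* `mean_bg` is computed **once**, over all non-missing positions,
  including positions later excluded. A single pass matches the use of one
  experiment-wide average; no iteration or re-estimation is performed.
* "At least five times" is inclusive (`bg ≥ 5·mean_bg`); the ten-record
  example with backgrounds (1×9, 9) — mean 1.8, threshold exactly 9.0 —
  pins this boundary in the tests.
* The first matching criterion is recorded as the reason; the excluded
  *set* is order-independent (a union), the reason labels are not.
* Negative-reactivity positions are excluded outright in automated mode
  (threshold exactly 0), becoming missing downstream.

All three criteria are sign tests or ratios against `mean_bg`, so the
classification is invariant under any positive rescaling of the
fluorescence units — a property the tests exercise directly.

The manual mode excludes user-selected positions (reason `MANUAL`) and
applies one of three treatments to reactivities below a user threshold:
keep (they then participate in normalization, including quartiles), zero,
or no-data (excluded). Detector quality against an expert reference is
summarized by the usual binary-classification rates (ACC, PPV, TPR, TNR)
with reliable positions as the positive class; rates with a zero
denominator are reported as not-applicable, never 0, and are additionally
rendered at 2 decimals for display.

## Box-plot normalization

Over the n included reactivities: Q1/Q3 by linear interpolation between
order statistics (quantile "type 7", the numpy default — the convention had
to be fixed for reproducibility and is pinned by the 1..100 example, Q1 =
25.75, Q3 = 75.25, effective max 96.5). UP = Q3 + 1.5·IQR; values above UP
are outlier candidates, capped at `floor(0.10·n)` when n > 100 and
`floor(0.05·n)` otherwise. Interpretation choices:

* The "longer than 100 nucleotides" rule is applied to the included data
  count, not the declared RNA length, since normalization operates on the
  data vector; n = 100 falls in the 5 % branch ("longer than" read as
  strict).
* When candidates exceed the cap, the largest values win (ties broken by
  value, then lower position) — removing the most extreme values best
  matches the meaning of "outlier".
* The effective maximum is the mean of the top `ceil(0.08·m)` non-outlier
  values (m non-outliers), minimum 1 value so small datasets remain
  normalizable.
* Outliers are excluded only from the effective-maximum computation; they
  are divided by it and retained in the output, flagged in the
  diagnostics. A 99×1.0 + 1000.0 dataset therefore yields the outlier at
  normalized value 1000, not a dropped position.
* At least 10 reliable values are required; a non-positive effective
  maximum (e.g. an all-zero profile) is an error rather than a silent
  division.

Normalization is scale-equivariant: quartiles, UP and the effective
maximum all scale linearly, so normalized profiles are invariant under
changes of fluorescence units. After normalization the mean of the top-8 %
non-outlier values is exactly 1 by construction.

Color bins are half-open — [0, 0.4) / [0.4, 0.85) / [0.85, ∞), rendered
black/orange/red by default — and negative values surviving a manual keep
policy fall in the low bin. An optional DMS filter restricts normalization
to A/C positions (DMS probes the Watson–Crick edge of unpaired A and C);
it is off by default, since the standard workflow normalizes whatever
survives exclusion.

## Replicates and statistics

Averaging uses the per-position mean and sample (n−1) SD over replicates
with a value present; missing values are skipped, never imputed, and the
per-position support count is reported. No inter-replicate rescaling is
applied beyond each replicate's own normalization.

The comparison cascade treats each profile's non-missing values as one
sample. "Departure from normality" is operationalized as *any* sample with
Shapiro-Wilk p < α (default 0.05): a single non-Gaussian sample already
invalidates parametric assumptions for the joint comparison. Bartlett's
variance test is reported but does not gate the branch. When all samples
pass normality no location test runs and the report states why — no
parametric fallback is offered. The Mann-Whitney test is two-sided, exact
for tie-free samples of ≤ 20 values and a continuity-corrected normal
approximation otherwise; Kruskal-Wallis handles 3–5 samples. Its type-I
behavior is checked empirically (rejection rate at α = 0.05 within
[0.03, 0.07] over 500 same-distribution pairs).

## Visualization

Bars are colored by exactly the same bin assignment as the tabular output;
missing positions are gaps, never zero-height bars, to avoid fabricating
"unreactive" signal. Box plots draw whiskers at min/max (the distribution
summary intended here is quartiles-plus-range, not fence-based). Figure
geometry, fonts and file metadata are pinned so identical inputs produce
byte-identical images. PNG and EPS are supported.

## Structure adapter

Reactivity-driven folding is delegated to an external RNAstructure `Fold`
executable; its pseudo-energy slope/intercept and DMS mode are exposed as
pass-through options with no defaults beyond the tool's own. The adapter
writes the restraint file through the same `.shape` writer as the rest of
the package (missing = −999 = no restraint), parses the connectivity-table
output, and renders nested pairs as dot-bracket; crossing pairs are
rejected (no pseudoknot notation). Absence of the executable is a hard
dependency error, never a silent skip, so the adapter is fully testable
with a mocked executable.

## Synthetic data generator

The generator emulates a CE probing experiment at the peak-area-table
level. Background areas are gamma-distributed (default mean 100 units,
CV 0.2 — typical mid-signal CE peak statistics); reaction areas are
background plus a signal proportional to an intended normalized reactivity
(default profile: right-skewed beta(0.7, 2)·1.5, i.e. mostly unreactive
positions with a reactive minority, as in structured RNAs). Planted
strong-stops are constructed *relative to the final realized mean
background* — high-background stops at 6.5×, low-difference stops at 1.3×
background with 0.2× difference, negative stops at rx = 0.7·bg — by
solving the post-planting mean exactly and then moving any clean
background that sits too close to the low-signal criterion into a safe
band. Every planted stop satisfies its criterion, and every clean position
violates all criteria, with ≥ 10 % margin; a literal audit re-checks the
margins and raises if the configuration is unachievable (e.g. too many
high-background stops for the length). This makes classifier-recovery
tests exact rather than probabilistic. Between-replicate variation is
truncated multiplicative noise on the areas (default relative SD 0.03,
clipped at ±3 SD) so margins survive noise; zero noise gives bit-identical
replicates. A separate boundary fixture places a background at exactly
five times the mean to pin the inclusive threshold.

What the generator does **not** emulate: raw electropherogram artifacts
(peak overlap, mobility shift, signal decay — the upstream tools' domain),
correlated noise along the capillary, partial-length reads, or ambiguous
stops sitting *on* a criterion boundary. Passing recovery tests therefore
demonstrates the classifier implements its criteria exactly, not that the
criteria themselves capture every artifact in real traces.

## Problem sizes

Default test and reproduction runs use 1,000 random experiments of ≤ 50
records for oracle-equivalence, 20 seeds of length 100–600 with 5–30
planted stops for recovery, datasets of 12–250 values for normalization
invariants, and 500 sample pairs of 50 values for the type-I rate — sizes
at which every check is exact or its sampling error is well inside the
asserted band, while a full run stays in the seconds range.
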