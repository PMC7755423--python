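# Methods

This note documents the models and procedures implemented in `cdrmatrix`,
the defaults and why they were chosen, what the synthetic data generator does
and does not emulate, and the numerical conventions that matter for
reproducibility.

## Matrix encoding

Each antibody contributes six CDR loop strings (CDR1/2/3 of the light chain,
then of the heavy chain).  Every loop is centre-aligned into a fixed-width
column block: for a loop of length `n` in a block of width `w`, the left pad
is `floor((w − n)/2)` zeros and any odd slack falls on the right.  This
tie-break is arbitrary but must be fixed for runs to be comparable.  Blocks
are separated by `buffer_width` zero columns (default 3; purely cosmetic
separation — buffer columns carry no information and are reported
"untestable" by the statistics layer).  Automatic layouts set each block
width to the maximum observed loop length across *all* records, both classes
together, so the two populations share one coordinate system.

Residues map to the integer codes 1–20 in the order
`AVLIMFWPGSTCYNQHRKDE` — hydrophobic, then polar, then charged — which
places leucine at 3, histidine at 16 and arginine at 17.  Those three
assignments are the fixed anchors of the encoding; the rest of the ordering
is this package's choice and is configurable, since nothing downstream
depends on it beyond bijectivity (masks and information measures are
invariant to relabeling).  Code 21 is reserved for `X` and any non-standard
or ambiguous letter; code 0 is buffer/pad.  Matrix coordinates are 0-based
with half-open spans.

### Labeling schemes

Reactivity against the ELISA ligand panel (0–7 ligands bound) drives two
labeling schemes.  `full`: two or more ligands bound → polyreactive,
otherwise non-polyreactive.  `parsed`: 4–7 → polyreactive, 0 →
non-polyreactive, 1–3 → excluded from analysis; this keeps only strong
phenotypes and removes the ambiguous middle of the scale.

## Property masks

A mask substitutes each residue code with a per-residue scalar; code 0 stays
0, and code 21 (non-standard) is imputed as 0 under every default mask, with
a log record when it occurs.  The default table has 62 masks in three
categories (`src/cdrmatrix/data/properties.csv`; regenerated by
`scripts/make_default_properties.py`):

* **basic (5)** — `hydrophobicity1` (Kyte–Doolittle rescaled to [−1, 1]);
  `charge` (see below); `hydrophobicity2` (Eisenberg consensus rescaled to
  [−1, 1]); `side_chain_flexibility` (rotatable side-chain dihedral count,
  0–4); `side_chain_bulk` (Zimmerman bulkiness).  Two distinct
  hydrophobicity scales are deliberate: they disagree enough (e.g. on
  tryptophan and proline) to carry complementary information.
* **kidera (10)** — orthogonal factors standardized to mean 0, SD 1 over
  the 20 residues, built here by PCA of a z-scored panel of thirteen classic
  scales.  This mirrors how the published Kidera factors were constructed
  (PCA of a larger property panel) but the values are a reconstruction, not
  the published ones; any table with the same shape can be substituted via
  `load_property_table(path)`.
* **hotspot (47)** — numbered structural-propensity descriptors.  Slots 6,
  24, 25 and 41 carry standardized α-helix, β-sheet and reverse-turn
  propensities and side-chain flexibility — the structurally meaningful
  slots referenced elsewhere in the package.  The remaining slots are
  synthetic standardized placeholder descriptors (seeded, reproducible) that
  keep the table at full width; they are valid masks (any per-residue scalar
  is) but encode no curated biophysics, and the metadata file flags them as
  placeholders.

**Charge model.**  Fractional side-chain charge at pH 7.0 from a single
Henderson–Hasselbalch term per residue: basic side chains contribute
`+1/(1 + 10^(pH − pKa))`, acidic ones `−1/(1 + 10^(pKa − pH))`, others 0.
Default side-chain pKa values: D 3.65, E 4.25, H 6.0, C 8.3, Y 10.07,
K 10.53, R 12.48.  The histidine pKa of 6.0 is what makes the rounded
anchor triple L/H/R → 0.000/0.091/1.000 come out exactly; the table is
overridable for other pH regimes.  No coupling between ionizable groups and
no N/C-terminal charges are modelled.

Feature matrices concatenate masked rows across a chosen property list into
`N x (L·P)` columns named `property@column`, optionally z-scored per column
(constant columns map to 0 rather than NaN).

## Two-population statistics

Per matrix column, class means are reported with bootstrap standard errors:
the SD of the column mean over `R` within-class resamples drawn with
replacement from the empirical distribution (default `R = 1000`).

Significance uses the two-sided **Studentized bootstrap test**.  The
empirical statistic is

    z₀ = (Ȳ₂ − Ȳ₁) / sqrt(σ₂²/n₂ + σ₁²/n₁)

with n−1 sample standard deviations.  The variance terms *add* under the
root — the standard Studentized form; a subtraction there would be negative
under the root whenever the second group's term is smaller.  Null replicates
pool both groups without labels and draw `n₁` and `n₂` observations from the
pool with replacement (a random-partition null is available via
`null="partition"`), and

    p = (1 + #(z² ≥ z₀²)) / (R + 1),

so `p` is floored at `1/(R+1)` and can never be 0.  Two-sidedness comes from
the squaring.  Degenerate inputs follow explicit conventions: both groups
constant and equal → `z₀ = 0, p = 1`; both constant but unequal → `z₀`
treated as exceeding every finite null statistic, `p = 1/(R+1)`.  Null
replicates that happen to be constant produce ±inf statistics and correctly
count as extreme.

The **permutation test** shuffles class labels over the pooled rows,
preserving group sizes, with the absolute difference of means as the default
statistic and `p = (1 + #(t ≥ t₀)) / (R + 1)`.  Any callable statistic can
be substituted — the mutual-information difference uses exactly this route.

Multiple testing across columns uses Bonferroni (`p_adj = min(1, m·p)`,
`m` = number of testable columns); contiguous significant columns are
reported as half-open intervals for profile plots.  Note an interaction
worth knowing: with `R = 1000` the smallest attainable adjusted p is
`m/1001`, so more than ~50 testable columns make 0.05 unreachable — raise
`R` or reduce the layout when testing wide matrices.

Calibration, measured by the acceptance suite (1000 null simulations,
n = 50/50, R = 1000): both tests hold their 5% nominal size within
[0.03, 0.07].

## Information theory

Each column is a categorical variable over residue codes.  By default the
buffer/gap code 0 counts as an ordinary symbol — loop-edge columns then
retain loop-length information; `gap_mode="exclude"` restricts estimation to
gap-free rows instead.  Entropy and conditional entropy are plug-in
(maximum-likelihood) estimates in bits with `0·log 0 = 0`; mutual
information is `I = H(X) − H(X|Y)`, clipped at 0 to absorb float dust, and
the L×L matrix carries `H(X)` on its diagonal.  No small-sample bias
correction is applied (the plug-in MI bias is roughly
`(|X|−1)(|Y|−1)/(2n ln 2)`; at the fixture sizes used here it is well under
0.01 bit).  The theoretical maximum for 20 equiprobable residues is
`log₂ 20 ≈ 4.32` bits, which is the value this package computes and reports.

Class MI-difference maps are signed polyreactive − non-polyreactive, with
per-pair permutation p-values.  Testing all `L²` pairs at `R = 1000` is
quadratic and slow, so the API accepts an explicit pair list; the full
difference map is always computed.

## Classification

* **Frequency differences** — per (column, residue) difference of
  within-class frequencies, with a 10% display threshold for the filtered
  view.
* **Feature selection** (`top_diff`) — rank z-scored columns by the absolute
  class mean difference, then walk down the ranking keeping a feature only
  if its |Pearson r| with every already-kept feature is below the threshold
  (default 0.75), until `k` features are kept (default 75, the main
  overfitting control).  PCA reduction is the alternative parser.
* **Fisher LDA (mode 1)** — two-class discriminant fit on all rows, with a
  ridge term (ε = 1e−6) on singular within-class scatter.  Separation
  accuracy is the fraction of rows on the correct side of the midpoint
  between projected class means, axis oriented toward the
  alphabetically-later class; ≥ 0.5 on training data by construction.
  Weights map back to `property@column` names; `top_weights(k)` returns the
  largest-magnitude entries.  A guard rejects fits with more features than
  rows.
* **SVM / LOOCV (mode 2)** — linear kernel, `C = 1`, class-balanced weights
  (simple defaults in the absence of a reason to tune).  In every
  leave-one-out fold the standardizer and the feature selector are refit on
  the N−1 training rows, so the held-out sequence cannot influence its own
  feature set; the no-leakage property is tested directly.  Folds whose
  training rows lose a class are skipped with a warning.
* **Scrambled control** — LOOCV repeated under random label permutations;
  for balanced classes the expected accuracy is 0.5.  Single scrambles have
  noticeable spread (SD ≈ 0.05 at n = 200, slightly wider than binomial
  because residual agreement with the true labels lets real signal bleed
  through), so the acceptance script reports the mean over five scrambles.

Whether to z-score features before LDA/SVM is genuinely open; it is on by
default and flag-controlled, since the masks live on very different numeric
scales.

## MHC platform domains

Aligned FASTA per molecular class (equal aligned lengths enforced), plus
user-declared feature boundaries — an ordered list of `(strand|helix, start,
end)` half-open intervals in alignment coordinates, from YAML/JSON.
Structural prediction itself is out of scope: boundaries are configuration,
which keeps the artifact deterministic and lets users bring boundaries from
any source.  Each feature segment is cut out, stripped of in-segment gaps
(a flag preserves gap columns as zeros instead), and centre-aligned into its
own block; the result is an ordinary encoded matrix with class names as row
labels, on which every downstream stage operates unchanged.  Held-out
platform sequences are assigned by nearest class centroid in a PCA space fit
on training rows only.

## Synthetic data generator

`synthetic_fixtures` draws two labeled classes of six-loop records.
Defaults: loop-length candidates reflecting typical CDR ranges (CDR2L fixed
at 3, CDR3H 10–22, others short and narrow), uniform background over the 20
residues (a `natural` preset with serine/glycine/tyrosine-rich CDR-like
composition is included), reactivity counts drawn consistently with class
(polyreactive 4–7, non-polyreactive 0) so records round-trip through the
`parsed` labeling.  Signals:

* property shifts — with probability δ, the residue at a target position of
  one class is replaced by a uniform draw from a chosen residue set (e.g.
  {R, K} to shift charge);
* couplings — with probability c, the residue at site j is copied from site
  i of the same record, in one class only.  At c = 1 over a uniform
  four-letter background the coupled pair's MI approaches the analytic
  2-bit limit.

Zero-strength signals consume no randomness, so a δ = 0 spec is
byte-identical to the signal-free spec at the same seed.  Label noise, when
requested, flips labels (and reactivity counts) after signal implantation.

What the generator does *not* emulate: germline gene structure and V(D)J
recombination, somatic hypermutation lineages (rows are i.i.d., with no
phylogenetic relatedness), position-dependent composition, and
length/composition correlations.  Passing tests therefore demonstrate that
the machinery recovers known signals under clean conditions — not that real
repertoires contain such signals, nor that the classifier's fixture
accuracies transfer to real data.

### Benchmark problem sizes

The acceptance checks use fixed-length compact loop layouts (4/3/4/4/8/6,
with a length-10 CDR2H for the classifier fixture) so that loop positions
map to unique matrix columns and the Bonferroni family stays small enough
for `R = 1000` resolution.  Sizes: calibration at n = 50/50 over 1000 null
simulations; charge-shift recovery at δ = 0.5, n = 200/200; coupling
recovery at c = 1, n = 500/500 (MI limit checked at n = 2000); classifier at
n = 100/100; MHC class assignment over 20 seeded replicates.

## Known limitations

* The residue ordering beyond the three anchor codes, the exact
  hydrophobicity scale choices, and the Kidera/hotspot default values are
  package choices; analyses that depend on specific published scales should
  supply their own table.
* Plug-in entropy/MI estimates are biased upward at small n; no Miller–Madow
  correction is applied (the estimator choice is isolated behind the module
  surface for future extension).
* The MI-difference permutation test at all column pairs is O(L²·R) and
  intended for targeted pairs or small layouts.
* Center alignment discards the distinction between loop-length variation
  and residue substitution at block edges; gene-usage analysis (AIRR TSV
  input) is the complementary view for germline effects.
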