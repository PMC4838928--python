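# Methods

`hdmascreen` models, simulates and analyses combinatorial screens run in
high-density microbioreactor arrays (HDMAs): microfluidic chips in which
*d* soluble factors, each at *c* concentration levels, are multiplexed into
*c^d* compositions, every composition feeds *a* adjacent replicate columns,
and each column holds *b* serially connected culture chambers, for
*n = a·b·c^d* chambers.  The reference geometry throughout is the
8100-chamber cardiomyocyte proliferation screen: *a* = 2, *b* = 50, *c* = 3,
*d* = 4, circular chambers of 0.513 mm diameter (0.2 mm² floor, ≈20 nL at
100 µm feature height), factors CHIR99021 (0/2.5/5 µM), purmorphamine
(0/1/2 µM), IGF-1 and FGF-2 (0/50/100 ng/mL).

## Design matrix

Compositions are enumerated mixed-radix over the per-factor level lists,
last-listed factor varying fastest and levels ascending, so the all-zero
control composition is always column-pair 0.  The ordering is a convention
(devices differ); `build_design` accepts a permutation to match a physical
chip.  Replicate columns of one composition are adjacent and 0-indexed left
to right.  The stock multiplier uses an idealized equal-flowrate merge of
factor/buffer stream pairs — each factor stream is diluted by the number of
merged streams (4 for the four-factor device), so stocks are supplied at
that multiple of the highest screened concentration.  No hydraulic network
is solved.

## Synthetic screens

The generator's defaults are the study conditions of the reference screen:

| parameter | default | meaning |
|---|---|---|
| mean cells/chamber | 200 | 10⁵ cells/cm² seeding density × 0.002 cm² floor |
| seeding CV | 0.148 | between-chamber variation of seeded cell counts |
| myocyte fraction | 0.80 | cTnT⁺ share of the input population |
| baseline Ki67⁺ myocytes | 0.15 | cycling fraction without factors |
| baseline Ki67⁺ non-myocytes | 0.10 | cycling fraction of the stromal side |
| binucleated fraction | 0.01 | cardiomyocytes with two nuclei |

Chamber cell counts follow a lognormal law parameterized by mean and CV
(a negative-binomial alternative is available); class memberships are
binomial.  The dose response is multiplicative on the baseline Ki67⁺
myocyte probability: each factor contributes a level-indexed multiplier
(1 at level 0), optional pairwise interaction multipliers, and an optional
per-row attenuation profile along the *b* serial chambers (off by default —
the depletion seen down real columns is qualitative and unquantified).  The
product is clamped at probability 1 with a warning.  The default
"screen-like" response gives the CHIR-like factor multipliers 1/1.8/2.0
(near-saturating doubling, matching the observed ~2× at 2.5–5 µM) and
leaves the other factors null.

Tiles are rendered at 2 µm/pixel into 272-px-square, channel-first uint16
arrays: DNA (all nuclei), cTnT (cytoplasm disks of myocytes, 7.5 µm
radius), Ki67 (nuclei of cycling cells).  Nuclei are soft-edged disks of
radius N(4, 0.5) µm placed uniformly in the chamber disk with 11 µm
minimum-distance rejection (spacing is relaxed progressively if a chamber
is too crowded).  Per-cell amplitudes are lognormal (CV 0.25) around the
channel gains; a Gaussian point-spread blur of σ = 1 µm, Poisson shot noise
and Gaussian read noise (σ = 8 counts) over a 100-count background complete
the optics model.  These values were set so that the analysis task is
non-trivial (overlapping soft edges, shot noise, dim tails) while a correct
pipeline can reach the fidelity the design targets (detection F1 > 0.95).
What the generator does **not** emulate: colony-structured attachment (a
clustering mode is deliberately out of scope), realistic PSFs, uneven
illumination, staining artefacts, focus drift and debris.  Passing tests
therefore demonstrate correctness of the measurement and statistics
pipeline, not robustness to every real-world imaging pathology.

Static-culture confirmation data use the same response model with a shared
lognormal between-induction multiplier on the baseline (CV 0.30, applied
identically to all condition arms of one experiment — this preserves the
paired structure of repeat inductions), a small per-well lognormal jitter
(CV 0.05) and binomial counting noise from 2000 cells/well.  With growth
enabled, final myocyte counts are Poisson(n·(1+p)): cycling cells complete
one division, so proliferative conditions also raise myocyte numbers.
Flow-style pulse events model binucleated cells as width ≈ 1.5 (vs 1.0)
at comparable pulse area, and cell doublets (2%) as large in both; the
binucleation gate counts cTnT⁺ singlets above width 1.25.

## Image cytometry

Nuclei: Gaussian smoothing (σ 0.8 px), global Otsu threshold, a
signal-to-noise guard that declares a tile empty when the foreground mean
sits within 4 background SDs of the background mean (plain Otsu always
splits a noise-only tile), removal of objects under 4 px, and
distance-transform watershed declumping of blobs above 30 px (about twice
the nominal nuclear footprint).  Cytoplasm: each nucleus is expanded into
the above-background cTnT signal by seeded watershed on the inverted
smoothed intensity, competing fronts meeting along intensity-guided
midlines; cells without cytoplasm signal keep the nucleus plus a 2-px
annulus, and the same SNR guard prevents a signal-free channel from being
thresholded into noise islands.  Features: nuclear/cellular areas,
centroids, eccentricity from per-label central moments, integrated
intensities as background-subtracted sums over each mask (background =
median of non-cell pixels), floored at zero.  Solidity requires a convex
hull per object and is optional on batch runs, where it is not consumed.
Chambers are flagged `empty` (no detected cells) or `failed` (processing
error, or more than 5% saturated pixels).

## Gating and reduction

Myocytes are gated rectangularly in the (cellular projected area, cellular
integrated cTnT intensity) plane — both minima must be exceeded (area
default 50 µm²); Ki67⁺ on nuclear integrated Ki67 intensity.  Default
threshold resolution is Otsu on log1p intensities (scale-free, invariant
under record duplication); alternatives are fixed values and a
control-population quantile for Ki67.  Per chamber: counts of the four
classes and %Ki67⁺ of myocytes / of non-myocytes.  A chamber with zero
myocytes has an undefined fraction, kept as missing by default; the
compatibility mode replaces every flagged chamber with all-zero
measurements, reproducing the convention used for array-wide heatmaps.
Column-pair series average the *a* replicate columns row-wise, giving *b*
values summarized as mean ± SD; pairs are compared by unpaired two-tailed
t-tests on those row values (identical series return t = 0, p = 1; zero
variance in both with different means is a degenerate-test error).  No
multiple-testing correction is applied across column pairs by default.

## Factorial analysis

Experimental units are per-column mean responses (162 columns, 2 per
composition), fitted with a classical balanced-design decomposition: level
effects are marginal means minus the grand mean; two-factor interaction
effects are two-way cell means with the grand mean and both main effects
removed; terms above second order pool into the residual
(df = N − 1 − Σ term df).  F ratios use the residual mean square, p-values
the F distribution; a constant response reports F = 0, p = 1.  Balanced
Type I/II/III sums of squares coincide; unbalanced inputs (columns lost to
QC) are routed to an effect-coded least-squares fit with Type-II SS, which
on balanced data reproduces the classical estimator exactly — that
equivalence, and exact zero-sum and SS-closure identities, are enforced in
the tests at 1e−10 / 1e−8.  Confirmation statistics: Pearson r between
platform and static condition means, one-way ANOVA with Tukey HSD (via the
studentized range, reported against the control arm), paired two-tailed
t-tests pairing by induction, and control-normalized myocyte fold change.

## Pipeline, determinism and problem sizes

One top-level seed feeds salted `numpy.random.SeedSequence` substreams per
stage and per chamber, so identical configs reproduce byte-identical CSVs
and changing, say, the gate method does not perturb the simulation.  The
bundled demo config runs a rendered 2×5×3² array (90 chambers, seconds).
Full-scale validation uses the 8100-chamber layout: statistical-recovery
studies (20 replicate screens) run on the generator's ground-truth count
path, while image-path fidelity renders and processes all 8100 tiles once
(several minutes); both paths share the gating, aggregation and factorial
code.  These sizes are the package's validation design: estimator recovery
is a property of the statistics and needs replication, whereas
image-measurement fidelity is a property of one full-scale pass.

## Known limitations

- Segmentation defaults are tuned to the synthetic optics model; real
  confocal data will need parameter review (all parameters are exposed).
- The serial-row attenuation profile is phenomenological; no transport
  physics is modelled.
- The Otsu-based gates assume clearly bimodal marker distributions; dim
  or continuous marker expression calls for the control-quantile method.
- Fabrication, flow distribution and hydraulic resistance are out of
  scope; `stock_multiplier` is an ideal mass balance.
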