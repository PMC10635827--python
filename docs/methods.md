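# Methods

This note documents the models behind each analysis arm, the default
parameters and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerically delicate choices.

## Imaging: percent steatosis and the lipid score

An image is a two-channel field: a nuclear counterstain (DAPI-like) and
a neutral-lipid stain (Nile-Red-like). Z-stacks are reduced by
maximum-intensity projection; all measurements are 2D (steatosis area
measurements in 2D and 3D track each other closely for near-spherical
organoids, and 2D keeps the pipeline fast and deterministic).

The organoid region of interest (ROI) is defined by nuclear signal
occupancy: Gaussian smoothing (sigma 2 px), global Otsu threshold,
morphological closing (disk radius 10 px) to bridge inter-nuclear gaps,
hole filling, largest connected component, and finally the convex hull
of that component. The hull step matters: nuclei sample the organoid
surface sparsely, so the closed mask has ragged bays at the rim that
understate the organoid area by 10–20%; organoid cross-sections are
close to convex, and with the hull the ROI area lands within ~3% of the
true disk on synthetic images. `convex_hull=False` recovers the raw
closed mask for non-convex specimens.

Droplets are segmented with an Otsu threshold computed from the
lipid-channel intensities *inside the ROI* (no smoothing, so droplet
boundaries stay sharp), intersected with the ROI; components smaller
than `min_area_px` (default 4 px, sub-diffraction speckle) are removed.
Because the threshold is recomputed from the data, percent steatosis is
invariant to uniform rescaling of the lipid channel.

Percent steatosis is `100 * droplet_area / roi_area`. The lipid score
is the affine map sending the mean WT coverage to 0 and the mean
vehicle-treated steatotic coverage to 1; it is deliberately unclipped
(scores > 1 = aggravated steatosis, < 0 = below-WT lipid). Batch mode
scores the largest ROI per image and averages scores across images;
whether replicate coverages are averaged before or after the affine map
is immaterial (the map is affine and commutes with the mean), which the
tests verify.

## Isotope tracing: the mass-shift DNL classifier

Fatty acids synthesized de novo on [U-13C]-glucose are built from 13C2
acetyl units, so their mass shifts are even and, for any realistic
precursor enrichment, at least +4 (a de novo chain with fewer than two
labeled units among its n/2 acetyl units is vanishingly rare: for C16:0
at enrichment 0.8 the probability is below 1e-4). Shifts of +2/+3 are
attributed to single-unit elongation of pre-existing chains and are
excluded. The per-fatty-acid fraction is

    f = sum(I[shift >= 4]) / sum(I[shift not in {2, 3}])

Two denominator conventions are implemented. The default (`m23 =
"exclude"`) removes +2/+3 from the denominator too, treating elongated
molecules as belonging to neither class; this introduces a small upward
shift (~1 pp at the default 5% elongation, since real +2 mass leaves the
denominator) but keeps the classifier a pure two-class ratio. The
alternative (`m23="keep"`) retains them and is nearly exact under
elongation (changes < 0.5 pp for elongation fractions up to 0.1). On
the worked example below the two modes give 60.7% and 59.9%.

No natural-abundance deconvolution is applied: at 1.07% 13C the mass
leaking past the >= +4 rule is < 1e-4 for chains up to 22 carbons, which
is also why an essential fatty acid (C20:4) works as a negative control
(apparent DNL ~0.09 pp at defaults, including its own elongation-derived
+2 mass). A correction hook would sit upstream of `dnl_fraction`; it is
deliberately absent by default.

Pooling weights per-FA fractions by molar abundance, renormalized over
the evaluated set (default: C14:0, C16:0, C16:1, C18:0, C18:1 — the
dominant synthesizable species). Equal weighting is available
(`equal_weights=True`); with the low between-FA heterogeneity of the
defaults the two differ by < 1 pp. Replicates are estimated
independently and averaged afterwards. The time-course slope is an
ordinary least-squares fit of pooled percent against day.

## TAG lipidomics

Quantification is class-level against one spiked internal standard of
known concentration (pmol), response factors assumed 1 — i.e.
`conc = intensity / IS_intensity * IS_conc`. Composition statistics are
molar (quantity-weighted): the total-double-bond histogram; the
"lower-unsaturation" class defined as TAG containing at least one fully
saturated constituent chain; total-carbon chain-length fractions over
the 48–58 C classes (off-grid species snap to the nearest class,
out-of-range species to the boundary, both with warnings); and the DNL
index, the ratio of C16:0 to C18:2 chain counts weighted by species
quantity (palmitate is the primary DNL product, linoleate is strictly
dietary). Isomeric species with identical C:D totals but different
chains are kept distinct. Species lacking chain resolution participate
only in the statistics that need no chains.

## Screening

Drug screens are aggregated per drug x dose by the arithmetic mean of
replicate coverages (median by option), scored with the lipid-score map,
and masked where any replicate is flagged toxic. Ranking uses the best
(minimum) non-toxic score per drug, ties broken by name; drugs toxic at
every dose are excluded with a warning. Model agreement is the squared
Pearson correlation of paired per-drug scores (equal to OLS R^2 with
intercept), listwise-deleting incomplete pairs, requiring >= 3 pairs and
non-zero variance.

CRISPR phenotypes use the three-way scale -1/0/+1 (lighter / similar /
darker than the steatotic baseline). The effect score
`s = (mean_target - mean_control) / (mean_control - wt_mean)` is
symmetric by construction: s = -1 is full reversion to WT, s = +1 a
doubling of the steatosis excess. The call threshold delta = 0.25 is
plumbing, not a biological claim — it reflects that the original calls
were made by eye, and it is exposed in the API. At the default
replicate noise the null (no effect) yields call 0 with probability
>= 0.9.

## Synthetic data: what is emulated, what is not

**Images** place bright nuclear disks (400 nuclei, radii 5–8 px —
densities at which the ROI pipeline resolves the organoid within a few
percent) across a centered organoid disk (radius 180 px in a 512 x 512
frame) and bright droplet disks (radii 3–12 px) fully inside it,
adding droplets until the union mask reaches the target coverage
(default 0.30, matching the spontaneous steatosis of VLDL-secretion
mutants; the sampled radius shrinks near the target so recorded
coverage lands within ~1%). Ground-truth coverage is exactly
mask-pixels / organoid-pixels. Additive Gaussian noise (sd 5% of the
signal amplitude) on 16-bit images. Not emulated: uneven illumination,
out-of-focus light, droplet clustering/coalescence, multiple organoids
per field, autofluorescence. Passing recovery tests therefore show the
pipeline is correct and unbiased under clean, disk-shaped geometry —
not that it is robust to every real-world artifact.

**Labeling** builds each fatty acid's isotopologue vector from three
molecule classes — unlabeled pre-existing, pre-existing elongated by one
acetyl unit (+2 with probability equal to the precursor enrichment,
since the added unit draws on the same acetyl-CoA pool), and de novo
with Binomial(n_units, enrichment) labeled units at +2 each — convolved
with the Binomial(n_carbons, 1.07%) natural-abundance distribution,
truncated at the chain length and renormalized. Defaults: DNL accrues
at 12%/day (60% cumulative at day 5), enrichment 0.8 (untraced
pyruvate/glutamine/amino-acid carbon keeps it below 1), elongation 5%,
multiplicative log-normal noise at CV 5%, n = 2 replicates. The default
pool gives the five major species 90.5% of total molar abundance and
~99% of the synthesizable pool. Not emulated: mass-resolution effects,
isotope impurity of the tracer, exchange/turnover kinetics within a day.

**TAG profiles** draw mean-corrected log-normal quantities per species
(CV 5%) around mean x condition fold change, with intensities emitted so
internal-standard quantification recovers them exactly. Scenario
defaults encode the study conditions: WT supernatant at 25-fold the
blank-medium TAG; FADS2 knockout at 3.0-fold (+200%) with composition
biased toward saturated-chain species; FADS2 overexpression at
0.45-fold (> 50% reduction) biased toward PUFA-containing, longer
species. Biases are applied per species and then renormalized so the
total-TAG fold change stays exactly the stated truth.

**Screens** draw coverages as
`steatotic_mean - effect x (steatotic_mean - wt_mean) + noise` with
wt = 0.02, steatotic = 0.30, replicate sd 0.015, n = 3, over a
12-drug panel in which DNL-axis drugs (ACC/FAS/DGAT2 inhibitors, FXR
agonist, FGF19) are effective and others are not, with two cytotoxic
top doses. Effects are constructed distinct so the true ranking is
unique.

All generators take explicit seeds, use a private `numpy` Generator
(no global state), and are bit-reproducible.

## Numerical choices and degenerate inputs

- Otsu on a zero-contrast nuclei image raises "no organoid detected";
  a zero-contrast lipid channel inside the ROI falls back to whole-image
  statistics, so uniformly bright ROIs segment as all-droplet and
  uniformly dark images as dropletless.
- `dnl_fraction` raises when the denominator after exclusion is zero;
  vectors shorter than 5 entries have a zero numerator by construction.
- Isotopologue vectors are renormalized to sum 1 (tolerance 1e-9 in the
  invariant tests) after truncation at the chain length.
- Ranking and correlation propagate missing cells as missing, never as
  zero; toxic wells never contribute coverage values.
- Problem sizes in the recovery suites — 20 image seeds, 2 labeling
  seeds x 2 replicates, 10 lipidomics seeds, 20 screen seeds — hold the
  Monte-Carlo error of each check comfortably below its tolerance.

## Known limitations

- The droplet threshold is global per image; strongly varying background
  would need local thresholding, which is out of scope.
- Class-level TAG quantification ignores per-species response factors.
- The DNL classifier reports glucose-driven synthesis only; acetyl-CoA
  from untraced sources lowers the ceiling below 100% by design.
- The CRISPR call threshold and the drug-effectiveness threshold are
  operating points, not estimated quantities.
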