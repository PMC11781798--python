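# Methods

## The localization index

The LI is a ratiometric, mean-normalized statistic on two-channel 3D
volumes. At each voxel the target signal (a tagged membrane protein,
visible only in the labeled cell type) is divided by a membrane
reference marker assumed to distribute uniformly over the plasma
membrane. Voxels without membrane signal carry no information about the
ratio and are censored. The remaining per-voxel ratios are divided by
their arithmetic mean over the region of interest, so that the mean LI
over valid voxels is exactly 1 — the map answers "where is the protein
relative to its own average density on this cell's membrane", not "how
bright is it".

Assumptions worth stating:

- The reference marker really is uniform on the membrane. Any structure
  in the reference (local over-expression, aggregation) is transferred
  inversely into the LI.
- Intensities are linear in fluorophore abundance. The reader never
  rescales, and no background subtraction is applied by default; a
  constant detector offset biases ratios at dim voxels.
- The normalization ROI is part of the statistic. The default ROI is
  the whole censoring mask; restricting it (e.g. to one labeled
  compartment) renormalizes the map, and region means are only
  comparable across samples when the ROI convention is fixed.
- One brain sample contributes one data point per region. Voxels within
  a sample are strongly correlated and are never pooled across samples.

Normalization uses the mean of per-voxel ratios, not the ratio of
summed intensities. The two differ on heterogeneous volumes; only the
mean-of-ratios convention makes mean(LI) = 1 hold identically, which is
the conservation law the tests and the acceptance script rely on.

### Censoring

"Devoid of membrane signal" is resolved as membrane ≤ threshold. The
library default is a fixed threshold of 0 — the literal reading, and
exact on clean synthetic data. On real or noisy volumes a zero threshold
admits voxels whose membrane value is dominated by noise, where the
ratio is unstable; the pipeline configuration therefore defaults to an
Otsu threshold resolved from the membrane histogram, with a quantile
method as the third option. The resolved threshold is always reported
next to the mask. Ratios are not winsorized by default; a quantile cap
is available in the config for data with extreme outliers.

## Rendering

Two quantities are encoded per pixel: color is the LI clipped to a
display range bracketing 1 and passed through a diverging colormap whose
midpoint is pinned at LI = 1 (default `coolwarm`, range 0.5–2.0, so red
means enrichment); brightness is the normalized membrane intensity
raised to a configurable gamma, so regions with little membrane — where
the ratio is least reliable — fade to black. Censored voxels are black
outright. Maximum-intensity projections select the displayed voxel per
ray by membrane brightness and carry its LI, rather than projecting LI
itself, which would mix values across depths. The display range is a
linear clip; symmetric fold-changes (×2 vs ÷2) are therefore only
approximately symmetric on screen. Range and colormap are recorded in
the run manifest.

## Puncta

Active-zone puncta are detected by scale-normalized
Laplacian-of-Gaussian blob detection (scikit-image), with the physical
sigma range (default 0.2–0.45 µm) converted to per-axis voxel sigmas so
anisotropic stacks are handled correctly. Centroids are refined to
sub-voxel precision by a local center of mass. Detections closer than
one sigma (physical distance) are merged keeping the brighter. The
response threshold default of 8.0 corresponds to four times the
synthetic benchmark's spot-channel noise sd of 2.0: on seeded noise-only
volumes, noise maxima die out around response 7 while spots at peak
SNR 5 respond above 10, giving zero false positives with full recall in
that regime. For other acquisitions the threshold scales linearly with
intensity and is a config parameter.

Whether a punctum belongs to the labeled cell is decided by the fraction
of its support (an ellipsoidal ball of radius 1.5 × sigma around the
centroid) lying on the membrane mask; the default majority criterion is
overlap ≥ 0.5. Receptor adjacency ("abutted" vs "barely detectable") is
the mean receptor intensity over a spherical shell [sigma, 3 sigma]
around the centroid, because receptor signal surrounds rather than
coincides with the active zone. Ties at either threshold classify
positive (≥, not >). The automatic adjacency threshold (k × the
volume-wide receptor median, default k = 2) presumes the background
dominates the volume and is nonzero; on noiseless synthetic data it
degenerates to 0 and an explicit threshold should be passed. Shells
clipped by the volume edge are scored on the available voxels and
flagged.

## Group statistics

Comparisons follow a fixed, recorded decision tree: Shapiro-Wilk per
group, then homoscedasticity, then the parametric branch (Student's
t-test for two groups; one-way ANOVA with Dunnett's test against a
control or Bonferroni-corrected pairwise t-tests; type-II two-way ANOVA
for factorial designs) if no assumption is violated at α = 0.05, else
the nonparametric branch (Mann-Whitney U; Kruskal-Wallis with Dunn's
tie-corrected post hoc test). Any single violated assumption routes the
whole comparison nonparametric. The homoscedasticity default is
Bartlett's test; a rank-correlation variant (Spearman correlation of
absolute residuals against fitted group means) is provided as an option
since that form of the check is not standardized. There is no exact
nonparametric factorial analogue, so a two-way design with violated
assumptions runs the factorial ANOVA on rank-transformed responses,
with the violation recorded in the decision path. Type-II sums of
squares are used; on the balanced designs the generator produces, all
SS types coincide. Significance symbols: * p<0.05, ** p<0.01,
*** p<0.001, ns otherwise.

The behavioral learning index is computed per second as
(#CS− − #CS+)/(#CS+ + #CS−) — positive for learned avoidance of the
punished odor under the aversive convention — and averaged over the
last 60 s of a 120 s test by default. The appetitive convention flips
the sign so that learned approach scores positive. Seconds with no fly
in either arm are excluded and flagged. A reciprocally trained pair of
groups is averaged into a single data point.

## The synthetic generator

The generator produces what the analysis assumes and nothing more. The
membrane channel is a tube around a smooth seeded random-walk
centerline threading the volume: a Gaussian shell of width 0.3 µm at
radius 1.5 µm (peak 100 AU) plus a dimmer lumen term (35% of peak),
mimicking a plasma-membrane marker's bright rim. The centerline is
partitioned into equal-arc-length compartments; the receptor channel is
membrane × the compartment's enrichment factor. Noise defaults model a
plausible confocal regime: 10% multiplicative CV per channel, additive
Gaussian noise at 2% of the membrane peak, clipped at zero; a
photon-like variance ∝ mean term is optional. Voxels default to
0.4 × 0.2 × 0.2 µm (z coarser, as acquired). The default volume
(48 × 192 × 192 voxels, two compartments at factors 1.0 and 2.0) gives
each compartment ≥ 10⁴ valid voxels, sized so region-mean estimates are
dominated by bias, not variance.

Spot benchmarks place Gaussian puncta (σ = 0.3 µm) with peak SNR drawn
uniformly from [5, 10] against additive noise of sd 2.0, pairwise
separated by ≥ 1.5 µm (> 4σ): in-cell puncta inside the tube (within
0.6 × radius of the centerline, so their support lies wholly on the
membrane mask), out-of-cell puncta ≥ 1.2 µm clear of any membrane
signal. A configurable fraction of in-cell puncta receives a receptor
"condensate": a shell of receptor intensity (amplitude 10 × membrane
peak) at radius 2σ, inside the [σ, 3σ] adjacency shell.

Factorial tables draw normal measurements around programmed
genotype × starvation-time cell means (default preset: one receptor
rising 1.0 → 1.7 over 0–48 h, the other drifting 1.0 → 0.8, sd 0.3,
n = 10 per cell — a crossover interaction detected at p < 0.01 with
power ≈ 0.97). Behavioral counts allocate each fly to the CS− arm with
probability (1 + LI_true)/2, independently per second.

What the generator deliberately does not emulate: optical PSFs and
axial blur, bleaching, sample-to-sample registration, autofluorescence,
realistic mushroom-body anatomy, and temporal autocorrelation of fly
positions in the T-maze. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artifact of real acquisitions.

## Numerical and testing choices

- The normalization law (mean LI = 1) is asserted to 1e-9 relative; the
  worked four-voxel example and the scalar per-voxel oracle to 1e-12.
- Otsu masks are compared against an exhaustive intra-class-variance
  search on data with two balanced, well-separated populations, where
  histogram binning cannot move voxels between classes.
- Statistical calibration uses 10⁴ seeded two-group null replicates
  (n = 10 each, the typical sample size for this kind of experiment);
  the tree's empirical type-I error is required to be within 0.05 ± 0.01.
  Interaction power uses 500 seeded replicates of the crossover preset.
- Problem sizes in the test suite (volumes up to 48 × 192 × 192, 500
  ANOVA replicates, 200 behavioral seeds) were chosen so the entire
  suite completes in well under a minute of compute while keeping every
  statistical assertion far from its decision boundary.
- Degenerate inputs fail loudly: empty masks, empty regions, constant
  groups, n < 3 per group, empty factorial cells, all-zero behavioral
  windows, and centroids outside the volume all raise with the
  offending name or index in the message.

## Known limitations

- The LI is undefined where the membrane is censored; comparisons of
  region means implicitly condition on the membrane mask, so systematic
  differences in masking between samples propagate into the statistics.
- Mean-of-ratios normalization is sensitive to heavy-tailed ratios at
  dim membrane voxels if censoring is too permissive; use the Otsu or
  quantile mask (or the winsorization cap) on noisy data.
- The punctum detector assumes approximately Gaussian, well-separated
  spots; overlapping active zones closer than ~1σ merge.
- Surface vs internalized receptor pools are indistinguishable at this
  resolution; the adjacency score measures proximity, not molecular
  interaction.
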