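# Methods

This note records the models behind `nicheshift`, the numeric choices that
matter, what the virtual-species validation does and does not establish, and
the known limitations.

## Occurrence processing

Records with invalid coordinates are dropped; records whose stated
coordinate uncertainty exceeds 5 km are removed, while records *without* an
uncertainty field are retained (literature-derived occurrences typically
lack one). Spatial rarefaction keeps one record per cell of an
equal-area-approximate grid: latitude bands of height `cell_km` (default
5 km) whose longitudinal cell width is widened by 1/cos(band latitude). The
grid origin is fixed at (−180°, −90°) for reproducibility, and the survivor
within a cell is drawn uniformly at random under the run seed, so the result
does not depend on input order. Native and introduced subsets are rarefied
independently because they are modelled separately. Species with fewer than
30 records in either population after rarefaction are excluded: sample sizes
below that make both the ensemble cross-validation and the occupancy-grid
bandwidths unstable.

## Predictor screening

A preliminary regularized logistic model fitted on the native presences and
one pseudo-absence replicate scores each climate variable by permutation
importance: IV(v) = 1 − mean over 5 iterations of the Pearson correlation
between predictions on the intact data and predictions after shuffling
column v, clipped to [0, 1]. The collinearity filter then repeatedly takes
the not-yet-resolved pair with the largest |r| ≥ 0.7 and drops its lower-IV
member; resolving the worst pair first is deterministic and removes the
strongest redundancy before weaker ones. Ties on IV are broken by variable
name. Correlations are Pearson only when both variables of a pair pass a
Shapiro–Wilk normality test at α = 0.05 (subsampled to 5000 values, above
which the test loses calibration), Spearman otherwise — the normality check
is applied per pair, both members having to pass.

## Ensemble suitability models

Each population's model is an ensemble over five algorithm families —
regularized logistic regression, logistic with full quadratic expansion,
random forest, gradient-boosted trees, and a rectilinear 5–95 % percentile
climate envelope whose per-variable scores decline linearly outside the
envelope and multiply. Pseudo-absences equal the presence count (minimum
1000) and are drawn uniformly without replacement from cells holding no
presence, in five replicates by default. Every (algorithm × replicate)
member is evaluated by stratified 5-fold cross-validation; its AUC (rank
form, ties counted ½) and TSS (at the fold's MSS threshold) are averaged
over folds. Members failing either gate — AUC < 0.8 or TSS < 0.6 — get
weight zero; survivors are combined with weights proportional to their CV
TSS. The consensus surface is the weighted mean of member scores, and the
final MSS threshold is computed on the pooled presences plus all
pseudo-absence replicates scored by the consensus. Candidate thresholds are
midpoints between consecutive distinct scores plus the extremes; ties go to
the lowest maximiser. Range areas use spherical cell areas
(R·Δλ)(R·Δφ)cos φ with R = 6371 km.

**A property of MSS ranges worth knowing.** The MSS threshold sits near the
suitability level where the presence and background score densities cross —
roughly the landscape-mean suitability — which is *below* the half-peak
contour of a Gaussian niche. Binary ranges are therefore permissive: in the
virtual-species experiments they contain essentially the whole half-peak
niche core (recall ≥ 0.9) but cover about twice its area. Comparisons built
on *two* such ranges (RRI, RSI) are unaffected, since both populations carry
the same bias; absolute range areas should be read with this in mind.

## Niche dynamics (COUE)

A PCA is calibrated on the pooled, centred, unit-scaled background climates
of both ranges, and occurrences and backgrounds are projected onto the first
two axes. Occupancy surfaces are estimated on a 100 × 100 lattice spanning
the pooled background extent plus a 5 % margin: occurrence and background
point sets are histogrammed and smoothed with a truncated Gaussian kernel
(normal-reference bandwidth per axis computed from the occurrence scores,
truncated at 4 bandwidths so the support is compact), and the occupancy is
the ratio occurrence/background density where background mass exists, scaled
to a maximum of 1. Using the *same* bandwidth for both fields makes the
availability correction cancel kernel edge attenuation. A cell is "occupied"
when z > 0 (the compact kernel makes exact zeros attainable); the floor is
configurable to exclude marginal climates.

Expansion is the fraction of introduced occupancy mass in cells not occupied
by the native niche; stability its complement (E + S = 1); unfilling the
fraction of native mass outside the introduced niche. Niche breadths NBN and
NBI are occupied-cell counts times cell area, NBS the doubly-occupied count,
giving NBR = NBI/NBN and the Sørensen-style NSI = 2·NBS/(NBI + NBN) ∈ [0, 1].
Niche conservatism is rejected exactly when the introduced niche is both
wider (NBR > 1) and positionally dissimilar (NSI < 0.5). The centroid shift
is the Euclidean distance between z-weighted centroids in axis units — the
natural summary of positional displacement in this space; the dominant
("top") predictor is the variable with the largest |loading| on axis 1 (ties
by axis 2, then name).

## Range dynamics

RN, RI and RS are the areas of the native range, introduced range and their
cellwise conjunction; RRI = RI/RN, RSI = 2·RS/(RI + RN). Range conservatism
holds when RRI < 1 or RSI > 0.5. The expanding range is introduced ∧ ¬native.
Range centroid shifts are great-circle distances between area-weighted mask
centroids; cross-species overlap maps are cellwise counts over a common
lattice.

## Cross-species synthesis

The study table carries one record per species (TPSR, NBR, NSI, RRI, RSI,
verdicts, COUE fractions, areas). Summary statistics: conservatism and
index-threshold counts; paired two-sided *t*-tests comparing RRI with NBR
within the NBR > 1 and NBR < 1 groups (NBR exactly 1 joins neither group)
and RSI with NSI over all species, with zero-variance differences reported
as p = 1; TPSR-consistency percentages (strictly TPSR > 1 within the
NBR > 1 and RRI > 1 groups); and normality-gated correlations among the
indices. Bypass mode ingests a pre-computed index table and recomputes
verdicts and all summaries, so this stage is verifiable independently of the
spatial stages.

## Virtual species: what the validation shows

The generator produces smooth random climate fields (white noise convolved
with a Gaussian kernel, optional latitudinal gradient, rescaled per
variable) and a Gaussian suitability surface in environment space —
s(x) = peak · exp(−½ (e−μ)ᵀΣ⁻¹(e−μ)) — from which presences are drawn
i.i.d. proportional to suitability, one record at the drawn cell's centre
(duplicates possible, as in real compilations; rarefaction collapses them).
The introduced population's niche is the native one displaced by a chosen
Mahalanobis magnitude — applied isotropically across variables, so the
displacement's projection onto the measured two-axis niche space does not
depend on any single variable's PCA loading — and scaled in breadth.

Validation conditions (chosen once): 64 × 64 landscapes of six variables at
0.1° resolution near the equator, niche sd one half of the landscape sd per
variable, 1000 presences per population, two pseudo-absence replicates.
Under these conditions a zero-shift species is recovered as conserved (NSI
and RSI above 0.85, E and U near 0, both verdicts "supported", ensemble CV
clearing the 0.8/0.6 gates), a doubled-breadth species yields NBR ≈ 2 in
the 2-D niche plane, and mean NSI decreases strictly along a 0/1σ/3σ
injected-shift ladder when each rung is averaged over three landscapes and
six replicate samples (the replication marginalises landscape-specific
projection geometry and support-estimation noise; a single draw at the 1σ
rung can sit within noise of zero shift).

What this does *not* show: the generator's fields are stationary,
independent across variables and free of the spatial sampling bias,
taxonomic error and dispersal limitation that real occurrence compilations
carry; real climates are strongly cross-correlated (which the collinearity
filter exists for) and real niches need not be Gaussian or stationary
between ranges. Passing these tests demonstrates internal consistency and
parameter recovery, not field accuracy.

## Degenerate inputs and numeric conventions

All-identical occurrence scores raise a degenerate-bandwidth error rather
than producing a zero-width kernel; empty niches, empty masks and zero
native breadth/range raise explicit errors instead of NaNs. Constancy checks
use exact range (ptp = 0), not floating-point standard deviations.
Stage-level seeds are derived from one global seed by stable hashing, so any
stage can be re-run alone with identical output; every pipeline stage writes
a manifest with parameters, seed and SHA-256 output hashes.

## Limitations

The calibration area is whatever climate stack is supplied; no
accessibility (dispersal) masking is applied, which inflates apparent
discrimination when the stack is much larger than the reachable region.
Ensemble membership is a five-family reduction of the broader algorithm
zoo used in large ENM platforms. Occupancy-grid breadths are area-based
(occupied-cell counts); density-weighted breadth definitions would change
NBR for strongly peaked niches. No niche equivalency/similarity permutation
tests are included.
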