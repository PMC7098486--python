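# Methods

This note documents the models implemented in `ubquant`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Mass model

Monoisotopic masses come from the IUPAC/NIST atomic-mass table shipped
with pyteomics; the proton is 1.007276 Da. Compositions admit fixed
isotope labels (`C[13]`, `N[15]`) for isobaric tags. Aggregated isotope
distributions are computed by exact per-element convolution
(exponentiation by squaring, truncated at `n_peaks`), tracking both the
abundance and the abundance-weighted centroid mass of each nominal
isotopologue; this matters at 8.5 kDa, where the mean peak spacing
(~1.0029 Da, a blend of ¹³C with minor ¹⁵N/¹⁸O contributions) differs
from the pure ¹³C spacing by enough to accumulate several mDa across an
envelope.

Printed modification deltas (+114.0429 diGLY, +79.966 phospho, +229.163
TMT, +57.021 carbamidomethyl, +15.995 oxidation, +0.984 deamidation) are
kept for reporting; full-precision composition masses are used in
arithmetic. The bundled modification table validates each printed delta
against its composition to 1 mDa.

Ub^ΔGG is human ubiquitin residues 1–74 (the protease clips after R74,
removing Gly75–Gly76). Proteoform identity is (branch count, pS65 state)
only: intact mass cannot distinguish which of the seven lysines
(K6/K11/K27/K29/K33/K48/K63) carries a branch, so branch positions are
deliberately not modeled. The quantified candidate list spans 0–3
branches × ±phospho (8 species); the type itself allows up to 7 branches.

The averagine model uses the Senko average-residue unit scaled to the
target mass, heavy elements rounded, sulfur dropped in sulfur-free mode,
and hydrogens adjusted so the monoisotopic mass lands within 0.5 Da.
Distributions are cached at 1 Da mass quantization — the envelope shape
changes negligibly over that scale.

## Spectrum simulation

Profile spectra are rendered on a uniform m/z grid (default step: finest
FWHM / 5) over 625–925 m/z with resolving power 60,000 at m/z 200 scaling
as 1/√(m/z). Each proteoform contributes Gaussian peaks at every charge
state whose full envelope fits the window, weighted by a discretized
Gaussian charge envelope (mean z = 12, σ = 1.2, truncated at z = 17) that
is renormalized over the usable charges, and by a Gaussian elution
profile over 5 scans (σ = 1 scan). Renormalizing the charge envelope
makes each species' total rendered area exactly fraction × total
intensity, which keeps the round-trip tests closed-form. Noise, when
enabled, is additive Gaussian scaled to a fraction of the base peak;
multiplicative log-normal noise is used for TMT channels, blots, and PRM
areas — the standard error structures of those measurements.

The two bundled compositions fix the phosphoproteoform fractions at their
published values (depolarized HeLa, 1 h: 12% / 1.42% / 0.05% for 0/1/2
branches; depolarized neurons, 6 h: 5.5% / 0.27% for 0/1 branches).
The unphosphorylated complements are not published; they are realistic
fills, chosen once, summing to 1 (file `simulate.py`).

## Deconvolution

Peak picking finds local maxima above `sn_threshold` × a robust noise
floor (1.4826 × MAD) and refines apexes with a 3-point parabola in log
intensity (exact for Gaussians). Deisotoping is greedy,
highest-intensity-first: for each seed centroid, every charge up to 17 is
scored by the normalized dot product between the observed heights and the
sulfur-free averagine envelope at the implied neutral mass, and — because
adjacent isotopologues near 8.5 kDa can be almost equally abundant — the
seed-to-apex alignment is also scanned over ±2 isotopologues. The best
alignment with fit ≥ 0.80 is accepted; fitted peaks are subtracted, and
residuals above 25% of the original centroid intensity are re-queued.
The vendor semantics of "fit factor" and "remainder" are proprietary;
the thresholds are preserved on this explicit metric.

The monoisotopic mass is the fitted-abundance-weighted mean over matched
isotopologues, each mapped to the k = 0 position through the theoretical
centroid offsets (accuracy ~1 mDa on noise-free input; the acceptance
bound is 10 mDa). Cluster area is analytic: Gaussian height × σ(m/z) ×
√(2π), summed over the envelope, using observed heights where a centroid
matched and fitted heights for unmatched tail isotopologues. Using
observed heights removes a ~1% systematic deficit that the pure
projection would introduce (the averagine shape is a template, not the
exact composition). Species are merged across charges when neutral masses
agree (descending intensity, ties to the lower charge), then across scans
within the 0.5 Da assignment tolerance. Proteoform fractions are reported
both relative to total deconvolved area (assigned + unassigned = 1) and
renormalized over assigned candidates; percentages quote the latter,
which is how relative proteoform abundance is conventionally reported.
The neutral-mass search range defaults to the vendor setting
(189–2000 Da) and is widened to 8000–9000 Da for Ub work.

## TMT layers

Filters are literal "less than" exclusions, so values at the thresholds
(specificity 0.7, summed S/N 150) are retained. Rollup sums reporter S/N
across matching PSMs; site-level rollup keys on (protein, 1-based
residue, modification type) — diGLY and phospho layers can never merge —
and keeps only localized sites (AScore ≥ 13). Peptides mapping to several
proteins are resolved by simple parsimony (most-quantified protein, ties
alphabetical); full protein-assembly parsimony is upstream of this
package's scope. Missing values are explicit (NaN) and excluded from
column sums: summed-S/N pipelines treat absent channels as missing, not
zero.

Equal-loading normalization scales each channel to the mean column sum.
Site-to-protein normalization divides a site's channel vector by its
protein's relative profile (protein vector / its own mean), flags sites
whose protein was not quantified as `unnormalized`, and converts
zero-protein channels to missing. Time courses divide each channel by the
mean of its genotype's untreated channels and error out if a genotype has
none.

The default 11-plex layout is WT-UT×3, WT-2h×2, WT-6h×3, S65A-6h×3 —
chosen so the primary untreated-versus-6 h contrast has triplicates in
both arms; the 10-plex layout is a WT / USP30-null 0–4 h time course with
one channel per point. The generator guarantees each simulated feature
one clean PSM (quality-violating PSMs are contamination on top), because
the feature set emulates peptides that were quantified; violation counts
in the ground truth are exact draws, so filter audits can be checked
against them.

## Statistics

The moderated statistic is Tusher-style: S0 is an additive constant in
the denominator of Welch's t on log2 data. p values use the
Welch–Satterthwaite degrees of freedom of the *unmodified* standard
error, so s0 = 0 reduces exactly to classical Welch (tested to 1e-12
against scipy). Features are complete-case per row; arms need n ≥ 2.

Permutation FDR enumerates all label assignments when C(n, n_A) ≤ 1000
(always true for the plex designs here) and otherwise samples 250
distinct assignments with a fixed seed. The FDR estimate at a cutoff is
the median permuted exceedance count divided by the observed count — the
robust SAM variant — with no π₀ correction, which keeps the estimate
conservative. The significant set is the largest one with estimated
FDR ≤ the level, found by walking the observed |d| values from the most
extreme downward and stopping at the first violation.

Organelle shifts use a two-sided one-sample t test of each class's mean
log2 ratio against zero with Benjamini–Hochberg correction across
classes; the choice of the one-sample test is an assumption documented
here, and single-member classes are never significant.

## Flux and PRM

The image equation multiplies the red-only mask area, the mask's percent
share of the field, 0.01, and the mean masked intensity; percent area is
interpreted as the masked fraction in percent units, which is what makes
the ×0.01 dimensionally sensible. Per-soma values are normalized by the
untreated-condition mean (division per value, before any averaging).
Blot backgrounds are subtracted per lane — standard quantitative-blot
practice. PRM assumes light and heavy areas are already comparable
(peptide oxidation equalization is a wet-lab step) and propagates errors
to stoichiometries at first order. With only two peptides per protein the
SEM is itself noisy; tests therefore check recovered ratios against an
absolute 0.02 band at 2% area CV rather than trusting a 2-point SEM.

## What the generators do and do not emulate

They reproduce the statistical structure the analyses rely on: isotopic
fine structure and charge envelopes at the stated resolving power,
chromatographic elution, reporter-ion noise and quality-attribute
distributions, planted differential effects with genotype attenuation,
band and punctum structure, and light/heavy area ratios. They do not
simulate chimeric MS2 spectra, the mechanism of co-isolation interference
(only its scalar specificity attribute), retention-time structure,
peptide-level sequence effects, or microscope optics. Passing round-trip
tests therefore demonstrates correctness and calibration of the
*quantification and statistics*, not robustness to every artifact of real
acquisitions.

## Problem sizes and determinism

Defaults are sized for interactive use: 5-scan runs with ~80k-point
grids deconvolve in under a second; the 2,400-feature 11-plex simulation
with exhaustive (20-permutation) FDR runs in ~10 s; calibration uses
1,000 features × 3 seeds. Every generator takes an explicit seed, the
pipeline derives stage seeds from the global one by fixed offsets, and
identical (config, seed) pairs produce byte-identical outputs.

## Known limitations

- The deisotoper assumes isotopologue-resolved clusters; it is not meant
  for unresolved (low-resolution) envelopes.
- Charge-envelope weights are shared across proteoforms, although real
  phospho species shift their charge distribution slightly; fractions are
  ratios of totals, so this does not bias recovery in the simulation but
  is a simplification of the instrument physics.
- The FDR walk assumes the significant region is a contiguous tail in
  |d|, the standard SAM convention.
- `check_acceptance` compares scalar values with absolute tolerances
  only.
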