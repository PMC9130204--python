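# Methods

This note records the models behind `echoscape`, the defaults that matter,
and the choices made where the design was genuinely open.

## Acoustic quantities

Echograms are ping × depth-bin matrices of volume backscattering strength
Sv (dB re 1 m⁻¹). Depth bins are half-open `[top, bottom)`; a bin belongs
to the water column while its top edge lies above the bottom line minus one
bin, so the bottom-echo cell itself is never integrated. Echo-integration
of a cell mask gives the Nautical Area Scattering Coefficient per ping,

    s_A = 4π · 1852² · Σ 10^(Sv/10) · Δz     [m² nmi⁻²],

and the per-ESDU s_A is the **mean** of per-ping s_A over each consecutive
25 m of along-track distance (a mean, not a sum, keeps the unit independent
of ping rate and ESDU length; a trailing segment shorter than half an ESDU
is merged into its predecessor). Only the 70-kHz channel is integrated and
propagated downstream; the 200-kHz channel serves classification.

### Two-frequency classification

A water-column cell whose stronger channel exceeds `sv_min_db` (−70 dB
default) is a scatterer. It is *fish-like* when (i) the bi-frequency sum
Sv70 + Sv200 lies inside configured bounds, (ii) |Sv70 − Sv200| is at most
the homogeneity threshold (3 dB default — swimbladdered fish well above
resonance backscatter almost equally at 70 and 200 kHz), and (iii) the
local Sv variance (5 × 5-cell window, both channels) lies inside its
bounds; otherwise it is *no-fish*. All thresholds are configuration: the
defaults were calibrated on the synthetic generator, and the variance bound
ships open (0, ∞) — the mechanism is in place but survey-specific values
must come from scrutinised echograms. Using the element-wise *maximum* of
the two channels for the Sv floor keeps the classifier symmetric under
swapping the frequency arguments.

## Survey pooling

Records are gridded to 100-m pixels anchored at the data bounding-box
corner. Inter-survey differences are taken between pixel means of
log10(s_A + 1) in pixels visited by both surveys; intra-survey differences
between same-pixel records at least one hour apart. Pooling is approved iff

    |median(inter)| ≤ k · IQR(intra)   and   IQR(inter) ≤ m · IQR(intra)

with defaults k = 0.5, m = 1.5. Survey practice often judges such
difference distributions visually; this rule is a reproducible
operationalisation and both constants are exposed.

## Unfolding and kriging

Around an island, "north–south" means nothing; the relevant directions are
along-coast and cross-shore. The annulus between coastline and offshore
boundary is covered by a closed ring of trapezes: inner corners partition
the coastline into arcs of equal length, outer corners are found by
shooting the outward coast normal onto the offshore boundary (falling back
to nearest-point projection, then to centroid rays if the normals cross).
Within a trapeze, inverse-bilinear coordinates give t ∈ [0, 1]
(coast → offshore) and a base fraction; the along-coast coordinate s adds
the cumulative inner-base length. The map is bijective; where the curved
boundaries bulge past the trapezes' straight chords, points are assigned to
the nearest trapeze and the bilinear map extrapolates exactly (round-trip
error stays at machine precision, verified to 10⁻⁶ of the domain diameter
over three geometries). When two preimages exist in a skewed quadrilateral,
the root whose forward image returns to the point (and lies in [0, 1]²) is
kept.

Before kriging, data from the last trapeze are duplicated below s = 0 and
data from the first trapeze beyond the total base length, so interpolation
sees across the ring seam. The cross-shore coordinate is scaled by the mean
annulus width so a single isotropic variogram applies to both axes
(geometric anisotropy between s and t can instead be expressed through
separate ranges).

Variograms use the Matheron estimator binned by distance and are fitted by
weighted least squares (weights = pair counts) over the spherical,
exponential and Gaussian families (practical-range convention); the family
with the lowest weighted residual wins. Interpolation is ordinary kriging
(weights sum to one) with a moving neighbourhood of the 32 nearest points,
solved per cell from the bordered semivariance system; duplicate data
locations are dropped with a warning. Maps use 55 m × 44 m cells, masked
outside the annulus, and are folded back to geographic space. Kriging is
performed on log10(s_A + 1) and mapped on that scale without back-transform
bias correction.

## Non-linear biomass estimation

Acoustic densities of schooling fish are mostly zeros plus a heavy right
tail, which makes a directly kriged mean fragile. The estimator:

1. **Indicator coding.** Five disjunctive classes — exact zeros, then the
   right-closed ]0–33], ]33–66], ]66–95], ]95–100] % quantile intervals of
   the *positive* values (a value equal to a cut joins the lower class).
   Each record's indicators sum to one, so the coding has rank 4.
2. **MAF transform.** The lag-0 covariance of the centred indicators is
   eigen-truncated (dropping the void sum direction) and used to whiten;
   the half mean squared increment matrix at a short lag h (default twice
   the median nearest-neighbour distance, tolerance h/2) is then
   diagonalised in the whitened space. The resulting factors have unit
   variance, are **exactly** uncorrelated at lag 0 on the fitting data and
   empirically uncorrelated at lag h, and are ordered by increasing lag-h
   increment semivariance (most spatially continuous first). The transform
   is stored with its pseudo-inverse.
3. **Global kriging per factor.** Each factor is kriged *globally* over the
   species polygon (discretised to ~900 interior points): the bordered
   system with point-to-domain mean semivariances yields the polygon-mean
   estimate and its estimation variance; the within-domain mean
   semivariance closes the variance term. Factors are treated independently
   — justified by their decorrelation at short lags and assumed beyond.
4. **Recombination.** The pseudo-inverse maps factor means back to
   indicator means (their sum-to-one closure is automatic because the
   inverse lands in the centred subspace); the global mean s_A is the
   class-mean weighted sum, and its variance propagates linearly assuming
   independent factor errors. Estimated indicator means are clipped to
   [0, 1] with a warning if they stray.
5. **Conversion.** Biomass = mean s_A × Surface × W / (1852² × 4π ×
   10^(TS/10)), in tonnes; the defaults W = 485 g and TS = −39.3 dB re 1 m²
   are the black triggerfish values (27.8-cm fish at 70 kHz). The CV of the
   biomass equals the CV of the mean s_A; surface, W and TS enter as
   constants, so weight- and TS-uncertainty are *not* in the reported CV.

The class-mean recombination ignores within-class dispersion of the top
class, whose mean is estimated from few records; this term is not in the
variance either. The coverage study below shows the net effect is mild at
the simulated sampling densities.

## Synthetic scenes

The generator emulates the study conditions end-to-end:

- **Geometry.** Elliptical coastline (default 1500 × 1000 m semi-axes)
  inside an elliptical offshore boundary (3500 × 2800 m), optionally
  perturbed by low-order harmonics; a no-take MPA sector covering 70% of
  the coastline out to the 50-m isobath; windward = eastern half (ties go
  windward).
- **Bathymetry.** Linear shelf from 5 m at the coast to 60 m at 60% of the
  cross-shore span, then a steeper power-law shelf-break to 120 m.
- **Field.** s_A = exp(log-Gaussian field) × spatially-correlated Bernoulli
  presence × windward multiplier. Defaults: median 200 m² nmi⁻² where
  present, log-variance 1, practical ranges 400/500 m, presence 0.4,
  windward factor 3 — a strongly right-skewed, zero-inflated surface, the
  regime the indicator estimator exists for. Gaussian random fields are
  generated by Gaussian-kernel smoothing of white noise on a 50-m grid
  (Gaussian covariance, σ = range/(2√3)), normalised to unit variance and
  interpolated bilinearly; all draws derive from the scene seed.
- **Survey.** Radial coast-to-offshore transects at equal bearings, pings
  every 2.5 m (2.5 m s⁻¹ × 1 s), 25-m ESDUs, 100-m acquisition range on the
  shelf. The fast point-sampler adds multiplicative lognormal observation
  noise (SD 0.15 in log10) and a ~30-m lateral jitter per pass, because
  repeat passes never steam exactly the same line.
- **Echograms.** Fish schools are 5-m-thick bands centred at 60% of the
  bottom depth whose linear sv integrates exactly to the field's s_A at the
  ping, responding identically at both frequencies; a non-fish layer
  occupies 4–12 m with a configured inter-frequency offset (12 dB default);
  an additive noise floor at −90 dB and 0.5-dB Gaussian noise ride on
  everything. Where school and layer bands overlap the school takes
  precedence. "SNR" in the validation studies means the margin between the
  school Sv at the median field intensity and the detection threshold.
- **Video.** Per-taxon Poisson event streams with 1 + Poisson count marks
  and piecewise-constant sediment segments from the nine-code vocabulary.

What the generator does **not** emulate: frequency-dependent target
strength beyond a class offset, school morphology and avoidance, tides and
currents, beam geometry, bottom-detection error, and visibility limits of
real video. Passing tests therefore demonstrate the correctness of the
*algorithms* under the stated statistical conditions, not field performance
on any real survey.

## Validation studies (scripts/acceptance.py)

- **Coverage.** 100 replicates; each simulates a zero-inflated exponential-
  covariance field jointly at ~400 ESDU points (10 transects, 2 × 2 km) and
  a 24 × 24 truth grid by Cholesky, runs indicator → MAF → per-factor WLS
  variograms → global kriging → recombination → conversion, and checks
  |estimate − realised truth| ≤ 2 estimated SD. Problem sizes were chosen
  to represent a realistic single-species survey at desk scale.
- **Classification.** Six transects at a 6-dB class offset and 10-dB SNR;
  recall per class and total classified-fish NASC against the ground-truth
  mask NASC *on the same echogram* (the shared noise-floor power cancels,
  isolating classification error).
- **Unfolding, MAF, kriging, merge** as described above, each at the sizes
  stated in the script.

## Depth strata, tests and tie-breaks

Strata are [0, 20), [20, 40), [40, 60), [60, 80), [80, 100] m (the last
closed); bottom depths beyond 100 m fall out of the scheme and are excluded
from strata comparisons. Group comparisons use Kruskal–Wallis followed by
all pairwise two-sided Wilcoxon rank-sum tests with Holm adjustment (no
correction is prescribed by convention; Holm is uniformly safe). Points on
the windward axis are windward; label-polygon overlaps resolve to the first
polygon listed; identical groups short-circuit to p = 1 to avoid degenerate
rank tests.

## Known limitations

- Global-kriging variance assumes the fitted variogram is correct;
  variogram uncertainty is not propagated.
- The merge rule's k and m have no inferential calibration; they encode
  "centred and comparable" pragmatically.
- The unfolded metric distorts distances where the annulus width varies
  strongly; the mean-width scaling is a first-order correction only.
- MaxN-family indices are conservative and saturate for large schools;
  TMaxN across videos can double-count individuals moving between video
  stations.
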