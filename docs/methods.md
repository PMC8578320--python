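# Methods

## The assay in brief

A protein at fixed final concentration (default 1 mg/mL) is mixed with
increasing concentrations of PEG in small wells (default 10 µL, 384-well
low-volume plate). After incubation and centrifugation, supernatant is
transferred to a prefilled UV-transparent measurement plate and full
absorbance spectra (220–700 nm) are recorded. The soluble concentration
falls sigmoidally with PEG; the inflection point PEG₁/₂ (% w/v) is the
relative-solubility readout.

## Titration planning

For each target PEG concentration the planner solves the exact volume
balance in a well of volume V:

* protein volume `v_p = V·c_final/c_stock` (mass conservation; 10/3 µL at
  the defaults),
* PEG volume `v_PEG = target·V/stock` from a chosen stock,
* buffer fills the remainder.

Arithmetic uses exact rationals, so conservation (volumes sum to V, realized
PEG equals target) holds identically, and the consumables report
(80 µL / 240 µg protein for the standard 12 × 2 run) is exact.

**Stock selection.** Of the stocks (default 15/30/50% w/v) the planner picks
the *lowest* concentration whose required volume both fits the non-protein
budget and exceeds the minimum pipettable volume (0.33 µL). Lower stocks
need larger volumes, and larger transfers of viscous PEG solutions are
pipetted more accurately, so this rule maximizes accuracy; it also makes any
"prefer larger volume" tie-break vacuous.

**Minimum-volume policy.** The 0.33 µL floor is enforced for PEG and protein
transfers — the accuracy-critical ones that set composition. The residual
buffer top-up may fall below it near the top of the range (a 33% target
leaves 1/15 µL of buffer): buffer volume only perturbs the total volume, a
≤0.3% effect on realized concentrations at the defaults, so such rows are
emitted rather than declared infeasible. Without this policy the documented
0–33% operating range would be unreachable.

**Achievable range.** `max_achievable_peg = max(stock)·(V − v_p)/V`: 33.3%
at the defaults, 45% when the protein stock is concentrated to 10 mg/mL
(1 µL protein per well), 50% in the protein-free limit.

**Supernatant transfer.** Each source well yields two 3 µL aliquots into
separate prefilled destination wells (doubling technical replicates: 4
measurement wells per concentration, 2 per blank), leaving ≥2 µL headroom
for evaporation losses. Worklists are CSVs ordered PEG → buffer → protein
(protein last so the incubation clock starts together), volumes to 0.001 µL.

## Spectral processing and QC

Spectra are smoothed per well with a Savitzky–Golay filter before anything
else (window 11 points, polynomial order 3, mirror edges; both
configurable). The filter passes polynomials up to its order, so plateaus
and gentle bands are preserved while uncorrelated read noise is attenuated.
Outlier criteria are applied to the smoothed spectra (a switch allows raw).

Two criteria flag wells distorted by bubbles or debris rather than by
precipitation: |A310 − µ| > 4σ, or the 350–400 nm band mean (inclusive
endpoints, arithmetic mean over grid points) more than 7σ from its reference
mean. Values exactly at the boundary are inside (a 1e-12 AU float guard
keeps boundary constructions stable). Reference µ/σ are sample statistics
(n−1 denominator) pooled over all wells of a reference ensemble of runs.
**The shipped defaults come from the simulator's clean-plate ensemble and
must be recompiled (`pegsolve qc-ref`) against your own instrument before
analyzing real data** — the criteria were designed around pooling several
real experiments.

The dye-titration check fits fluorescence = α + β·PEG by least squares;
each point's realized PEG is (F − α)/β and its error |realized − expected|
is reported in % w/v with the median as the headline accuracy figure.

## Quantification

Soluble concentration from a blanked spectrum follows Beer–Lambert with a
plain scattering correction:

    c = (A280 − A340) / (ε·l) · D

ε (AU per mg/mL per cm) comes from the sequence, l is the optical path
(default 0.4 cm; it must reflect the actual fill height), and D is the
dilution from supernatant to measurement well, default 16/6 following the
two-aliquot prefill convention. D is a plain configurable constant: set it
to (prefill + transferred)/transferred for your actual geometry (a single
3 µL aliquot into 10 µL prefill is 13/3). Blanks are matched by PEG
concentration (PEG scatters slightly in the UV at high concentrations); a
pooled-blank fallback and single-shared-blank mode exist because PEG does
not absorb at 280 nm. Negative corrected absorbances clamp to zero with a
warning — soluble protein cannot be negative. Turbidity is blanked A500 and
can drive the same curve/fit machinery (`readout="turbidity"`), though it is
the noisier readout, particularly for small proteins.

Curves require ≥4 surviving PEG concentrations; flagged wells are excluded
and counted per point, and a point whose wells are all flagged is dropped
with a warning.

## Sigmoid fit and uncertainty

The model is the four-parameter logistic above with s > 0 encoding a
decreasing curve (bound-constrained). Fitting is trust-region least squares
(`scipy.optimize.least_squares`, trf) with analytic Jacobian, tolerances
1e-10, at most 2000 evaluations. Initial guesses: a = max(y), b = min(y),
PEG₁/₂ = x nearest the mid-drop, s = 4/(x-width of the 10–90% drop).
Exactly flat data raise a "no transition detected" error; non-convergence
returns best-effort parameters flagged `converged=False`.

After the initial fit the data are normalized by the plateaus,
y′ = (y − b)/(a − b), and refit with plateaus fixed at 1/0. PEG₁/₂ is
invariant under affine scaling of y, so normalization changes the units,
not the answer.

**Bootstrap.** 95% intervals on PEG₁/₂ and s use 500 percentile-bootstrap
cycles (case resampling), seeded and reproducible. Two properties of the
small-replicate design required care:

1. *Blank-error resampling.* The blank mean subtracted from every sample
   well of a concentration is itself estimated from (typically 2) blank
   wells; its error is common to the whole point and invisible to
   sample-well resampling. Blank wells are therefore resampled as cases
   alongside sample wells.
2. *t correction.* With n ≈ 4 wells per point the bootstrap estimates each
   point's variance on ~3 degrees of freedom; a raw percentile interval then
   behaves like a z-interval where a t-interval is required and undercovers
   (≈0.85 observed). Resampled means carry the √(n/(n−1)) scale correction,
   and interval deviations from the point estimate are scaled by t/z at the
   Welch–Satterthwaite effective degrees of freedom of the design
   (sensitivity-weighted via the linearized fit).

With both corrections the empirical coverage at the standard design and
noise level is ≈0.92 (200 simulated assays, 200 cycles). Intervals are
widened if needed to contain the point estimate. When replicate information
is absent the bootstrap falls back to residual resampling with a t
correction on n_points − 2 degrees of freedom.

**Known limitation — steep curves on a coarse grid.** With 3%-spaced PEG
targets and a steep transition (s ≳ 2), an inflection point falling between
grid points is bounded but not well localized by the data: the estimate
acquires an irreducible bias of up to ~0.2% w/v that no resampling scheme
can see, and interval coverage degrades (≈0.70 observed at s ∈ [2,3] with
randomly placed truths). This is a property of the design, not the
estimator; the remedy is the assay's own guidance — concentrate PEG targets
around the expected transition when slopes are steep.

**Derived quantities.** The onset is the intersection of the inflection
tangent with the upper plateau; on this parameterization the tangent slope
is −s(a−b)/4, giving onset = PEG₁/₂ − 2/s independent of the plateaus. The
apparent absolute solubility extrapolates ln(c) linearly over transition
points (fitted drop fraction within 20–80%, window configurable; strictly
positive measured values; ≥3 points) to 0% PEG. A ±10% error on a single
transition point moves this extrapolation by far more than 10%; it is
reported as *apparent* and should be treated as qualitative.

## The plate simulator

The simulator emulates the measurement plate of a full run with known
ground truth, using the same planning code for geometry and the same
optical constants as quantification, so the noiseless pipeline inverts it
exactly:

* true soluble concentration `c(x) = c0/(1 + exp(s(x − PEG₁/₂)))`
  (the fit's own family with a = c0, b = 0), scaled by 1/(1 − evaporation);
* protein band: unit-peak truncated Gaussian at 280 nm (σ = 14 nm, compact
  support ±55 nm) scaled by ε·l·c. Truncation makes the protein contribute
  exactly nothing at the 340 nm correction or in the 350–400 nm QC band, so
  the scattering correction is unbiased in the noiseless limit;
* PEG scattering baseline: 0.002 AU per % PEG at 400 nm, scaling as λ⁻⁴,
  identical in samples and blanks at the same concentration (cancels on
  blanking);
* bubble artifacts (probability `bubble_rate` per well): a broad λ⁻²
  scattering offset of 0.8 AU at 310 nm, sized to violate both QC bands by
  construction;
* noise: additive i.i.d. Gaussian read noise per wavelength (default
  0.002 AU) plus multiplicative per-well concentration noise (default 3%,
  the pipetting/path-length variability the assay reports as its working
  noise level).

Defaults (12 concentrations 0–33%, 2 replicates + 1 blank, two 3 µL
transfers each, c0 = 1 mg/mL) are the assay's standard operating conditions
and are also the conditions of the statistical tests: parameter recovery
(median |PEG₁/₂ error| ≤ 0.3% w/v over 100 assays), bootstrap coverage
(within [0.90, 0.99] over 200 assays at 200 cycles), and QC discrimination
(sensitivity ≥ 0.9, false-positive rate ≤ 0.05 on injected bubbles). These
problem sizes keep the suite comfortably fast while leaving the Monte-Carlo
error well below the margins tested.

What the simulator does **not** model: PEG–protein interactions and
excluded-volume thermodynamics (the sigmoid is imposed, not derived),
instrument drift, condensation, well-to-well path-length gradients,
non-Gaussian artifact shapes, and kinetic effects of incubation time.
Passing tests therefore demonstrate the correctness of the computational
chain under its stated noise model, not the biophysical fidelity of any
instrument.

## Interfaces

Worklists: CSV `step,source_labware,source_well,dest_labware,dest_well,volume_ul,reagent`.
Layout: CSV `well,role,peg_pct,replicate,protein_id`. Spectra: long CSV
`well,wavelength_nm,absorbance` or wide (wells × wavelengths). Fit results:
JSON with `a,b,s,peg_half,ci95_peg_half,ci95_s,rss,n_boot,converged` plus
onset and apparent solubility. All CLI outputs embed the seed and a config
hash; identical config and inputs produce identical outputs.
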