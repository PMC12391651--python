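# Methods

This note records the models implemented in `tchasim`, their
assumptions, the parameters that matter, and the deliberate design
choices — in the spirit of a model-description appendix.

## Tether reach (freely jointed chain)

The flexible polymer linker is `NS` rigid dsDNA rods of length
`a` joined by ssDNA hinges. Because each 45 bp rod (15.3 nm at
0.34 nm/bp) is much shorter than the ~50 nm dsDNA persistence length,
and ssDNA hinges are much shorter than their own <1 nm persistence
length would require for stiffness, the chain is treated as freely
jointed. The analytic radial end-to-end density uses the Gaussian-chain
(large-`N` random-walk) limit

    P(r) = 4πr² (3 / 2πNa²)^{3/2} exp(−3r² / 2Na²),

whose mode is `a·√(2N/3)`. This approximation is used even at `N = 5`,
where it is still accurate to a Kolmogorov–Smirnov distance of ~0.027
against the exact chain; at `N = 1` it is qualitatively wrong (the
exact chain is a delta at `r = a`) and is never quoted. The exact-FJC
Monte-Carlo sampler (sum of `N` isotropic unit vectors) is kept as the
physical oracle, and the tests assert both the agreement at `N ≥ 5` and
the deliberate disagreement at `N = 1`. The full-space density is used;
whether the sensor wall (a reflecting half-space) should fold the
distribution is left out because the unreflected form reproduces the
reference reach numbers.

Two rod-length values coexist on purpose: `rod_length(45, 0.34) =
15.3 nm` is the exact design value, while the headline reach numbers
(mode 27/37 nm, FWHM 32/42 nm for `NS` = 5/9) are computed with the
rounded `a = 15 nm`; only that value gives the conventional FWHM
figures. The reach *area* squares the mode **after** rounding it to the
nearest nanometre (`π·27² ≈ 2.3·10³ nm²`, `π·37² ≈ 4.3·10³ nm²`) —
a reporting convention, kept because the capacity figures (95 and 178
binder molecules at 24.1 nm² each, round-half-up) follow from it.

## Surface sites

Binding-site density is a pure unit conversion of the measured surface
mass density: `Γ / MW · N_A`, giving 4.16·10⁻² nm⁻² (24.1 nm² per
molecule, ~4.9 nm spacing) for 4.14 ng mm⁻² of 60 kDa neutravidin. All
binding pockets are treated as occupied and monovalent — the tetramer's
four biotin pockets are not modelled, matching how the reference
figures are computed. Tether anchors occupy a molar fraction of sites
equal to the tether:filler solution ratio (10⁻⁵ by default → ~4.2·10³
anchors max on the 100×100 µm footprint) and are placed as a
homogeneous Poisson point process; at ≤10⁻³ site occupancy, hard-disc
exclusion between anchors is negligible and is omitted.

## Transport

Capture on the footprint uses the Lévêque thin-boundary-layer solution
for a perfectly absorbing wall in laminar shear flow; the strip
integral gives the prefactor `3^{1/3}/(2Γ(4/3)) ≈ 0.8075`. Assumptions:
capture is diffusion-limited (infinitely fast surface reaction), inlet
concentration is constant (the instrument recirculates the sample; the
depletion per pass is tiny), and depletion across the channel *height*
is neglected — the boundary-layer thickness `(9Dx/γ)^{1/3}` is checked
against `h/2` and reported with every estimate. The footprint's
upstream offset `x₀` along the capture-active surface is not fixed by
the instrument geometry; the default 5 mm reproduces the order of
magnitude of the reference capture estimates and is carried in the
config so results always state it. Diffusivities default to the
empirical dsDNA power law `D = 4.9·10⁻¹⁰·bp⁻⁰·⁷² m²/s` for DNA
constructs and Stokes–Einstein for globular species; both are
overridable. With these defaults the model gives 87 captured tether
constructs (10 fM, 30 min) and 5.5·10⁷ filler hairpins (1 nM) — within
a factor of 1.1–1.3 of the reference estimates, whose own internal
ratio is only order-of-magnitude consistent.

## Docking kinetics

The multi-step strand-displacement cascade (trigger opens the labelled
hairpin, the opened hairpin docks onto a filler hairpin, the trigger is
released) is collapsed into one effective pseudo-first-order docking
rate per free site, `k_on·c_HA`, with optional per-emitter loss `k_b`
(bleaching):

    dn/dt = k_on·c_HA·(C − n) − k_b·n,   0 ≤ n ≤ C.

The closed-form solution drives the deterministic mode; a Gillespie
birth–death realisation provides per-spot stochasticity. `k_on` is not
identifiable from published ensemble data; the default 10⁵ M⁻¹s⁻¹ makes
10 nM hairpin saturate in about an hour and 100 nM in under ten
minutes, matching the qualitative saturation times reported for those
two concentrations. It was fixed once on that basis. Spot-intensity
traces are summarised by a logistic fit (plateau, rate, midpoint) —
the conventional saturation description — and decay regimes by
`A·exp(−kt) + F₀`, initialised by log-linear regression and refined by
nonlinear least squares (tolerances 10⁻¹³).

## Synthetic frames

Frames are rendered at 0.2 µm/pixel (8 µm camera pixels through a 40×
objective) over the 100×100 µm field → 500×500 px, with an isotropic
Gaussian PSF of σ = 0.22 µm (≈0.21·λ_em/NA for λ_em = 670 nm and an
assumed NA of 0.65 — the objective's NA is not printed anywhere and is
a documented assumption). Pixel values are counts per second. Each
anchor adds a Gaussian of **peak** amplitude `emitters ×
counts_per_emitter` (total flux `amp·2πσ_px²`); the background is a
uniform 2400 cps with additive truncated-Gaussian noise of 120 cps
(camera-dominated regime; Poisson shot noise is available but off by
default).

`counts_per_emitter = 30 cps` and `background_sd = 120 cps` are the
forward model's two free calibration knobs — no instrument value pins
them. They are chosen for internal consistency: a saturated
~178-emitter spot then peaks ~5300 cps above the 2400 cps background,
and the 3000 cps counting threshold sits 5σ above background (blank
false-positive rate per frame ≈ 10⁻⁷ at the 2-pixel minimum area).
Per-anchor emitter counts are binomial around the mean-field occupancy,
capped by the tether's docking capacity; time stacks couple the
checkpoints through common per-site uniform draws so individual spot
traces are monotone while spots remain heterogeneous.

What the generator does *not* emulate: EMCCD gain statistics, the
~100 nm evanescent decay of the plasmonic enhancement (all tethered
emitters are enhanced equally), optical aberrations and flat-field
structure, drift between frames, and non-specific binding backgrounds.
Passing closed-loop tests therefore demonstrates the internal
consistency of the pipeline under an idealised camera model, not
robustness to real-image artefacts.

## Spot counting

The analysis mirrors the standard particle-analysis protocol: binarise
at a fixed absolute threshold (`pixel ≥ F_t`, boundary inclusive,
`F_t = 3000 cps`), label 8-connected components, reject components
smaller than 2 px, and report count (`NFS`), centroids, areas, peak and
integrated intensities. The threshold is intentionally absolute — the
readout is calibrated in cps and results must depend on the intensity
scale. On sparse synthetic fields (≤100 spots/field) the counter
recovers ground truth to within ~2% on average; residual losses are PSF
overlap merges. For stacks, spots are defined on the final frame (where
occupancy is highest) and per-frame maxima within each footprint give
the traces.

## Calibration and LOD

The dose–response is fitted as a straight line in log₁₀(c) vs
log₁₀(mean NFS) over concentrations that carry information in log space
(c > 0, mean NFS > 0). The LOD inverts the fitted line at the decision
level `NFS_b + 3σ` (blank mean plus three sample standard deviations)
in closed form. Two pipeline-level rules, both analysis-side:

* **Crowding exclusion.** Digital counting assumes sparse spots.
  Concentrations whose frames have more than 10% of pixels above
  threshold (or whose histogram mode reaches the threshold) are
  excluded from the fit — their counts undercount through merging —
  but still bound the dynamic range. The 10% limit is the same
  sparsity rule-of-thumb used for the transport site-limitation flag.
* **Decision-level floor.** Under the default camera model blank
  frames almost never count a spot, so `NFS_b + 3σ = 0`; the decision
  level is then floored at one spot, the smallest resolvable digital
  signal.

With the shipped defaults, a simulated 0.1 fM–1 pM series fits with
slope ≈ 0.8–1.1 (the forward model is linear; sub-linear slopes in
real calibrations reflect experimental compression the generator does
not model, and an efficiency-vs-concentration knob is deliberately not
shipped) and recovers the analytic capture-line/one-spot intersection
(~0.11 fM) within a factor of 2.

## Saturation boundary

At the 1 pM top of the range the forward model puts ~8.7·10³ spots on
the field: 47% of pixels exceed the threshold and connected-component
counting undercounts roughly tenfold — the spot-overlap ceiling. The
*histogram-mode* saturation flag (background peak at or above `F_t`),
however, only trips at ~4–5 pM in this model: above-threshold pixels
spread over a wide intensity range while sub-threshold pixels keep the
modal bin near 2400 cps, and the mode's position is insensitive to
spot brightness (the between-spot tail field scales with density, not
amplitude). The upper range reported by `dynamic_range` on a series
extending past 1 pM therefore lands at the first calibrator beyond the
overlap transition rather than exactly at 1 pM. This is a known,
documented divergence between the idealised additive-Gaussian frame
model and real dense-field images.

## Problem sizes

Defaults used by the test suite: Monte-Carlo sampler n = 10⁵–2·10⁵;
50 seeds per density for counting closure; 20 repeats × 5
concentrations × 3 frames for the end-to-end calibration study; 10³
Gillespie runs for occupancy bounds. These sizes give standard errors
comfortably inside the asserted tolerances while keeping the whole
suite under a minute on one core.
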