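# Methods

## The counting model

A two-color experiment is summarized by five integers: the total platelets
of each color over the surveyed fields (`n_red`, `n_green`; singlets plus
platelets bound in doublets) and the doublet counts by color class (`d_rr`,
`d_gg`, `d_rg`). Totals rather than singlets are the natural bookkeeping
because they satisfy the accounting identity `n = s + 2·d_same + d_rg`,
which the `FieldCounts` container enforces.

Two mechanisms create doublets. Incidental contact during mixing is
color-blind: conditional on a doublet being a contact pair, its class is
red-red, red-green or green-green with probabilities `r²`, `2rg`, `g²`
where `r = R/(R+G)`. Division creates same-color pairs only, because the
progeny stays adjacent to its parent in the viscous medium. Red-green
doublets are therefore a pure readout of the contact process, and the
expected contact contribution to the same-color classes follows from the
binomial ratio RR : RG = R₀ : 2G₀.

**Tail test.** Under the no-division null, `d_rg ~ Binomial(T, p)` with
`T = d_rr + d_gg + d_rg` and `p = 2RG/(R+G)²`. The reported probability is
the lower tail (a *deficit* of mixed doublets indicates division), computed
with the plain normal approximation and **no continuity correction**:
`p_le = Φ((d_rg − Tp)/√(Tp(1−p)))`. This choice reproduces the reference
values for this assay across three orders of magnitude; the exact binomial
lower-tail sum is available as `method="exact_binomial"` for diagnostics
(at small T the two differ noticeably, e.g. 0.50 vs 0.39 at T = 11).

**Estimator.** The four balance equations (totals and same-color doublets,
see README) determine `(R₀, G₀, F_r, F_g)` in closed form via the ratio
`t = R₀/G₀ = (n_red − d_rr − a)/(n_green − d_gg − a)`, `a = d_rg/2`. The
implementation re-checks the two doublet-equation residuals to 1e-9
(relative) after solving. Degeneracy (`n − d_same − a ≤ 0`) is impossible
for validated integer counts because of the accounting identity, but the
solver guards against it for real-valued inputs (expectation-mode records)
and raises rather than returning a non-positive R₀ or G₀. Negative
fractions are legal outputs: with no true division the estimate scatters
around zero.

**Confidence intervals.** The reference tables print 95% CIs without
stating their construction; we use a percentile bootstrap as our own design
choice, so the printed bounds are not reproduction targets. Each replicate
redraws the doublet class vector from `Multinomial(T, observed proportions)`
and the two singlet totals from Poisson laws at the observed singlets
(field-to-field sampling), then re-runs the closed-form estimator.
Replicates where the (real-valued) system degenerates are dropped; >20%
failures trigger a warning carrying the achieved replicate count. Intervals
are deterministic given the seed.

Display rounding follows print convention: percentages to one decimal,
probabilities to three significant figures; internal values keep full
precision. Summary statistics use decimal half-up rounding (85.55 → 85.6).

Known print anomalies in the source tables are documented rather than
matched: the MCX1-initial fractions print 0.8%/0.8% where the stated
equations give 0.3%/1.3%, MCX4 F_g prints 9.7 vs recomputed 9.8, and MCX6
prints 14.0/11.8 vs 13.9/11.9. The suite asserts the recomputed values and
checks that the deltas are real.

## The synthetic-data generator

`SimulationTruth` fixes the generative parameters: seeded inputs `r0`,
`g0`, a happen-to-be contact-pair budget `H` (`n_contact_pairs`),
per-platelet division probabilities `f_red`, `f_green`, and (for spatial
mode) field geometry. Defaults mirror the scale of the real experiments:
~150 platelets per color surveyed over ten 100×100 µm fields, `H = 24`
contact pairs (≈10–25 observed doublets of which roughly half are mixed),
division fractions near 0.12, contact distance 2 µm (≈1.5× a platelet
diameter), division offset 1 µm.

* **expectation** mode emits the real-valued model expectations
  (`d_rr = H·r² + f_red·r0`, etc.). It is the algebraic fixed point of the
  estimator: recovery is exact to 1e-9, which pins the algebra
  independently of sampling noise.
* **sampling** mode draws the `H` contact classes multinomially (rejecting
  draws that overdraw a color) and lets each *non-contacted* platelet
  divide independently. Contacted platelets do not divide — a dividing
  contacted platelet would form a triplet, which the counting protocol
  excludes — so every doublet is cleanly a contact pair or a division pair
  and the estimator's model holds. Consequence: the **division fraction**
  (newly generated / seeded, the quantity the estimator measures) is
  `f·(1 − E[contacted]/n0)`, slightly below the per-platelet probability
  `f`. `SimulationTruth.implied_division_fractions` exposes this value and
  `calibrate_division_probability` inverts it, so simulations can be
  parameterized directly by the division fraction they should realize.
  Platelet conservation holds exactly:
  `n_red + n_green = r0 + g0 + divisions`.
* **spatial** mode places platelets uniformly in the fields (with a 3 µm
  edge margin so the rendered point-spread function is never truncated at a
  border), adds a division sibling at the fixed offset in a random
  direction, groups spots by single-link clustering at the contact
  distance — the *same* routine the imaging front-end uses, so "in contact"
  means the same thing on both sides of a round trip — and drops clusters
  of three or more from all counts. Contacts emerge from density rather
  than from `H`; divided pairs may touch bystanders and be excluded, which
  is exactly the model violation this mode exists to exercise. As the
  contact distance shrinks to zero, happen-to-be doublets vanish.

**Rendering.** Each spot becomes an isotropic 2-D Gaussian (default
σ = 0.3 µm, pixel 0.2 µm) of integrated intensity `photon_scale` on a
constant background, point-sampled at pixel centres ((i+0.5, j+0.5) px
convention shared with the detector), optionally with Poisson photon noise
plus Gaussian read noise, quantized to 16-bit. There is no depth,
aberration, or spectral bleed-through: channel registration is exact. A
passing round trip therefore demonstrates the counting logic, not
robustness to real optics.

**Dilution events.** Generation-0 intensities are lognormal truncated to
the sorting gate (default width 0.05 log10 units); a divided platelet is
replaced by two events at half the parent intensity times lognormal noise
(CV default 0.05); an optional leak fraction of undivided platelets is
placed just below the gate to emulate sorter impurity. One division turns
one platelet into two events, so the divided-event fraction is
`e = 2q/(1+q)` for a platelet fraction `q`.

## Imaging front-end

Spot detection: difference-of-Gaussians band-pass (σ and 2σ), local maxima
above `median + snr × 1.4826·MAD` (with a half-count floor so noiseless
synthetic images threshold sensibly), maxima closer than the minimum
separation collapse to the brighter. Centroids are intensity-weighted over
a window of half-width 2σ and then refined by iterative neighbor
subtraction (each pass re-estimates every spot on the image minus the
current Gaussian models of all others). This matters for division pairs at
~3σ separation, where a plain windowed centroid is pulled ~0.3 µm toward
the partner — enough to flip a near-threshold cluster assignment; with
subtraction the error drops to ~0.01 µm. Detection limits: same-channel
spots closer than the minimum separation merge, and the detector makes no
attempt at deconvolving them.

Clustering is single-link across both channels at the contact distance
(centre-to-centre, boundary inclusive), chosen to mirror visual adjacency
judgment; the contact threshold is a declared convention (default 2 µm),
not a claim about any particular microscopist's practice. Colocalized
red+green spots remain two spots (one per channel) and form an RG doublet.
Clusters of ≥3 are excluded from counts but reported in QC, along with
border-proximal spots (counted, flagged).

## Dye-dilution quantifier

Intensities are log2-transformed; the density is a 0.01-log2-bin histogram
smoothed with a Gaussian kernel (σ = 0.05 log2 units). The undivided mode
is the highest-intensity peak (prominence ≥ 2% of the maximum); the
generation boundary is the deepest histogram minimum within one log2 unit
below it (valley method) or exactly 0.5 log2 units below (half-dilution
method, also the fallback when no interior minimum exists). Both the event
fraction and the platelet fraction `q = e/(2−e)` are reported. Only one
division generation is modeled (undivided vs divided), matching the single
reduced cluster seen in short platelet cultures; multi-generation
deconvolution is out of scope. The estimate is scale-invariant by
construction.

## Simulation study sizes and numerical choices

The test suite uses: 1000 random count vectors for closed-form vs
root-find agreement (tolerance 1e-6 relative); 200 sampling-mode replicates
at r0 = g0 = 5000, H = 200, f = 0.12 for mean recovery (|bias| < 0.01 —
the small negative bias from contact-excluded divisions is expected and
documented above); 500 paper-scale datasets (r0 = g0 = 150, H = 24,
division fraction calibrated to 0.12, 1000 bootstrap replicates) for
interval coverage, evaluated pooled over the two exchangeable colors
against the 95 ± 3 band; a 20-field noiseless imaging round trip required
to be count-exact; and dilution recovery within 0.02 over
q ∈ {0.1, 0.3, 0.5, 0.8} at 10⁵ events.

Observed calibration, computed by those tests: pooled coverage ≈ 93%.
The prescribed resampling scheme understates the binomial division-count
variance (its implied standard error is ~9% narrow at this scale) and the
estimator carries a small positive Jensen bias (~+0.004 at paper-scale
counts), so coverage sits in the lower half of the band; against each
dataset's *realized* division fraction the same intervals over-cover
(≈99%), bracketing the nominal level.

## Known limitations

* The estimator assumes at most one division per platelet and no division
  of contacted platelets; longer cultures (multiple generations, triplet
  formation by re-division) break the accounting.
* The bootstrap interval is our construction; it is mildly anti-
  conservative at paper-scale counts (see above).
* The imaging model omits optical realism (depth, aberration,
  bleed-through, platelet shape); spatial-mode exclusion bias is available
  for study but not corrected for.
* Flow-cytometry raw data handling is limited to event lists
  (`event_id,intensity[,generation]` CSV); FCS parsing, compensation and
  scatter gating are out of scope.
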