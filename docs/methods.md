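# Methods

## The question and the model

Diurnal biting flies (tsetse, stable flies, horse flies) are strongly
attracted to blue objects, a behaviour exploited by blue traps and
insecticide-treated targets. `flychrome` implements a sensory-ecological
account of that attraction: it models the five photoreceptor signals a
generic higher fly obtains from natural scenes, trains minimal neural
classifiers to solve the two ecological discriminations a host-seeking fly
faces — *animal vs. leaf* and *shaded vs. unshaded* — and then asks how
trained classifiers respond to the reflectance spectra of control-device
fabrics.

### Photoreceptor front end

The fly retina is modelled with five spectral receptor classes: R1-6
(broadband, main peak ~490 nm plus UV sensitizing-pigment peaks near
332/350/369 nm), R7p (UV, ~335 nm), R8p (blue, ~460 nm), R7y (UV triple
peak near 337/355/373 nm) and R8y (green, ~520 nm with modest UV
sensitization). Curves are built from Govardovskii A1 alpha-band templates
plus Gaussian UV lobes and peak-normalized. Two physiological details of
the yellow ommatidial type matter for the downstream results and are
modelled explicitly: R7y's carotenoid screening pigment suppresses its
blue-pigment sensitivity (we keep only a 5% blue shoulder), and R8y lies
beneath the R7y rhabdomere, whose screening truncates R8y's
short-wavelength flank (a sigmoidal cut at ~480 nm; the template peak is
placed so the screened product peaks at ~522 nm). Without the R8y cut the
green channel responds substantially at 460 nm and blue fabrics no longer
look "green-dark" to the model fly. A `glossina` variant shifts the R1-6
peak +10 nm; it changes no qualitative conclusion.

### Quantum catch and excitation

For stimulus reflectance `R_s` under stimulus irradiance `I_s`, viewed by a
fly adapted to a background `R_b` under `I_b`, the quantum catch of
receptor *i* is the von Kries-style ratio

    Q_i = ∫ I_s(λ) R_s(λ) S_i(λ) dλ / ∫ I_b(λ) R_b(λ) S_i(λ) dλ

integrated over 300–700 nm, and the receptor signal is the excitation
`E_i = ln Q_i`. The background is always the mean leaf reflectance under
the open illuminant: the fly scans vegetation from an open position
regardless of where the stimulus sits. Linear (`E=Q`) and hyperbolic
(`E=Q/(Q+1)`) transforms are available as options for sensitivity
analysis; `ln` is the default and the only transform the headline numbers
use.

Under `ln`, two invariants follow and are asserted in tests: multiplying
`I_s` by a constant *c* shifts every excitation by exactly `ln c` (the
achromatic signature of shade), and between-receptor differences are
unchanged by shared dimming (chromatic signals are intensity-invariant).

### Numerical integration

All integrals are left-Riemann sums times the grid step on the master grid
(300–700 nm at 2 nm, endpoints inclusive, 201 points; a constant-1
integrand gives exactly 400). Quantum catches are ratios of such sums on
one grid, so the quadrature rule cancels to first order; the test suite
checks 2 nm catches against a 0.1 nm oracle on analytic spectra (relative
error < 1e-6) and checks that excitation ranks are identical at 2 nm and
10 nm input resolution (Spearman ρ rounds to 1.000), mirroring the
resolution robustness check of the original analysis.

## The synthetic stimulus sample

Real analyses of this kind run on measured reflectance libraries. The
package instead ships parametric generators whose *defaults define the
study conditions*: 72 leaf and 72 animal spectra (seeded, deterministic),
each viewed under two illuminants — 288 excitation records. The generators
encode the statistical structure of the three spectral classes of
terrestrial scenes; real CSV spectra can be substituted through the same
loaders without touching any downstream stage.

**Leaf green.** Reflectance is a plateau (0.12–0.45) times
`exp(−absorbance)`, with chlorophyll absorbance bands in the blue
(450 nm, σ 52; depth 1.0–2.8) and red (662 nm, σ 50; depth ≥ 1.0, covarying
with the blue band), a carotenoid shoulder extending blue absorption to
~500 nm, and a deep UV wall; a flat cuticular-wax specular component
(0.005–0.035) sets the small near-UV reflectance; a broad maturity tilt
and band-scale smooth noise provide within-class diversity. The green peak
position (540–570 nm in the 400–680 nm window) is part of the class
definition and is enforced by rejection sampling.

**Grey–brown (melanin).** Reflectance is monotone non-decreasing,
essentially flat through the UV (a small variable residual slope) and
rising from ~400 nm with exponential curvature k ∈ [3, 7] from a dark
baseline (0.008–0.035) by a rise of 0–0.65; variability is applied in
derivative space, so no sample ever decreases with wavelength. Steep
curvature keeps dark specimens dark through the green band — the property
that makes the green channel the most informative single input.

**Fabrics.** Eleven deterministic spectra (7 blue, 3 black, 1 violet)
mirroring the composition of control-device fabrics: blues are narrow
Gaussian peaks (centres 446–464 nm, heights 0.33–0.52, σ 22–26) on a dark
base with low UV and green–red reflectance; blacks are flat at ~3%; violet
adds a long-wavelength tail. Fabrics never enter training.

**Illuminants.** Photon-flux blackbody shapes: open/cloudy ~5800 K and
woodland shade ~8000 K (bluer but only mildly so — a strongly blue shade
makes the green channel an overwhelmingly dominant shade cue, which
contradicts the redundancy of shade classification). The shade total flux
is exactly 4.4% of the open total. Seeded low-frequency ripples emulate
day-to-day atmospheric variation and are shared by both members of the
pair (one sky).

### What the generators do and do not emulate

The generators reproduce the class-level geometry that the analysis
depends on: green-peaked vs. monotone spectra, neither natural class
informative in the UV, the green-brightness gap between foliage and dark
integuments, heavy within-class diversity, and a blue–green opponent cue
that separates the classes imperfectly (animal-task accuracy ~0.87–0.95
across seeds rather than 1.0). They do not reproduce any particular
species' spectrum, measurement noise structure, specular geometry, or the
exact per-fabric reflectances of commercial materials — so fabric-level
results should be read as class-level patterns (blue fabrics are
misclassified as animals, never as shade under open light), not as
predictions for a named product.

## Classifiers and the ensemble protocol

The classifier is a fully connected k→3→1 network: k receptor excitations
in, three logistic hidden units, one logistic output read as the
probability of the positive class ('animal' or 'shaded'; ties at p = 0.5
classify positive). Training minimizes the conditional negative
log-likelihood plus a quadratic weight penalty (biases unpenalized) by
L-BFGS with analytic gradients.

Protocol per task: split the 288 stimuli 60/40 at random (resplitting if a
side lacks a class), train 100 networks from independent uniform
initializations on the 60%, keep the one with the best penalized fitting
criterion, record held-out accuracy on the 40%; repeat 20 times. The 20
selected networks are the ensemble used by clamping, reclassification and
fabric analyses. All randomness derives from one master seed by
seed-sequence spawning; an ensemble is bit-for-bit reproducible.

Optimizer settings are package choices, exposed in `TrainConfig`:
`weight_decay = 1e-2`, `init_scale = 0.1`, `max_iter = 500`. They were
chosen for stable convergence *and* well-behaved extrapolation: with weak
regularization these tiny networks frequently converge to optima containing
a hidden unit that is saturated at ~1 for every training stimulus — an
effective bias whose input weights are unconstrained by the data. Such
units behave arbitrarily on out-of-distribution inputs like fabric
excitations. Stronger decay, small initializations and selection by the
penalized criterion (rather than the raw likelihood, which systematically
prefers the sharpest optimum) suppress them. A `select_on="test"` flag and
a `tanh` hidden activation exist for robustness checks; neither is used by
the defaults. Splits are simple random, as in the protocol; a stratified
option exists.

## Interpretation analyses

**Clamping.** Each trained network classifies the full 288-record database
with one receptor input fixed at that receptor's median over the database
(fabrics excluded; a flag can include them). A receptor whose clamping
drops accuracy toward the chance level — 0.5 in this balanced design,
documented rather than estimated — was load-bearing. Expected signature,
asserted in the acceptance tests: animal-networks collapse to ~0.5 for
*every* receptor (the illumination-invariant opponent code needs all its
inputs), shaded-networks are unaffected by any single clamp (five redundant
achromatic channels).

**Reclassification direction.** Among stimuli whose classification a clamp
changed, split by the sign of (clamped − original) excitation and report
the proportion reclassified towards 'animal' within each sign group
(models with an empty group are recorded as missing, never zero). Raised
blue (R1-6) excitation drives leaf→animal reclassification; raised green
(R8y) drives animal→leaf — the blue–green opponency readout.

**Weight export.** All connection weights of an ensemble flatten to a
22-column table (5·3 + 3 + 3 + 1) for inspection; a qualitative test
confirms that shaded-network hidden units carry same-sign (summing) input
weights far more often than animal-network units (opponent sign mixtures).

## Problem sizes and determinism

The shipped study scale is the full protocol: 288 records, 2 ensembles ×
20 repetitions × 100 initializations (4000 trained networks, ~2–4 minutes
on one CPU). The input-subset experiment (21 subsets per task) uses a
reduced protocol by default (20 initializations × 5 repetitions) to keep a
full run under ten minutes; the subset *ranking* is stable at this scale.
The orchestration layer (`run_all`) derives all stage seeds from one
master seed and writes every intermediate product as CSV/JSON, so a saved
`RunConfig` reruns to numerically identical outputs.

## Known limitations

- Receptor sensitivities are template reconstructions honouring the
  published peak positions, not digitized measured curves.
- Ensemble-level proportions (clamped accuracies of weakly load-bearing
  receptors, per-fabric vote counts) vary somewhat with the master seed:
  which receptors the selected networks lean on is itself sampling-
  dependent, at the stated sample size of 72 + 72 spectra.
- No receptor noise model, no opponent-space projection, no polarization
  channel, no odour or trap-geometry effects: classification operates on
  noiseless excitations exactly as the protocol defines them.
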