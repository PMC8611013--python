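# Methods

`pcct` simulates a prototype spectral photon-counting CT (PCD CT) system
end to end on a desk scale and implements the analysis chain used to
characterise such a system: per-bin reconstruction, K-edge threshold
calibration, per-pixel neural-network material decomposition, and
ROI-based image-quality statistics.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## System model

**Geometry.** Third-generation fan-beam with a curved equiangular
detector: source-to-isocenter (SID) 227.5 mm, 48 modules of 80 × 48
pixels (80 rows × 2304 columns), pixel pitch 0.230 mm in-plane ×
0.190 mm in z, 1440 projections per rotation, 250 mm field of view.  The
source-to-detector distance (SDD) is not an independent input: it is
fixed at SID × (5 × 0.190 mm) / 0.640 mm = 337.7 mm, the unique value
for which the 5-row binned detector z pitch magnifies to the 0.640 mm
slice thickness at the isocenter.  The same geometry then gives
0.640 / 5 = 0.128 mm effective z pixels in 1 × 1 high-resolution (HR)
mode.  The pitch-to-axis assignment (0.230 mm → columns, 0.190 mm →
rows) is likewise the only one consistent with those numbers.

The simulator is single-slice 2-D: detector rows enter only through
binning multiplicity and slice accounting; ray tracing uses one in-plane
fan.  Reconstruction of the cone angle, helical motion, scatter, and a
bowtie filter are out of scope.

**Spectrum.** Analytic Kramers bremsstrahlung, fluence ∝ E·(kVp − E),
at 140 kVp, hardened through 2.5 mm aluminium-equivalent inherent
filtration (a configuration value; the prototype's true filtration is
not part of the system description) on a 1 keV grid over 20–140 keV.  The absolute scale is
600 photons per native detector column per view per mAs, chosen so the
12-bit high-energy counter stays below saturation in an air scan at the
default 10 mAs imaging exposure.  Exposure scales fluence linearly.

**Attenuation.** Each material carries a density and a compact log-log
sampled mass-attenuation table (8–12 points per segment) following the
standard published photon cross-section shapes over 20–150 keV, split at
K-edges so interpolation never bridges a discontinuity; an on-edge query
returns the right (above-edge) limit.  The two normative anchors are the
calibration-filter K-edges: gadolinium 50.2 keV and tungsten 69.5 keV.
Iodine and calcium solutions are expressed in mg/mL with linear
partial-attenuation mixing (solute volume fraction c/(1000·ρ), water
reduced accordingly), so per-pixel fractions always sum to ≤ 1.

White and gray matter are water-based pseudo-tissues: density offsets of
−0.5% / +0.5% relative to water plus an energy tilt
1 + t·((30/E)³ − (30/70)³) with t = ∓0.12 standing in for an
effective-atomic-number difference.  The tilt magnitude is an overt
demonstration parameter: it is set so that the white/gray pair is
separable in three-bin data at the desk-scale geometry's coarse detector
sampling, and it is deliberately larger than any real white/gray
spectral contrast.  Passing the white/gray segmentation test therefore
demonstrates that the decomposition machinery works, not that real brain
tissue is separable at this dose.

**Counting chain.** For each ray the expected spectrum after
Beer–Lambert attenuation is sorted into three bins (30–50, 50–65,
65–140 keV) through a Gaussian energy response (σ = 4 keV): the
probability that a photon of true energy E lands in bin [lo, hi) is
Φ((hi−E)/σ) − Φ((lo−E)/σ).  These weights telescope across adjacent
bins, so the three bins sum *exactly* to one wide 30–140 keV bin
(bin-additivity invariant).  Charge sharing, pulse pile-up, K-escape and
detector lag are out of scope.

Counters are 14/13/12-bit for the low/middle/high bins and saturate per
*native* pixel at 2^bits − 1, upstream of the digital 5 × 6 binning sum;
the binned expectation is therefore clipped at native level and then
Poisson-sampled with a multiplicity-scaled ceiling (a sum of m
independent Poisson counts is Poisson with the summed mean, so sampling
after binning is statistically exact and avoids simulating 80 rows).

**Energy calibration.**  The DAC→keV map of the thresholds is recovered
from open-threshold count sweeps behind gadolinium (0.1 mm) and tungsten
(0.05 mm) foils.  The K-edge appears as a Gaussian bump (the edge step
convolved with the energy response) on a smooth background in
d²counts/dDAC²; the locator takes the curvature peak, then refines it by
a Gaussian-plus-linear-background least-squares fit over a ±10 keV
window.  Two located edges and their known energies give gain and offset
exactly.  A sweep that does not cover an edge is detected by requiring
the curvature peak to sit well inside the sweep with a ≥ 8% local drop
in the differential count rate, and raises a calibration error naming
the filter.  Recovered accuracy on simulated sweeps: edges within
0.15 keV, gain within 1%, offset within 0.45 keV.

**EID comparison mode.**  The energy-integrating signal is
Σ_E E·N(E) with Gaussian noise of variance Σ_E E²·N(E) (the exact
variance of an energy-weighted Poisson mixture) plus optional electronic
noise; it is log-normalized and reconstructed like the photon-counting
data, with its own water calibration.

## Reconstruction

Log-normalization p = −ln(max(counts, ε)/air) with ε = 0.5 counts as the
zero-count guard; the total-energy channel sums counts over the three
bins first.  Reconstruction is the classical equiangular fan-beam FBP:
weight by D·cos γ, convolve with the equiangular ramp kernel (FFT, with
optional Hann apodization), back-project with the 1/L² distance weight
and linear interpolation in the detector coordinate.  On a noiseless
known-μ disc the reconstruction is accurate to ~0.1% in a central ROI.

HU calibration is by water-disc self-calibration: an 80 mm water
cylinder is acquired noiselessly and reconstructed per channel; the mean
attenuation in a central ROI defines μ_water_eff for each bin, the total
channel, and the EID mode, so water reconstructs to 0 HU everywhere by
construction.  Beam hardening is simulated but not corrected (cupping of
a few HU at these diameters); iterative reconstruction and
metal-artifact reduction are out of scope.

The total-energy channel is defined as the combined 30–140 keV range of
the three bins throughout.

## Material decomposition

The decomposition is a per-pixel multilayer perceptron: input = the
pixel's HU value in each of the three bins (standardized per bin),
eight hidden ReLU layers, linear outputs, one channel per material
(iodine, calcium, white matter, gray matter).  Training samples are the
pixels of 25 × 25-pixel ROIs in regions of known composition: seven
insert-phantom ROIs (iodine at 2/5/10 mg/mL, calcium at 50/150/300
mg/mL, water) and two brain-phantom ROIs (white, gray), giving the
canonical 9 × 625 × 3 = 16,875 scalar training units.

Targets: tissue channels are one-hot; water is the zero vector (plain
water decomposes to "no material"); solute channels are
concentration-scaled (c/c_max), which is what makes the decomposed
iodine map a monotone function of true iodine content — with pure
one-hot labels every training concentration would map to the same
output and the map could not rank concentrations.  The loss is the mean
squared error.

Optimisation honours the published learning rate (5 × 10⁻⁵) and epoch
count (4500) with full-batch Adam.  Plain full-batch gradient descent is
available (`TrainingConfig(optimizer="gd")`) but at this learning rate
and epoch budget it stalls near 40% of the initial loss, which cannot
reproduce a cost curve that "converges close to zero"; Adam reaches
< 1% on the noiseless canonical set.  Hidden width is unpublished; the
default is 64, and the pipelines use 16, which trains in under a minute
on one CPU with no measurable accuracy loss on these 3-feature
problems.  Initialization is He-style scaled uniform under an explicit
seed; training is fully deterministic given the seed (pure numpy).

Applying the model reshapes the per-bin images to one feature row per
pixel and back to grid × materials; the iodine map is the iodine output
channel.

## Phantoms and what they demonstrate

All phantoms are rendered at twice the reconstruction grid (standard
inverse-crime hygiene) and are deterministic given their parameters.

* **Insert phantom** — 95 mm water cylinder, seven 16 mm inserts on a
  62 mm ring (3 iodine, 3 calcium, 1 water).  Training source.
* **Brain phantom** — elliptical skull (cortical bone), scalp muscle,
  gray ribbon, white core, two 5 mm iodinated vessels (4 mg/mL).
  Decomposition and PCD-vs-EID HU comparison.
* **Liver phantom** — body ellipse with liver (1 mg/mL parenchymal
  iodine), an 18 mm tumor with a 6 mm rim at 5 mg/mL iodine and an
  unenhanced core, a 9 mm aorta at 10 mg/mL, back muscle, and a fixed
  homogeneous noise ROI.  The tumor ROI sits on the enhancing rim — the
  measurement targets the hypervascular hotspot.  Concentrations are
  typical hepatic-arterial-phase values.
* **Bar phantom** — alternating 0.5 mm bone/air bars in a soft-tissue
  disc, emulating sub-millimeter turbinate-scale anatomy for the
  standard-vs-HR resolution comparison.

ROI centers are fixed in the phantom specifications (the physical
experiment drew them manually; fixing them makes runs reproducible), and
"measured thrice" is realised as three noise seeds rather than three
manual draws.

The phantoms share none of real anatomy's texture, scatter, motion, or
partial-volume complexity, and the white/gray contrast is exaggerated
(above); passing tests shows the chain is self-consistent and correctly
implemented, not that in-vivo imaging performance is reproduced.

## Problem sizes

Three geometry profiles share the full system's fan coverage and SID/SDD:

| profile | views | native cols | col pitch | recon grid | use |
|---|---|---|---|---|---|
| full | 1440 | 2304 | 0.230 mm | 625² | published numbers |
| reduced | 720 | 768 | 0.690 mm | 313² | demos, integration tests |
| tiny | 240 | 384 | 1.380 mm | 160² | unit tests |

The reduced profile keeps the binned in-plane sampling within 3× of the
full system; the resolution demo instead uses a narrow 480-column fan at
the *native* 0.230 mm pitch over a 64 mm field, since the bar experiment
is about native-pixel sampling.  Geometry-derived quantities (effective
pixel sizes, module arithmetic) are always evaluated on the full
profile.

## Numerical choices and edge cases

* Forward projection: fixed-step ray sampling (half a phantom pixel)
  with bilinear interpolation, clipped to the phantom bounding circle;
  chord lengths accurate to ~0.4%.
* Backprojection: linear detector interpolation; pixels behind the
  source are skipped.
* Zero counts: guarded by ε = 0.5 counts in the log.
* On-edge attenuation queries: right limit (the above-edge segment).
* Ratios: CNR raises on a zero noise SD; the CNR gain raises on a zero
  total-energy CNR.  The gain is numerically meaningless for tissues
  whose total-energy contrast is near zero (the liver-parenchyma ROI at
  1 mg/mL), and the report carries per-seed spread so this is visible.
* The white/gray accuracy property is evaluated inside pure-material
  regions eroded by 5 mm — the partial-volume band at the reduced
  profile's in-plane resolution, where no per-pixel label is meaningful.
* All randomness flows from one master seed through fixed per-stage
  offsets; phantoms are seed-independent (deterministic geometry).

## Known limitations

No charge sharing, pile-up, scatter, bowtie, cone-beam effects, or
beam-hardening correction; attenuation tables are compact shape-faithful
approximations rather than a full cross-section database; the EID mode
shares the PCD geometry rather than modelling the original
energy-integrating detector; and the decomposition is strictly
per-pixel — no spatial context, as in the method it implements.
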