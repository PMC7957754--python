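# Methods

## Coordinate chain and pose interpolation

All lengths are millimetres and timestamps seconds throughout; this
single-unit discipline is enforced at the I/O boundary. Image geometry uses
pixel centres with 0-based indices: column index → image x (lateral), row
index → image y (depth), image plane z = 0. A pixel maps to world space
through two rigid transforms: the fixed image-to-marker calibration and the
probe pose (marker-to-tracker). The calibration procedure itself is out of
scope — it is consumed as configuration, with an identity default that suits
the simulator, where the virtual probe is tracked directly at the image
frame.

Poses arrive at ~7 Hz while SWV frames arrive at ≤2 Hz, so each frame's pose
is interpolated: translation linearly, rotation by spherical linear
interpolation between the bracketing poses. Slerp is computed on the
relative rotation (rotation-vector magnitude ≤ π), i.e. always the shortest
arc, so antipodal quaternion encodings of the same orientation cannot
produce wrap-around. Frames whose timestamp falls outside the recorded pose
span are dropped with a warning rather than extrapolated: acquisitions halt
while the probe is repositioned, and extrapolating poses would fabricate
geometry.

## Voxel reconstruction

Samples are binned by `floor((p − origin)/spacing)` into an isotropic grid
(default 0.5 mm). The grid is the tight bounding box of the mapped samples
padded by one voxel, and the origin is snapped to a multiple of the spacing
so voxel boundaries are reproducible across runs. Zero-valued SWV pixels are
discarded *before* binning (they encode failed velocity estimates; exactly
0.0, not a small-value threshold, because device exports use the literal
sentinel); B-mode frames keep all pixels. Multiple sweeps of one acquisition
are pooled into a single sample stream.

Per-voxel statistics are computed in two passes — sums/counts, then squared
deviations from the voxel mean — so the results equal the definitional
estimator (mean, n−1 standard deviation) to machine precision rather than
suffering the cancellation of a sum-of-squares shortcut. σ is defined as 0
for single-sample voxels; the 0.5 m/s floor makes that choice
inconsequential.

The structure summary weight is implemented exactly as the printed formula
ω = n/max(σ, 0.5). The accompanying prose description ("inverse of the
standard error") would instead give √n/σ; because the two readings cannot be
reconciled, the printed form is the default and
`weight_scheme="inverse_se"` exposes the alternative. With pixel noise below
the 0.5 m/s floor the two schemes differ only through the n vs √n factor.

The 2D estimator pools masked pixels across its frames and discards zeros by
default, for consistency with the 3D rule; `discard_zeros=False` restores a
literal all-pixel average, since the historical practice is ambiguous on
this point.

## Longitudinal profiles

Voxel centres are projected onto the axis through two landmarks; relative
position 0 is the first landmark, 1 the second, and voxels projecting
slightly outside [0, 1] are kept. The profile at position z is
Σ ωᵢG(dᵢ)vᵢ / Σ ωᵢG(dᵢ) with G a Gaussian of σ = 5 mm evaluated on axial
distances in physical mm (so the kernel width is anatomy-independent),
truncated at 4σ for speed (mass loss < 10⁻⁴). Defaults: 101 positions
(0.01 steps, ≈1 mm on a 10 cm tendon — the sampling density is otherwise a
free choice). Positions whose total kernel weight is below 1 % of the
maximum support are reported as undefined rather than letting a single
far-away voxel define the tendon end.

The single-profile standard error is the kernel-weighted between-voxel
dispersion divided by √n_eff, with n_eff = (ΣwG)²/Σ(wG)² (Kish effective
sample size); group curves use the between-subject SE implicitly via the
per-position paired t-test. Group comparisons run a two-sided paired t-test
per position at α = 0.05 with **no** multiplicity correction, replicating
the reference protocol; a Bonferroni switch exists but is off by default.
Positions undefined for any subject are skipped, and positions with fewer
than two complete pairs are marked untestable.

## Reliability statistics

ICC(2,1) is computed from the two-way ANOVA mean squares,
ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)), with the
McGraw–Wong absolute-agreement single-measures confidence interval
(Satterthwaite-approximated F degrees of freedom) — the same computation
SPSS reports. The implementation is in-package; the test suite cross-checks
it against both a definitional sums-of-squares oracle and pingouin's
ICC(A,1).

SEm is fixed as SD·√(1 − ICC) with SD the pooled standard deviation of all
n·k values — the dominant convention in the tendon-SWE reliability
literature; the source protocol names SEm without a formula, and its printed
values cannot adjudicate the convention without raw data. ICC bands: poor
(≤0.2), fair (0.21–0.4), moderate (0.41–0.6), good (0.61–0.8), very good
(>0.8), with boundaries closed on the left label.

Modulus conversion v = √(E/3ρ) assumes isotropic, incompressible linear
elasticity — valid for phantom materials, knowingly violated by tendon,
which is why analyses stay in velocity units. Percent deviation is
100·(measured − reference)/reference, reported to one decimal.

Paired t-tests are two-sided with df = n−1; zero-variance differences are
resolved as limiting cases (t = 0, p = 1 when the mean difference is 0;
p = 0 otherwise). A summary-statistics entry point (mean difference, SD, n)
supports recomputation from printed tables; note that 2-decimal printed
summaries can move the recomputed p by ~0.001–0.006 in the third decimal.

## Synthetic phantom and scanner

The simulator models the *observation process only*: the phantom is a
ground-truth piecewise-constant SWV field (closed-region membership, first
matching inclusion wins; inclusions may not overlap) and no shear-wave
propagation, guided-mode dispersion, speckle, shadowing or tissue
deformation is simulated. Consequences for interpretation: passing tests
demonstrate that geometry, binning, weighting and statistics are correct and
unbiased under the stated noise model — they say nothing about acoustic
artefacts of a real device. The empirically observed speed-of-motion
artefact in particular is represented only by the optional `speed_bias`
hook (default off), because its magnitude is device physics.

Default acquisition parameters mirror the reference acquisition conditions:
SWV frames at 2 Hz, poses at 7 Hz, sweep speed 3 mm/s (freehand sweeps stay
below 5 mm/s; the motorised speed series spans 0–33 mm/s), tracking jitter
0.09 mm vector RMS implemented as isotropic Gaussian with per-axis
sd = RMS/√3. Frame count follows floor(duration × rate) with the first
frame at t = 0; a final pose is emitted at the exact sweep end so no frame
requires extrapolation. Pixel noise (default 0.1 m/s) and dropout (default
5 %) are simulator choices — the reference protocol reports neither — sized
to be visible but small against the 0.5 m/s σ floor. Pixel values are
sampled at the *true* probe position and the emitted poses carry the jitter,
as with a real tracker. Negative noisy values are clamped to 0, i.e. they
become invalid-pixel dropouts. Everything is reproducible bit-for-bit from
the seed.

The default phantom carries four 5 mm-radius cylinders at 1.47, 2.24, 4.04
and 5.42 m/s (densities 1040, 1040, 1050, 1060 kg/m³) in a 1.0 m/s
background. Segmentation masks generated for inclusions are shrunk by a
1.5 mm margin (3 voxels at 0.5 mm) so boundary voxels with mixed-region
samples are excluded, as a careful manual segmentation would.

## Numerical and test-design notes

* The reconstruction equivalence test demands *bitwise* equality against a
  brute-force per-voxel loop; both paths accumulate in the same
  frame-major, row-major order to make that meaningful.
* The large-kernel limit (profile → global weighted mean) is checked at
  σ = 10⁴ mm on a 20 mm structure: the second-order kernel variation scales
  as L²/2σ², so the 10⁻⁶ tolerance requires a short axial extent; on a
  100 mm tendon the deviation at this σ is ~10⁻⁵ by the same expansion.
* ICC parameter-recovery simulations use a small rater variance (0.01
  against subject 1.0, error 0.4): with k = 2 the rater component has one
  degree of freedom, so a large rater variance makes any single realization
  swamp a ±0.02 recovery check irrespective of estimator correctness. CI
  coverage is assessed over 1000 seeded n = 10, k = 2 replicates.
* Problem sizes in the examples, tests and acceptance script (20–40 mm
  sweeps, 16–25 px frames, 10 seeds, 1000 CI replicates) are chosen so the
  full pipeline runs in seconds while keeping Monte-Carlo error well inside
  every asserted tolerance.

## Known limitations

* No hole filling or interpolation: voxels never visited stay empty and are
  excluded from all summaries.
* Calibration and temporal synchronisation are inputs, not estimated.
* In-vivo reliability magnitudes are cohort properties and cannot be
  recomputed from simulations; the package verifies the estimators, not the
  published cohort values.
* The simulator's B-mode channel is a schematic intensity map (for container
  and segmentation plumbing), not a speckle model.
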