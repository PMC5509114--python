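# Methods

## Problem and pipeline

Identifying fossil bovid teeth from the shape of the occlusal (chewing)
surface outline is a standard task in paleoenvironmental reconstruction,
and crowdsourcing the tracing step is attractive because expert
digitization is slow. `occlumorph` implements the complete quantitative
pipeline around crowd-traced outlines:

1. **mask normalization** — any grayscale/color silhouette is forced to a
   strict two-level mask (tooth black, background white);
2. **boundary extraction** — the outer boundary of the largest
   8-connected foreground component, traced by marching squares at
   iso-level 0.5;
3. **elliptical Fourier analysis (EFA)** — the outline
   `x(t) = A0 + Σ a_j cos(jt) + b_j sin(jt)`,
   `y(t) = C0 + Σ c_j cos(jt) + d_j sin(jt)` is fit with `H` harmonics,
   normalized, and re-emitted as `K = 150` canonical-start landmarks;
4. **grading** — each worker tracing is scored by its Riemannian shape
   distance to the expert (or to the workers' own mean) and rejected
   beyond a threshold (default 0.2);
5. **consensus** — surviving tracings are averaged with the full
   Procrustes mean;
6. **classification** — harmonic amplitudes feed a random forest under
   leave-one-out cross-validation (LOOCV), scored by log-loss,
   confusion matrix and classification rate.

## EFA estimation and normalization

Coefficients are estimated with the classical closed-form expressions
for a chord-length-parameterized piecewise-linear contour (exact for
polygons; validated in the tests against a dense trapezoidal
integration oracle). A documented `parameterization="uniform"` option
assigns equal parameter increments per vertex instead; it recovers the
generating coefficients exactly when vertices are samples of the
parametric model at uniform `t`, and it is capped at the Nyquist index
`H ≤ ⌊n/2⌋`. Chord mode accepts any `H ≥ 1` because the underlying
piecewise-linear curve is continuous. Note that the two
parameterizations describe the same geometric curve with different
coefficient values: an ellipse with semi-axes (2, 1) is
`(a1, b1, c1, d1) = (2, 0, 0, 1)` under the uniform parameterization
but `(1.8284, 0, 0, 1.0730)` under chord length.

Landmark homology across tracings of one tooth is established by the
standard first-harmonic normalization: the start parameter is rotated
to the first harmonic ellipse's semi-major axis and the coordinate
frame is rotated so that axis defines phase zero (`a1 > 0`,
`b1 = c1 = 0` afterwards). Reflection is deliberately not normalized —
left and right molars are genuinely mirrored shapes and tooth
positions are analyzed separately.

The number of harmonics is configurable (default `H = 10`, i.e. 40
features); `cumulative_power` reports the captured harmonic power so
users can pick an `H` capturing ≥ 99%. For the synthetic molar shapes
used here, `H = 10` captures > 99.9%. Feature vectors keep the raw
coefficients by default (size carries signal because specimens are
pre-scaled to each other); `drop_normalized_entries=True` rescales by
`a1` and drops the three pinned entries, giving a size-invariant
`4H − 3` vector.

## Shape distance and consensus

Tracing error is Kendall's planar Riemannian shape distance: center
each landmark configuration, scale to unit size, treat it as a complex
K-vector `z`, and take `ρ = arccos |⟨z1, z2⟩|`, with range `[0, π/2]`.
It is invariant to translation, rotation and scale of either input and
does not quotient reflections, matching the EFA choice above.
Numerically the distance is evaluated through the equivalent stable
chordal form `ρ = 2 asin(‖z1 − e^{iβ*} z2‖ / 2)` because `arccos` near
1 loses half the available precision; identical shapes then score
`< 1e-12` rather than `~1e-8`. A byte-order canonicalization of the
two preshapes makes the function exactly symmetric in its arguments.

The consensus of several tracings is the full Procrustes mean:
preshapes are iteratively rotated (closed-form optimal rotations via
the complex representation) and averaged until convergence, then
rescaled to the mean centroid size of the inputs. A coefficient-space
mean (`coefficient_mean_shape`) is provided for comparison; the two
agree closely at small dispersion. In `worker_mean` grading mode the
reference is the mean of all tracings and, after exclusion, the mean
is recomputed once (two passes), so the stored consensus never
contains a rejected tracing.

## Synthetic data: what it emulates and what it does not

The original photographs and worker submissions are not
redistributable, so the generator defines truth directly in EFA
coefficient space. Each class template is a superellipse-with-waist
caricature of a molar outline (aspect ratio, corner squareness, waist
depth, overall size), fit with `H = 10` harmonics; specimens perturb
the template's amplitudes with zero-mean Gaussian noise of s.d.
`coeff_sd_scale × size / j` for harmonic `j`, so perturbations decay
with harmonic order.

Two stock layouts mirror the study design: a four-class population of
33 + 10 + 35 + 18 = 96 specimens with tooth positions distributed as
in the original sample, and the three-class second-lower-molar subset
(15 + 15 + 8 = 38) used for the classification experiment. The
Alcelaphini- and Hippotragini-like templates are deliberately similar,
because that is the pair the real data confuses.

Worker tracings are simulated per submission with independent
mechanisms:

* **correlated jitter** — Gaussian landmark noise smoothed circularly
  over a fraction of the perimeter (default 0.08); hand-tracing errors
  are locally smooth, and i.i.d. landmark noise would inject
  unrealistic high-frequency harmonics;
* **boundary bias** — an optional signed offset along the outward
  normal (tracing consistently inside/outside the edge), default 0;
* **gross errors** (default probability 0.05) — a different specimen's
  outline given a strong anisotropic stretch and a low-order radial
  bump, escalated until its distance from truth exceeds 0.2, so the
  rejection filter provably has work to do;
* **dropout** (default probability 0.05) — no submission, emulating
  the incomplete replicate counts of real crowdsourcing.

Calibration: the default `jitter_sd = 0.2` (units of the outline's
r.m.s. centroid radius) was chosen so that the median worker-to-expert
distance of canonical landmarks is ≈ 0.10, the order of magnitude of
reported crowd tracing error; `coeff_sd_scale = 0.03` puts the expert
condition at ≈ 76% LOOCV classification rate and log-loss ≈ 0.6 on the
38-specimen layout, the published operating regime. No claim is made
of matching the full error distribution of real workers; the generator
has no worker-skill heterogeneity, no learning effects, and no
photographic artifacts. Passing tests therefore demonstrate the
correctness and qualitative behaviour of the pipeline, not
quantitative agreement with any particular crowd.

## Classification experiment

`run_conditions` reproduces the four evaluation conditions: expert
outlines; the sampling distribution of log-loss over `R` datasets that
pick one random tracing per specimen (both "all tracings" and
"filter-survivors only" sampling are supported, since either reading of
the protocol is defensible); the filtered worker consensus; and the
consensus averaged together with the expert. Specimens with no usable
tracings are dropped from worker conditions and counted. Every outline
— truth and tracing alike — passes through the same
fit-normalize-regenerate step before any landmark comparison, exactly
as raw crowd images would.

Log-loss uses the natural logarithm (`−mean ln p̂(true class)`), so
uniform guessing over three classes scores `ln 3 ≈ 1.0986`;
probabilities are clipped at `1e-15` to keep zero-vote outcomes
finite. Argmax ties resolve to the lexicographically first label and
are logged. Forest settings are configuration, not claims: the API
default is 500 trees with `sqrt(p)` features per split; the
experiment-scale runs and the acceptance script use 30 trees, which at
`n = 38` specimens and 40 features gives log-losses within a few
thousandths of the 500-tree values at a fraction of the cost.

## Numerical choices and degenerate inputs

* Contour coordinates are pixel centers with the y-axis flipped to
  Cartesian; all downstream distances are invariant to this convention.
* Marching-squares boundaries get a light circular moving average
  (window 5 vertices, skipped below 16 vertices) to suppress the
  pixel-lattice staircase, which otherwise biases perimeter estimates
  upward by ~5%; with it, a rasterized disk's perimeter and area are
  recovered within 0.5%.
* Holes in a tracing are ignored (only the outer occlusal outline is
  used); multi-blob images resolve to the largest component, and
  border-touching foreground triggers a clipped-tracing warning.
* Self-intersecting polygons are refused by the rasterizer so the
  even-odd interior is well defined; an isolated single-pixel tracing
  yields the marching-squares diamond of area 0.5 px².
* Degenerate inputs raise: empty masks ("no tracing found"), zero-size
  configurations, a degenerate first harmonic, mismatched landmark
  counts.
* Determinism: every stochastic step derives its generator from
  explicit integer seed tuples; rerunning any stage with the same seed
  is bit-identical, and the pipeline manifest records config hash and
  artifact checksums to prove it.

## Run configuration schema (YAML)

```yaml
seed: 7
out_dir: runs/demo
template_preset: lm2_three_tribe   # default_four_tribe | mini_three_tribe
coeff_sd_scale: 0.03
harmonics: 10
landmarks: 150
resamples: 20                      # single-worker datasets drawn
drop_normalized_entries: false
write_masks: false
noise:
  jitter_sd: 0.2
  jitter_correlation_length: 0.08
  boundary_bias: 0.0
  p_gross_error: 0.05
  p_missing: 0.05
  n_replicates: 3
consensus:
  threshold: 0.2
  reference_mode: gold_standard    # or worker_mean
  include_expert_in_mean: false
forest:
  n_trees: 500
  max_features: sqrt
```

## Known limitations

* The published headline numbers that depend on the original
  photographs (real-data log-losses, the empirical error distribution)
  are not reproducible without those images; the package reproduces
  the statistics derivable from the published confusion tables exactly
  and the qualitative condition ordering on synthetic data.
* The Procrustes mean is not outlier-robust; robustness comes solely
  from the threshold filter.
* Only closed outer outlines are modeled — no partial/broken teeth, no
  open curves.
* `worker_mean` grading needs at least two tracings to be meaningful;
  with a single tracing the mean is the tracing itself and nothing is
  rejected.
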