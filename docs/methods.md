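# Methods

## Scope and design

`eamsim` is a forward-simulation and analysis pipeline for functional
substrate electroanatomic mapping (EAM) in post-infarct left ventricles.
Every stage is synthetic and seeded: the geometry, the infarct, the
electrophysiology, the electrogram synthesis and the statistical evaluation
are all generated by the package itself, so every number it reports can be
recomputed from a seed. The package quantifies two directional claims:
(i) maps paced from multiple sites (multiple-wavefront pacing) improve
detection of infarct remodelling, the more so the smaller the infarct, and
(ii) premature-stimulus (S2, decremental) maps expose additional
conduction-reserve abnormalities, improving both remodelling detection and
discrimination of the inner VT circuit.

## Idealized ventricle

The LV is a truncated prolate-ellipsoid shell voxelized on a regular grid
(all lengths mm, times ms, potentials mV). Defaults: epicardial semi-axes
34 × 34 × 70 mm, wall 10 mm, 70% of the long axis kept from the apex,
2 mm voxels (≈18,000 nodes). Ventricular coordinates are analytic:
apicobasal is linear in the long axis (0 apex, 1 base), rotational is the
angle about the long axis, transmural solves the interpolated-ellipsoid
equation (0 endo, 1 epi). Fibres lie in the local tangent plane with a
helix angle linear in the transmural coordinate, +60° (endo) to −60° (epi),
the standard rule-based convention.

EAM surfaces are closed genus-0 triangulations of each side built by
Fibonacci-lattice sampling of the (convex) truncated body followed by a
convex hull; the sample count is iterated until the mean edge length is
within 5% of the 2.0 mm target. The basal opening is closed with a shallow
dome ("cap") so each side is a closed manifold; cap points are flagged and
excluded from pacing-site selection, feature validity and all analyses —
they hover over the cavity and have no physiologic meaning. Pacing sites
are selected per side by farthest-point sampling under the surface geodesic
metric (Dijkstra over mesh edges); the default 50 sites per side gives the
100-site layout used by the cohort design.

## Synthetic infarcts

`generate_infarct` thresholds a noisy distance field: w(x) = min over foci
of |x − focus|·(1 + 0.35 z(x)) with z spatially smoothed white noise, and
the threshold set at the target-fraction quantile, so the achieved
remodelled fraction equals the target exactly. Foci (1–4) are seeded with
a mild mid-wall bias so the remodelling reaches both surfaces. The dense
core is the interior of the remodelled set — nodes farther than a rim
distance (≥1.8 voxels, so the core never touches normal tissue even
corner-to-corner) from non-remodelled myocardium — and the rim depth is
chosen from a small candidate set to approach the requested core:border-zone
ratio. `carve_channels` relabels a corridor of core to border zone along a
core-crossing shortest path, preserving the remodelled fraction.

For induction studies, `engineered_channel_substrate` provides a
deterministic substrate with ring topology: a dense-core sector spanning
110° of rotation over the full apicobasal and transmural extent, crossed by
one border-zone channel. The only re-entrant path is rotational — around
the ventricle through healthy tissue and back through the slow channel —
which makes sustained anatomical re-entry achievable in a ventricle whose
healthy-tissue wavelength (CV × APD ≈ 10 cm) exceeds any purely functional
circuit the small model could host.

Cohorts spread per-heart target fractions evenly over [0.10, 0.50] — a
range bracketing the reported clinical median of ~28% remodelling — and
split at the cohort median into hLIR (larger) and hSIR (smaller) groups.
All hearts share one geometry by default; all randomness flows from one
cohort seed through per-heart spawned seeds.

## Monodomain propagation

Two-variable Mitchell–Schaeffer kinetics on the voxel lattice:

    du/dt = ∇·(D∇u) + h u²(1−u)/τ_in − u/τ_out
    dh/dt = (1−h)/τ_open  (u < u_gate),   −h/τ_close  (u ≥ u_gate)

with u ∈ [0,1] mapped to Vm = −80 + 100u mV. The diffusion operator is an
18-neighbour finite-difference stencil whose edge weights satisfy the
second-moment condition Σ w δδᵀ = 2D with per-edge tensor averaging — a
consistent discretisation of ∇·(D∇u) with nonnegative weights for
anisotropy ratios up to 4:1, and natural no-flux boundaries. Dense core is
excluded from the domain entirely. Explicit Euler stepping at dt = 0.1 ms
with a periodic stability check (|u| > 3 or non-finite aborts with a
diagnostic); Vm is recorded at 2.5 ms (400 Hz).

Parameter defaults (per tissue):

| parameter | normal | border zone | units | role |
|---|---|---|---|---|
| τ_in | 1.0 | 2.0 | ms | upstroke; slowed in BZ (reduced excitability) |
| τ_out | 12 | 20 | ms | repolarization rate |
| τ_open | 40 | 120 | ms | gate recovery; slow BZ recovery → decrement |
| τ_close | 90 | 200 | ms | plateau duration (APD ~170 / ~250 ms) |
| u_gate | 0.13 | 0.13 | – | excitation threshold |
| d_long | 1.35 | 0.55 | mm²/ms | CV ≈ 55 / 22 cm/s along fibre |
| d_trans | 0.34 | 0.275 | mm²/ms | 4:1 (normal), 2:1 (BZ) anisotropy |

τ_in is deliberately slower than the classic 0.3 ms so the depolarization
front stays resolvable on 2 mm lattices: the measured planar CV changes by
<2% between 1 mm and 2 mm grids, and <3% between 1 mm and 0.25 mm. The
diffusivities were calibrated once on a slab to the stated CV targets;
the recovery constants were chosen so that (a) a premature stimulus at
150 ms coupling fails while 310 and 360 ms capture (the protocol's two
couplings), (b) most pacing sites capture S1/S2 (≈90–100% on test models,
mirroring clinical capture-rate behaviour), and (c) the border-zone
effective refractory period is shorter than the engineered circuit's cycle
length (~420 ms) so re-entry sustains. Within those constraints the values
are ordinary phenomenological choices, not fits to any dataset.

Stimuli are intracellular current injections in a 2 mm ball for 2 ms at
~2× the surface-site diastolic threshold (amplitude 3.2 /ms). On a 2 mm
lattice a 2 mm ball covers 0–4 voxel centres, which cannot source a wave,
so the footprint is padded to the nearest 8 conducting nodes within 2.5
radii — a coarse-lattice electrode approximation.

Capture is declared when ≥10% of conducting nodes farther than 10 mm from
the site activate within the beat window (activation = upward crossing of
−20 mV). Programmed stimulation (`induce_vt`) drives each of the
farthest-point-sampled induction sites (default 6 beats at 600 ms; the
desk-scale studies use 3 beats at 450 ms), then scans S2 downward in 10 ms
steps from a checkpointed post-drive state, falling back to an S2+S3 scan
after block. Re-entry is a node re-activating periodically at least twice
(three upstrokes) after the last stimulus; the cycle length is the median
inter-activation interval at the most-active node, and episodes whose exit
sites lie within 10 mm with cycle lengths within 10% are deduplicated as
one VT.

## Unipolar electrograms

Infinite homogeneous volume conductor:
φ(x) = −(σ_i/4πσ_e) Σ_nodes ∇Vm(y)·(x−y)/|x−y|³ h³, with central-difference
gradients (one-sided at boundaries and beside scar), a conductivity ratio
of 0.4, and the kernel zeroed within one voxel diagonal of the observation
point (singularity regularization). For a fixed geometry the map from node
Vm to point potentials is assembled once as a dense single-precision
operator and reused across time samples, beats and pacing sites; the
spatial mean of Vm is removed before application, which keeps the analytic
annihilation of constant fields exact in single precision. Signals are
produced at 400 Hz (polyphase resampling if the solver output interval
differs).

## EAM features

Per point and beat: V_amp = max − min of the signal; FP = the area under
the one-sided periodogram of the de-meaned signal with the convention that
(by Parseval) it equals mean((x−x̄)²)/Δt, in mV²/ms; EGM_dur = span between
the first and last 11-sample (27.5 ms) sliding windows whose SD exceeds 10%
of the maximum window SD (0 for flat signals); FI counts deflections in the
residual after subtracting a zero-phase 30 Hz low-pass template — each
negative-going pair of consecutive residual extrema with peak-to-trough
above max(0.05 mV, 4× the median absolute residual, 0.25× the largest such
pair) counts once, so an isolated R–S deflection scores 1 and filter
ringing is suppressed; CV fits a plane to activation over each triangle and
averages element speeds (1/|∇t|, capped at 200 cm/s) whose centroids lie
within 5 mm; IC counts distinct members of the 16 equal isochrones (spanning
that map's activation range) within a 1 cm geodesic radius (Euclidean
fallback available). Surface activation times come from each point's linked
volume node. Scalar reference implementations are kept alongside the
vectorized batch paths and the tests enforce their agreement.

## VT circuits

The exit site is located automatically (the clinical analogue is a manual
read of the 3-D activation sequence): among remodelled nodes within 2 mm of
normal tissue, crossing events where a boundary node fires shortly before
an adjacent normal node mark the wavefront leaving the substrate; the
earliest such event per cycle nominates a node and the majority vote across
cycles wins (ties to the lowest node id). On the engineered substrate this
lands within one voxel of the designed channel mouth. The circuit window is
exit-centred: 0.4 apicobasal units × 72° rotational (wrapping the 0/360
seam; clamped shifts preserve width at the apicobasal ends) × full wall.
One cycle, anchored at the exit activation, is split into 8 equal
isochrones; surface points take the modal volumetric isochrone within 5 mm
(ties to the lower index); outer = isochrones 1–4, inner = 5–8, split by
side into four subregions whose per-map feature means feed the circuit
classifiers. Subregions can be empty (purely endo-, epi- or mid-myocardial
circuits) and are then flagged and excluded.

## Evaluation

Concordance is the Pearson correlation of a feature between two maps over
common valid points (optionally restricted to remodelled or non-injured
points; Spearman by flag). Remodelling labels on the surface use the ≥10%
remodelled-myocardium-within-5 mm rule, sweepable to 50%. Sites are ranked
by mean geodesic distance to the remodelled zone (or to the VT exit
projection), ties by site id; a side with no remodelled points ranks last.
The incremental logistic ladders add covariates in proximity order —
skipping non-captured maps with order preserved — with per-heart z-scored
features and weak L2 regularization (C = 1000); fits and metrics are
in-sample, matching the evaluation protocol of procedure-time mapping
(no held-out split). AUROC uses the exact rank-statistic form of exhaustive
concordant-pair counting (ties 0.5); F1, sensitivity and specificity use a
0.5 probability threshold. Group contrasts use two-sample or paired
t-tests; an all-zero paired difference returns (statistic 0, p 1), other
zero-variance cases return NaN sentinels.

## Problem sizes

The package's studies run at desk scale: the standard cohort is 8 hearts on
a 22 × 22 × 44 mm shell (8 mm wall, 2 mm voxels, ≈5,700 nodes), 2.5 mm
surfaces (≈2,900 points), 10 pacing sites per heart with S1 everywhere and
S2 maps at the two most infarct-proximal sites, and regression ladders to
N = 8. VT induction uses 4 sites with a 3-beat 450 ms drive. The full
48 × 100 × 3 design (14,400 pacing simulations) is expressible through the
`full` tier of the experiment config and runs the identical code path; it
is a multi-hour batch rather than an interactive run.

## What the generator does and does not emulate

The synthetic cohort reproduces the *structural logic* of post-infarct
substrates — a non-conducting core, a slow rim, channels, a controllable
remodelled fraction spanning small to large infarcts — and the functional
consequences the analyses rely on (direction-dependent activation, low
voltage and slow conduction over scar, decremental border-zone responses,
inducible anatomical re-entry). It does not emulate patient-specific scar
morphology from imaging, wall-thickness or fibre heterogeneity, the right
ventricle, Purkinje-mediated activation, bath loading on electrograms, or
electrode geometry (bipolar signals are out of scope by design). Passing
tests therefore demonstrate internal consistency and the *direction* of the
mapping-strategy effects under controlled conditions, not quantitative
agreement with any patient cohort: headline clinical numbers (e.g.
concordance r ≈ 0.87 for voltage) depend on patient-derived models that are
not reproducible here, and the package makes no claim to them.

## Numerical choices and degenerate inputs

Explicit dt must satisfy the lattice stability bound (checked at runtime);
activation times are step-quantized at 0.1 ms. The convex-hull surface
contains occasional sliver triangles; CV's 200 cm/s element cap and the
5 mm averaging absorb them. Triangles with undefined or equal vertex times
are skipped and points with no valid element masked. Flat signals yield
V_amp 0, FP 0, EGM_dur 0, FI 0. Empty map subsets return NaN sentinels
rather than raising; single-class label sets raise. Farthest-point
sampling, ranking and modal projection all break ties deterministically
(lowest index), and every stochastic step takes an explicit seed, so
identical configurations are byte-identical on re-run.

## Known limitations

Coarse lattices underestimate transverse CV more than longitudinal (the
wavefront is a few voxels wide); the analytic ventricular coordinates are a
functional stand-in for Laplace-solver coordinates and are exact only for
the idealized ellipsoid; the exit-site heuristic assumes the re-entrant
wavefront crosses a remodelled boundary each cycle and can fail for purely
functional re-entry; in-sample regression metrics overstate out-of-sample
accuracy by construction and are used only for within-package comparisons
between pacing strategies.
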