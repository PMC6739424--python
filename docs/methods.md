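# Methods

## Peptide-frame lipid localization maps

The density mapper answers: *where, in the reference frame of a
membrane-bound amphipathic helix, do lipids of each species concentrate?*
Lab-frame maps smear any helix-fixed feature as the peptide rotates in the
membrane plane, so every frame is rotated into the helix frame before
averaging.

Per sampled frame the steps are: (1) wrap the (x, y) of each matching
lipid marker into the periodic box and increment exactly one bin of a grid
centred on the box centre (default 1 Å bins tiling the whole box, so the
bin total always equals the marker count); (2) fit the in-plane rotation θ
of the backbone markers against a reference structure by least squares —
the closed form θ = atan2(Σ(x_ref·y − y_ref·x), Σ(x_ref·x + y_ref·y))
after centroid removal is the exact minimizer, verified in the tests
against an explicit 10⁻⁴-rad grid search over rotation matrices; (3)
rotate the count grid by −θ about the grid centre, sampling with a
third-order spline from a 3×3 periodic tiling so the margin exceeds half
the grid diagonal; (4) average over frames, skipping the first 100 ns of
the trajectory (equilibration) and sampling every 250 ps — both
configurable. Maps are emitted as raw mean counts per bin and, optionally,
normalized to sum to 1 ("localization probability").

Numerical choices. Spline undershoot is clipped to zero only **after**
averaging: single-frame histograms are spiky, and clipping each frame's
ringing would add ~65% spurious mass on sparse maps; after averaging the
ringing has largely cancelled and the residual clip is small. Rotation by
−θ (not +θ) is pinned by a delta test: a marker rigidly co-rotating with
the helix must collapse to a stationary peak. The reference structure is
built from the first used frame's backbone — centred, principal axis on x,
with the chain direction (first → last marker) along +x; without that
orientation rule the helix frame is defined only up to a two-fold flip.
Leaflets are taken from the trajectory's labels (synthetic data carries
them); the analysis field of view defaults to a 100×100 Å patch, matching
the scale on which such maps are usually displayed.

The independent oracle (`oracle_density`) rotates raw marker coordinates
by −θ about the box centre (with periodic wrap), bins afterwards, and
never interpolates. It is exactly invariant under a global rigid rotation
of the system, and the spline route must agree with it: Pearson r > 0.95
at 1 Å bins on enrichment-site trajectories, with the mean absolute
difference shrinking as bins refine.

## Synthetic membrane trajectories

The generator emulates the statistical structure the mapper assumes, not
membrane physics. Markers are ideal points performing 2D periodic Gaussian
random walks; the default composition is the study bilayer (414 POPC, 120
cholesterol, 60 DOPS, 6 PI4P per membrane), split evenly between leaflets
with odd remainders assigned to the embedded (helix-containing) leaflet.
The helix is a rigid rod of backbone markers whose orientation performs
rotational diffusion (σ = 0.02 rad/frame). Enrichment sites are Gaussian
wells (default depth 5 kT, width 4 Å) fixed in the helix frame; affected
species in the embedded leaflet take Metropolis accept/reject steps on the
instantaneous potential, which preserves the Boltzmann distribution for a
static helix. Two PI4P sites on opposite helix flanks are the default,
reflecting the strong, persistent PI4P association the maps are meant to
reproduce; 5 kT (~150× local enhancement) produces pronounced hot spots
while still allowing exchange, which a 3 kT well does not at only three
embedded PI4P markers.

Three sampling choices matter for verification. First, affected species
are **initialized from the Boltzmann distribution** of the site potential
(rejection sampling): lipid diffusion is slow enough that a cold-started
trajectory would not equilibrate within the runs used here, and time
averages would not match ensemble averages. Second, unaffected markers
start on a jittered lattice per leaflet rather than iid-uniform: an
equilibrated fluid membrane has liquid-like short-range order, and uniform
draws leave large-scale density clumps that persist for the whole run.
Third, the default diffusion coefficients (2×10⁻³ Å²/ps phospholipids,
3×10⁻³ cholesterol) sit at the fast end of reported lipid mobility so that
successive 250 ps samples decorrelate at the 1 Å bin scale; real atomistic
membranes mix more slowly and would need proportionally longer trajectories
for the same map quality. Uniformity checks use long free-diffusion runs
(12800 frames) because the coverage variance of random-walk sampling
scales with box area / (frames × markers) independently of bin width.

What the generator does **not** emulate: excluded volume and lipid–lipid
interactions, leaflet coupling, membrane undulations, peptide internal
dynamics, and z-dynamics (leaflets sit at fixed ±18 Å). Passing tests
therefore certify the analysis pipeline — alignment, binning, rotation,
averaging — not any membrane physics.

With only 6 PI4P molecules at the paper-scale composition, per-seed
occupancy of a single site is close to a coin flip (a marker is either
trapped for most of a run or never arrives), so seed-robust map statistics
use either the more abundant anionic species (DOPS, 30 embedded markers)
as the site target or a deliberately PI4P-enriched test membrane; both
choices are stated where used.

## Relative plasma-membrane fluorescence

Profiles are sampled at unit-pixel spacing by bilinear interpolation along
user-given or automatically placed segments. Outer peaks on the crossing
profile are local maxima with prominence ≥ 10% of the profile range
(threshold configurable); F_cross averages the six samples at the two
outer peaks ± 1 px. F_in and F_out are plain profile means, and
relative F_PM = (F_cross − F_out)/(F_in − F_out) is exactly invariant
under I → αI + β because every statistic is affine-equivariant. A single
broad flat maximum (membrane indistinguishable from cytosol) degenerates
to coincident peaks at the plateau midpoint, so a uniform cell reads
exactly 1.0; genuinely flat profiles are an error. Automatic placement
thresholds the image (Otsu), takes the largest component's centroid and
equivalent radius, and draws the crossing line through the centroid along
the longer image axis, the inside line as a chord within half a radius of
the centroid, and the outside line along the far image edge.

The image generator renders an annulus (default ring width 8 px) over a
disc on a dark background, then Gaussian blur (σ = 1 px) and additive
Gaussian noise. The ring default keeps the membrane resolved relative to
the blur so the ±1 px peak averaging is unbiased (< 0.2%); narrow rings
under heavy blur bias F_cross low, which is a property of the line-profile
method itself. Poisson shot noise and multi-cell scenes are out of scope.

## Progress-curve kinetics

ΔEm530(t) = (raw(t) − raw pre-ATP baseline) − (bg(t) − bg pre-ATP
baseline), with the background interpolated linearly onto the raw grid and
negative values retained. Initial velocity is the least-squares slope over
[0, t_w], where t_w is the first up-crossing of the smoothed curve
(boxcar, ~2% of points) through max(20% of the plateau estimate, 3× the
point-noise level); the plateau estimate is the mean of the final 10% of
points, the noise level comes from median absolute successive differences,
and the fallback window is the first 10% of points. The noise floor
matters: low-substrate curves never approach their plateau, and without it
baseline wiggle truncates the window to a handful of points of pure noise.
The policy is configurable (`plateau_fraction`, `fallback_fraction`) and
exact on linear curves.

The allosteric sigmoidal model v = Vmax·S^h/(Khalf^h + S^h) is fitted by
bounded nonlinear least squares with multi-start initialization (h₀ ∈
{0.5, 1, 2, 4}, Vmax₀ = max v, Khalf₀ interpolated at half-max, h ∈
[0.2, 10]), keeping the lowest-RSS solution; h = 1 reduces the model to
Michaelis–Menten, and Khalf is reported as the apparent Km. Optional
residual-bootstrap confidence intervals are seeded. The probe calibration
is an ordinary least-squares line with intercept over standards inside the
0.125–1 mol% linear range (outside points excluded and reported); initial
velocities can be converted from signal/s to mol%/s by the fitted slope.
In the synthetic assay, velocities are in product mol%/s and the
calibration slope converts to signal units, so progress curves plateau at
full substrate conversion (product capped at S mol%).

## Corrected FRET

a is regressed from donor-only series (F on D), b from acceptor-only
series (F on A). The CFP/Venus variant fits through the origin with no
offset — its published correction has none — while the Trp/Dansyl variant
estimates a shared constant offset c jointly from both series, treated as
an instrument constant. cFRET = F − a·D − b·A − c, negatives retained.
Coefficients are instrument-specific: the reference presets are shipped
for comparison, never applied silently to new data. On noiseless series
the estimators are exact to numerical precision, and a FRET component
injected by the spectra generator is recovered within sampling error.

## Pipeline and reproducibility

A YAML config selects stages and parameter blocks with one global seed;
per-stage seeds derive from the global seed plus a stage-name CRC offset
(all below 2³¹). The manifest records package version, per-stage seeds and
parameters, and SHA-256 checksums of every output, so identical configs
give byte-identical outputs. `scripts/acceptance.py` recomputes the
headline quantities from scratch at the study conditions: composition
counts (exact), apparent-Km recovery at 6.2 and 1.5 mol% (2% noise, three
replicates), density/oracle agreement on a 2000-sampled-frame site
trajectory and flat-map uniformity on a 12800-frame free-diffusion run,
alignment worst-case error over 100 random rotations, relative F_PM
recovery (noiseless and at 5% noise, 50 seeds), bleed-through estimation
at the reference coefficients, and mass conservation. Problem sizes were
chosen so the full recomputation takes about a minute on one CPU.

## Known limitations

Trajectory I/O is the package's own columnar text format (adapter hooks
for standard MD formats are an extension point, not core). Density maps
are 2D only; no order parameters, contact lifetimes, or 3D densities.
Automatic cell quantification assumes one roughly convex bright cell.
Kinetic fitting is per-condition (no global fits across conditions), and
the initial-window policy, while configurable, is a heuristic on curves
with strong early curvature.
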