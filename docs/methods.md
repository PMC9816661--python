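# Methods

## The agent-based model

The simulation domain is a 1 mm cube. Tumor cells live on a 50×50×50
lattice (20 µm site spacing, at most one cell per site); the vasculature
lives on a 10-fold finer 500³ lattice (2 µm), reflecting the smaller
calibre of microvessels. All distances are computed in µm; fine-lattice
coordinate = 10 × coarse coordinate. One iteration represents 6 h exactly
and the default run is 300 iterations (75 days).

**Cells.** Two proliferative phenotypes: stem cells (limitless replicative
potential, division probability 0.05 per iteration, symmetric
stem + stem division with probability 0.05, else stem + fresh progenitor)
and progenitors, which divide with probability `p_div` per iteration until
their lineage has used `div_lim` divisions. Progenitor division is
interpreted generationally: both post-division cells carry the incremented
division count (a telomere-style budget of 2^div_lim descendants per
lineage), and a cell reaching the limit becomes senescent — it stays on the
lattice, blocking space, until removed with probability 0.1 per iteration.
A daughter is placed on a uniformly chosen empty Moore (26-)neighbor site;
a fully surrounded cell simply fails to divide (spatial inhibition). Each
daughter is high-migratory with probability 0.05. Migration converts the
continuous rates (8.3 / 0.83 µm/h for high/low) into expected lattice steps
per iteration (rate × 6 h ÷ 20 µm); the fractional part is realized as a
Bernoulli extra step, and each step picks one of the 26 directions
uniformly, rejected if occupied or out of bounds. Cells are processed in a
uniformly shuffled order each sweep.

**Initialization.** 20 stem + 80 progenitor cells packed into the corner
nearest the origin (sites sorted by squared distance from the corner,
lexicographic tie-break — a compact blob equivalent to a ~5×5×4 block at
n = 100), stems interleaved by seeded uniform choice. Eight mature,
perfused vessels run as straight lines along the three boundary faces
adjacent to the corner, at lateral offsets of one-fifth and three-fifths of
the domain.

**Oxygenation.** A cell is normoxic iff its Euclidean distance to the
nearest perfused vessel site is ≤ 100 µm (a classic oxygen diffusion
limit); otherwise hypoxic. Hypoxic cells divide at 0.5× their probability
and migrate at the high rate regardless of class (direction stated by the
underlying model; magnitudes are this package's choice, both exposed in
`ABMConfig`).

**Angiogenesis.** Hypoxic cells are VEGF sources. Sprouting substrates are
the mature vessels and — once a sprout loop has closed and carries blood —
perfused chains, which have functionally matured into vasculature
(angiogenesis is recursive; with only the 8 boundary vessels as substrates
the network stays a radial line bundle, unlike vascularized tumors). Each
hypoxic cell can recruit at most one sprouting attempt per iteration,
assigned to its nearest perfused element; an element attempts at most once
per iteration and succeeds with probability 0.2 × (1 − d/200 µm), where d
is the distance to the nearest recruiting hypoxic cell. This VEGF-supply
competition (tip-cell competition for a limited ligand) makes sprouting
scale with the hypoxic population and cease as hypoxia resolves; without
it, per-element attempts over a growing perfused network produce unbounded
chain proliferation. Sprout tips advance 20 µm per iteration (10 fine
sites) along the discrete ray toward the nearest cancer cell (exact
squared-distance ties broken by lowest lexicographic cell coordinate),
laying stalk behind them. A tip within 20 µm of another sprout or a mature
segment fuses with it (anastomosis), closing the chain; a sprout becomes
fusion-competent only once its stalk is longer than the anastomosis radius,
else every sprout would fuse back into its parent at birth. A chain is
perfused iff it is closed and both attachment points connect through the
vessel network (breadth-first search over the attachment graph; open
stalks conduct) to the mature vasculature. Vessels are never pruned.

**Update order per iteration:** perfusion update → oxygenation → sprouting
→ tip migration → anastomosis → divisions → migrations → senescent death.
The cell count obeys N(t+1) = N(t) + divisions − deaths exactly, checked
every iteration.

**Reproducibility.** One root seed per run drives a numpy Generator; the
division and migration sweeps are numba kernels seeded from that stream,
so identical config + seed gives bit-identical output. Replicate r of a
multi-run experiment uses seed root + r, recorded in dataset metadata.

## Surrogate models and fitting

Candidates: generalized Gompertz dN/dt = N^λ(δ − γ ln N) (the alternative
reading λN(δ − γ ln N) is available behind a flag), generalized logistic
dN/dt = γN(1 − (N/K)^λ), and von Bertalanffy dN/dt = αN^γ − βN. vB and GL
have exact closed forms (Bernoulli and logistic substitutions), used as the
default evaluation path; the adaptive numerical route (LSODA, rtol 1e-8,
atol 1e-10; |1−γ| < 1e-6 routes vB to its exponential limit) is retained
and cross-checked against the closed forms in the tests. The GG equation is
integrated in u = ln N with a blow-up event that truncates divergent
parameter draws. Trajectories are anchored so N(times[0]) = N0 on every
route.

Fits minimize χ² = Σ((zᵢ − yᵢ)/σᵢ)² with z the replicate mean and σ the
standard error, floored at 10⁻³ × max z (replicate SE can be zero when all
runs coincide early). Each model has 3 free parameters, estimated on a log
scale by trust-region least squares from 20 Latin-hypercube starts over
data-scale-aware log-uniform boxes. N0 is pinned to the recorded initial
size (`meta["N0"]`, e.g. a known inoculum) when the dataset carries one,
else to the first observation. ABM iterations are converted to days
(× 6/24) before fitting, so SM rates are per-day in both pipelines.

AIC/BIC use the Gaussian concentrated-likelihood forms
n·ln(RSS/n) + 2k and n·ln(RSS/n) + k·ln n. For multi-dataset candidates the
per-dataset RSS, n and k are summed before scoring. Note that the GG family
reproduces vB trajectories to within ~0.1% over tumor-relevant ranges, so
on vB-generated data the GG/vB argmin is decided by noise; the meaningful
selection property (asserted in the tests) is that the generating model
always sits inside the AIC indistinguishability band of the winner.

## Profile likelihood and identifiable combinations

Each parameter is profiled by fixing it on a grid (41 log-spaced points
spanning ×/÷10 around the MLE, grown adaptively up to ×/÷10⁴) and
re-optimizing the others, warm-started walking outward from the MLE. The
95% CI is read off where the profile crosses χ²_min + 3.84 (χ²₀.₉₅, 1 df);
each crossing is refined by bisection to 0.2% relative accuracy, since the
first grid point can land far outside the confidence region and coarse
linear interpolation would badly underestimate the interval. Profiling is
confined to the parameter's search box; a side that never crosses the
threshold before the box edge is flagged practically non-identifiable, with
the box edge reported as the interval endpoint (the convention of standard
profile-likelihood tooling). On a linear-Gaussian test problem the profile
CI matches the analytic MLE ± 1.96·SE to 0.06% of the SE.

The identifiable combination γ = (β + a)/(β + b) is fitted to the
(β, re-optimized γ) pairs harvested from the below-threshold portion of the
β profile: the form is linear in (a, b) after clearing the denominator, so
a linear solve seeds a nonlinear refinement. A near-constant γ raises a
degenerate-combination error; the pipeline then falls back to using the
profile pairs directly as the admissible (β, γ) set.

## Surfaces and regions

Profile CI endpoints at the 9 sampled (p_div, div_lim) combinations
({0.05, 0.125, 0.245} × {8, 12, 15}) are bilinearly interpolated
(scipy RegularGridInterpolator on the irregular rectangle) into lower and
upper confidence surfaces; evaluation outside the sampled rectangle is an
error — no extrapolation. `div_lim` is treated as continuous for
interpolation; admissibility output also reports the integer-div_lim
subset. A surrogate value s is admissible at an ABM point where
lower ≤ s ≤ upper; per-pair regions are intersected across SM parameters
and unioned over the data-admissible pairs (25 β samples across the
admissible range by default, γ from the combination). The default region
grid is 101×101.

## Synthetic calibration data

Real calibration data are xenograft volume curves rising sigmoidally to a
~2,000 mm³ plateau. The generator emulates them with a vB trajectory
(defaults α = 0.18·2000^(1/3) ≈ 2.268, γ = 2/3 — surface-limited growth —
β = 0.18/day, N0 = 50 mm³, plateau exactly 2,000 mm³) times multiplicative
lognormal noise with unit mean and CV 5% per replicate (volumes are
positive; caliper error scales with size); z = mean and σ = SE over 8
replicates. The default measurement grid is every 3 days to day 39 (14
points, a typical xenograft cadence); the parameter-recovery study uses 20
points every 4 days to day 76, a design that spans the plateau (β is weakly
identified from pre-plateau data). What the generator does not emulate:
inter-animal growth-rate heterogeneity, measurement dropout, engraftment
failures, and serially correlated caliper error — so passing recovery tests
demonstrate statistical correctness of the machinery under the stated noise
model, not robustness to those real-data features. With 8 replicates the
estimated SEs are themselves noisy (~27% CV), which leaves the 95% profile
CIs slightly anti-conservative under the fixed 3.84 threshold (~80–90%
observed coverage); exact-variance weights recover ~90%.

## Morphology metrics

Box-counting dimension: occupied ε-boxes are counted for dyadic
ε ∈ {1, 2, 4, …} fine-lattice units up to a quarter of the longest
bounding-box extent, and the dimension is the least-squares slope of
log N(ε) against log(1/ε) over all sizes (a straight line measures ~1, a
filled cube ~3). Tumor surface area and volume come from an alpha complex
over the voxel-corner cloud of the cell snapshot (corners, not centers, so
a 10³-voxel block measures as its true 200 µm cube): Delaunay tetrahedra
with circumradius ≤ α (default 3 voxel spacings = 60 µm) are kept, with
geometrically small slivers retained via a min-enclosing-ball proxy (half
the longest edge) because joggled lattice points otherwise punch spurious
internal faces; volume is the summed tetrahedral volume and surface area
the summed once-only boundary triangles. Components smaller than 50 voxels
(26-connectivity, strict inequality) are removed first to exclude migrated
satellites. Compactness is (36π)^(1/6)·Vol^(1/3)/√SA — exactly 1 for a
sphere (it is the square root of classical sphericity) and scale-invariant;
the non-dimensionless variant dividing by SA is available behind a flag for
comparison with the source's typeset formula. Replicate comparisons use
Welch's unequal-variance t-test.

## Problem sizes used in the checks

The end-to-end closure study runs the full pipeline at 100 ABM iterations
with 3 replicates per grid node and verifies the inferred region contains
the generating (0.125, 12). The morphology study runs 300 iterations with
3 seeded replicates per parameter set. The recovery study uses 50 seeds.
These sizes give stable, seeded results on a single CPU.

## Known limitations

* The vascular networks are one-voxel-wide polyline chains. Their
  box-counting dimension measures ~1.2–1.4 at the default parameters —
  line-like at fine scales — rather than the ~1.9–2.0 reported for densely
  vascularized tumors; reproducing that would require vessel calibre,
  tortuosity and branching detail beyond this model's resolution.
* Tumor growth at aggressive parameters can overshoot and relax toward a
  quasi-steady population (lineage exhaustion outpaces stem replenishment);
  the monotone ordering of final size in (p_div, div_lim) holds for
  replicate means across the sampled rectangle's corners.
* vB parameters fitted to pre-plateau ABM output sit near the exponential
  ridge (γ → 1, α − β fixed), where β is practically non-identifiable; the
  method then correctly reports wide admissible regions rather than point
  estimates.
* Only the 2-D (p_div, div_lim) ABM parameter space is implemented;
  the API keeps the node/surface structure general but higher-dimensional
  sweeps are out of scope.
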