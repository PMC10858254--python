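# Methods

This note documents the models, the parameters that matter, the
synthetic-data generators and their limits, and the numerical and design
choices behind `larvaconnect`.

## Domain and coordinates

All positions are WGS84 lon/lat degrees; timestamps are UTC; grids are
regular lon/lat with half-open cells `[edge, next_edge)` and a boolean
land mask. Metre↔degree conversion is local equirectangular (1° lat =
R·π/180 m, 1° lon scaled by cos φ, R = 6371 km). At fjord scales the
resulting position error is orders of magnitude below the 2 km settlement
radius, the only length scale a decision depends on. Distances for
settlement scoring use the haversine formula.

A regular grid replaces the unstructured triangular meshes of operational
coastal models deliberately: it keeps interpolation simple and preserves
every downstream contract. `FlowField` is format-agnostic (NetCDF with
dims time/lat/lon, variables u, v in m s⁻¹, land_mask), so a mesh-based
provider could be swapped in behind the same sampling protocol. Flow is
2-D at a single nominal depth (default 6 m, metadata only): the release
protocol this package emulates used one fixed depth and no vertical
migration, so depth is not a dynamic dimension.

## Synthetic flow generator

`generate_flow` writes hourly fields as the sum of

* a steady northward current `mean_current_speed` (default 0.1 m/s) —
  the predominant south-to-north alongshore transport regime;
* a rotary tide `(u, v) = a·(cos, sin)(2πt/T)` with amplitude
  `tidal_amplitude` (default 0.3 m/s) and period `tidal_period_h`
  (default 12.42 h, the M2 semidiurnal constituent);
* eddy-like noise: white noise low-pass filtered with a Gaussian of 5
  cells, rescaled to RMS `noise_speed` (default 0.05 m/s) over water,
  with lag-1-hour temporal autocorrelation 0.9. This gives spatially
  smooth, slowly evolving variability without any turbulence physics.

`diffusivity_D` (default 10 m²/s) is the horizontal turbulent
diffusivity handed to the tracker. It is a free parameter: no value is
fixed by the protocol the package emulates, and users should treat it as
a tuning knob with the 1–10 m²/s range typical of coastal dispersal
studies.

What the generator does **not** emulate: baroclinic 3-D structure, wind
events, wetting/drying of shallows, and realistic bathymetric steering.
Tests passing on these fields show the *pipeline* is correct, not that
any particular coastline is well predicted.

## Particle transport

Releases: `release_rate` particles (default 20) at every whole hour at
every site for the first `release_days` (default 14) of a
`total_days` (default 34) run. Integration: classical RK4 with
`dt_s = 360 s` on the interpolated velocity — bilinear in space with land
cells excluded from the stencil (weights renormalised over wet
neighbours), linear in time between hourly fields. Diffusion adds
independent N(0, √(2DΔt)) metre offsets per axis after the deterministic
step. Positions are recorded hourly.

Boundary policy: a step that would land on shore or leave the domain is
cancelled and the particle holds its previous position ("no-slip hold").
This keeps particle conservation trivially exact and testable; reflecting
or killing policies could be substituted behind `apply_boundary`.
Particles never die and never stop — settlement is inferred afterwards
from recorded positions, which is what makes a multi-day settlement
window meaningful.

Verified accuracy (test suite): uniform-flow displacement exact to
<10⁻⁶ relative; rigid-rotation radius drift ~10⁻⁸ per revolution at
dt = 360 s; agreement with a 1 s forward-Euler oracle within 0.02 m over
24 h in a smooth shear field; diffusion-only ensemble MSD within 5% of
4Dt at 10⁴ particles.

## Settlement and connectivity

A particle released at site i counts toward destination j if any recorded
position in the final `settle_window_days` (default 7) lies within
`settle_radius_m` (default 2000 m) of j — at most once per (particle,
destination), the distinct-particle convention standard for connectivity
matrices. A particle may count toward several destinations; "accumulation"
is ambiguous between distinct particles and particle-hours, and the
distinct-particle reading keeps row sums bounded by releases and hence
testable. Particle-hours are retained where the particles/m³ unit demands
them: `density_map` accumulates per-cell particle-hours over a half-open
window and divides by (window hours × cell area × `layer_thickness_m`).
The layer thickness defaults to 1 m and is explicit config, because the
volume convention behind particles/m³ is otherwise unstated.

Source/sink roles are net flux (row sum minus column sum, diagonal
excluded); `n_sources` is the off-diagonal in-degree of a destination.
Stepping-stone generation counts are shortest directed path lengths in
the graph with edges where counts ≥ `min_count` (default 1 — no
threshold is canonical, so the permissive choice is the default and the
parameter is exposed). Weekly seasonal accumulation sums matrices
element-wise; the default restart schedule is 1 February plus 7-day
steps, 14 starts (ending 2/3 May depending on year).

## Genotype generator

Balding–Nichols: ancestral frequencies uniform on [0.05, 0.95];
subpopulation frequency Beta(p(1−F)/F, (1−p)(1−F)/F), i.e. mean p and
variance p(1−p)F, so `target_fst` is a closed-form divergence target and
Weir–Cockerham estimation on the output is parameter recovery (the
estimator recovers 0.10 to ±0.004 across replicates at 4×50 individuals,
552 loci). With an `admixture_Q` matrix, cluster frequencies are drawn
instead and each individual's allele probability is the Q-weighted
mixture. Genotypes are Binomial(2, p); missingness is completely at
random. Defaults mirror the emulated sampling design: 13 sites × 40
individuals, 552 loci, 5% missingness, 30% spat.

Deliberately absent: linkage disequilibrium and haplotype structure
(loci are independent), genotyping error, non-random missingness,
inter-species hybridisation (the real system includes
*M. galloprovincialis*/*M. trossulus* introgression; no attempt is made
to model it). Spat/adult labels are a sampling-design annotation, not a
separate generative model — successive generations drawn from the same
population distribution — unless `admixture_Q` distinguishes them.

## QC filters

Order is frozen and audited: call rate (keep ≥ 0.5, inclusive), then MAF
(keep strictly > 0.05), then HWE (1-df χ² against expected proportions at
the estimated allele frequency; keep P ≥ 10⁻⁸, inclusive; monomorphic
loci pass trivially). The audit log records the first failing rule per
dropped locus. Note the default HWE threshold is calibrated for panels of
hundreds of individuals; a 20-individual toy table cannot reach
P < 10⁻⁸, which is why the packaged worked examples raise the threshold
when demonstrating the HWE rule.

Imputation is frequency-based: each missing dosage is Binomial(2, p̂)
with p̂ the called-genotype frequency in the individual's population at
that locus (global-frequency fallback, logged, when a population has no
calls). A haplotype HMM would add nothing at a panel of unlinked SNPs.

## F_st and bootstrap

Weir & Cockerham (1984) components with unequal sample sizes; loci where
any population has no calls, or with zero denominator, are excluded and
logged. Multi-locus combination is ratio-of-sums (per-locus averaging is
biased at small locus counts). The bootstrap resamples loci with
replacement (default B = 1000), giving a one-sided
P = (#{θ̂* ≤ 0}+1)/(B+1) for differentiation > 0 — "significance" in the
pairwise-distance sense — plus a percentile 95% CI. Add-one smoothing
means a fixed-difference pair reports exactly 1/1001, never 0. The test
suite pins the vectorised components to an independent scalar
transcription of the 1984 formulas at 10⁻¹².

## Admixture and K

The likelihood is the binomial admixture model (no linkage, no
sequencing-error term). EM updates are the standard responsibilities for
alternate/reference allele copies; the implementation asserts monotone
log-likelihood every iteration and keeps the best of `n_restarts`
(default 5) seeded restarts. K = 1 is closed-form.

K selection substitutes masked-entry cross-validation for a variational
marginal likelihood: per fold, 5% of observed dosages are hidden, the
model is fitted on the rest, and hidden entries are scored; the K with
the best mean held-out log-likelihood wins. This is reproducible without
variational machinery and penalises overfitting directly. In simulation
it recovers K = 5 on five well-separated populations and K = 1 on
panmictic data in ≥ 80% of seeded trials (verified at 100 individuals ×
200 loci, 3 folds).

t-SNE is a thin wrapper over scikit-learn on centred dosages, for plots
only; no statistic consumes its output.

## Communities and agreement

Connectivity matrices become undirected graphs by summing the two
directed counts (walktrap is defined on undirected graphs; how
directionality should be collapsed is not canonical, and the sum is the
symmetric choice that preserves total flux). Self-loops are dropped;
isolated nodes stay as singleton communities.

Walktrap uses t = 4 random-walk steps (the common default of the
reference implementation), Ward-style merge costs on walk profiles with
degree-weighted distances, merges restricted to adjacent communities, and
a modularity-maximising dendrogram cut; ties break deterministically on
the smallest involved node ids. A fixed-K cut is available for comparison
with a known genetic K. The implementation reproduces python-igraph's
partitions exactly on planted-partition benchmarks in the test suite.

Genetic partitions are projected to sites by majority vote over
individual admixture-argmax labels (ties toward the smaller label);
agreement is adjusted Rand index (chance-corrected) and NMI (arithmetic
normalisation), with the full contingency table retained.

## Pipeline coupling and the two-bay scenario

In `run-all`, the dispersal stage runs first and its walktrap communities
define the ancestral clusters of the genotype generator (one cluster per
community, divergence `target_fst`). This realises the study logic —
dispersal structure should imprint genetic structure — as a directly
testable closed loop: in the packaged two-bay scenario the two stages
recover identical site partitions (ARI = 1). Real data break this loop in
exactly the ways the generator omits (migration-drift disequilibrium,
historical structure, hybridisation), so perfect agreement is a pipeline
property, not an empirical claim.

## Problem sizes and determinism

Every stochastic stage takes an explicit integer seed and is bit-for-bit
reproducible; run manifests record config, seeds and input checksums.
The packaged tests and the acceptance script use desk-scale sizes chosen
to exercise every code path while staying light: toy flows of ~50×60
cells over 2–5 days, 10²–10⁴ particles, genotype panels of 100–552 loci
and 60–200 individuals, 5-seed/20-seed replicate averages, and planted
graphs of 10–80 nodes. The full release protocol (20 particles/h × 24 h
× 14 d = 6720 per site, 440 sites ≈ 3 M particles) is exercised through
its scheduling arithmetic rather than materialised.

## Known limitations

* No mortality, maturation, growth or behaviour in the tracker — the
  settlement window stands in for larval competence.
* Hold-in-place land policy can artificially trap particles against a
  straight coast in strong onshore flow.
* The bootstrap tests loci, not individuals; small per-site sample sizes
  propagate into θ̂ variance that the locus bootstrap does not see.
* Masked-entry CV for K is consistent in simulation but, like every K
  criterion, heuristic on real admixed data.
* The synthetic coastline is rectangles; no attempt is made to represent
  real bathymetry or shorelines.
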