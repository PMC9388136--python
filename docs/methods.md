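# Methods

## The model

`mtnet` simulates quasi-two-dimensional networks of stabilized
microtubules organized by motile cross-linkers, the in-silico
counterpart of self-organization assays in thin flow chambers.  The
domain is a thin 3D box (default Z thickness 0.2 µm), periodic in X/Y
and bounded by reflecting mirrors in Z.  Filament vertices are stored
unwrapped; periodicity enters only through minimum-image displacements,
so trajectories are directly usable for displacement analysis.

### Microtubules

A microtubule is a polar, inextensible, bendable line discretized into
segments of rest length `l` (default 0.5 µm), vertex 0 being the minus
end.  Bending uses the linear worm-like-chain energy
`E = (kappa/2 l^3) sum |r_{i+1} - 2 r_i + r_{i-1}|^2` with flexural
rigidity `kappa` (default 20 pN µm²; literature microtubule scale).
Filaments nucleate from a fixed set of randomly placed point seeds
(one filament per seed, uniform in-plane orientation, z at the box
mid-plane) with first-order kinetics at rate 0.1 /s, so nearly all
filaments exist within the first minute.  The plus end grows at

    vg(t) = alpha (1 - sum_i L_i(t) / Omega),

a shared, finite tubulin pool Omega (µm of polymer) throttling growth
linearly; the per-filament maximum speed is drawn once as
`alpha = alpha0 |1 + 0.25 N(0,1)|`, hard-clipped to 0–2 µm/s, which
reproduces broad length distributions.  There is no catastrophe or
minus-end growth; growth stops for good when the configured growth
phase (default 600 s) elapses.  Omega is parameterized as (target mean
steady-state length, default 2.5 µm) x (filament count), which makes
the steady state explicit: as the pool exhausts, the mean length
approaches Omega/n regardless of the per-filament speeds.  Cross-linker
units bind to discrete 8-nm lattice sites along the filament; several
units may occupy one site (no exclusion rule is imposed).

### Cross-linkers

A cross-linker complex is two microtubule-binding units joined by a
Hookean spring, `f = k (1 - e/|u|) u`, with stiffness `k` (default
50 pN/µm) and rest length `e` (default 0.05 µm); the joints rotate
freely.  The two units may never occupy the same filament.  A unit is
either

* a **motor**: stochastic 8-nm steps toward its directional end as a
  Poisson process of rate `v/a`, with the linear force–velocity law
  `v = vm (1 + f·d/fs)` clipped to `[0, 2 vm]` (stall at `f·d = -fs`,
  assisting loads at most double the speed, no backward stepping); or
* a **diffusive** unit: force-biased hopping with rates
  `r± = (D/a²) exp(±f·a / 2 kBT)`, the symmetric splitting of the
  detailed-balance condition `r+/r- = exp(f a / kBT)` (alternative
  splittings differ only at second order in `f a / kBT`).

Unbinding is force dependent via the Bell law `k_off0 exp(|f|/f_unb)`;
binding occurs at rate `k_on` to a uniformly chosen lattice site within
the capture radius.  At a filament end a unit either *holds* (stepping
past the end suppressed, off-end hops rejected) or *releases*
instantly; release motors detach at the end they walk toward.

The catalog (`mtnet.crosslinkers.linker_catalog`):

| name | unit A | unit B | ends |
|---|---|---|---|
| `kif11` | plus motor, processive | idem | release |
| `hset` | minus motor, nonprocessive | diffusive tail | hold |
| `hset_plus` | plus motor | diffusive tail | hold |
| `hset_stiff_tail` | minus motor | non-hopping unit (D=0), same dwell | hold |
| `double_motor_hset` | minus motor | minus motor | hold |
| `double_tail_hset` | diffusive tail | diffusive tail | hold |
| `double_tail_end_release` | diffusive tail | diffusive tail | release |
| `symmetric_minus` | mildly processive minus motor | idem | hold |

Kinetic defaults are **reconstructions**: only a few constants are
pinned by published statements (kinesin-14 motor speed ~80 nm/s; two
steps per engagement on average; tail dwell 500x the motor unit's;
kinesin-5 sliding ~30 nm/s per motor pair).  From these: HSET motor
step rate `vm/a = 10 /s` and `k_off0 = 5 /s` (mean two steps, dwell
0.2 s); tail `k_off0 = 0.01 /s` (dwell 100 s = 500x).  Everything else
(`k_on = 10 /s`, capture radius 0.06 µm, `f_unb`, `fs = 5 pN`, tail
`D = 0.02 µm²/s`, spring constants) is set at literature scale and
exposed in the scenario configuration; "mildly processive" symmetric
minus motors take ten steps per engagement on average.

### Dynamics

Each vertex of drag `gamma` obeys first-order (overdamped) Langevin
dynamics,

    dx = F dt / gamma + sqrt(2 kBT dt / gamma) xi,

with `dt = 0.005 s`, `kBT = 4.23e-3 pN µm` (306 K) and isotropic
slender-body drag `gamma = 3 pi eta l / ln(l/2r)`, microtubule radius
`r = 12.5 nm`.  The default viscosity `eta = 0.5 pN s/µm²` represents
a crowded assay buffer and keeps the explicit part of the update stable
(see below).

Numerical scheme, in fixed order per step (fixed ordering guarantees
seed reproducibility):

1. deterministic forces on pre-update geometry; per-linker spring
   loads are stored and drive this step's kinetic rates;
2. vertex update.  Bending and cross-link springs are integrated
   **implicitly** (backward Euler): with the default parameters the
   stiffest bending mode has `k dt/gamma ≈ 16`, and tens of
   cross-linkers stacked between one filament pair are routine in
   bundles, both far beyond the explicit stability bound
   `k dt/gamma < 2`.  Spring forces are linearized about the
   step-start extension direction and periodic image, so all three
   coordinates satisfy independent linear systems with one shared
   symmetric positive-definite matrix, solved by conjugate gradients
   preconditioned with the per-filament inverse bending operator
   (tolerance: initial-residual-relative 1e-5, i.e. relative to this
   step's displacement, not to the absolute coordinates).  Steric
   forces, one-sided and self-limiting, remain explicit, and thermal
   noise enters the right-hand side.  The implicit scheme slightly
   damps fluctuations of modes with `k dt/gamma` of order one; the
   statistical-physics tests therefore run at reduced `dt`, and a
   dt-halving consistency check bounds the discretization error of
   observables at the production step.
3. segment-length constraints: Newton iteration on the Lagrange
   multipliers of the per-segment length constraints; each pass solves
   the tridiagonal Gram system of constraint gradients exactly and
   applies the minimal-norm correction (converges to a relative
   tolerance of 1e-6 in a few passes, where plain pairwise-projection
   sweeps stall on long filaments);
4. mirror reflection of vertex Z coordinates;
5. linker kinetics (unbind, move, bind), with binding prefiltered by
   the rate (the probability `1 - exp(-k_on dt)` does not depend on
   the number of available sites, so the site search runs only for
   units that will bind) and candidate sites enumerated per segment
   within the capture radius;
6. nucleation and pool-limited growth; the terminal segment splits
   when it exceeds 1.5x the rest length.

Steric interactions between segments of distinct filaments apply a
Hookean soft-core force of magnitude `k_steric (d_steric - r)` along
the closest-approach direction orthogonalized against *both* filament
axes — repulsion produces minimal axial sliding force, and the pair
forces stay exactly equal and opposite (so the deterministic force sum
vanishes to machine precision).  This projection makes the steric
force deliberately non-conservative; energy-gradient identities are
therefore checked on configurations without steric contacts.
Neighbor search uses X/Y cell grids rebuilt every step: a coarse grid
for segment pairs and a finer one for binding queries.

All randomness in the kernel derives from one seed; two runs with the
same configuration and seed are bitwise identical.

## Quantification

* **Signed microtubule speed**: for disjoint windows of length
  `delta_t`, the unwrapped minus-end displacement of each filament is
  projected on its axis at the window start, oriented plus-to-minus;
  positive = minus-end-leading sliding (plus-motor driven).  The
  window is long (640 s at full scale, scaled with the box) so
  diffusion is negligible against directed transport; for undriven
  filaments the measure decays toward zero as `delta_t` grows.  Two
  properties matter when interpreting small systems: the per-window
  noise scales like `sqrt(2 D_eff delta_t)/(delta_t sqrt(N))`, and
  tracking the minus end (not the centroid) with the start-of-window
  axis adds a small systematic *negative* bias,
  `-(L/2)(1 - E[cos theta(delta_t)])/delta_t`, from rotational
  decorrelation of the axis (about -0.002 µm/s for motor-free
  2.5-µm filaments at `delta_t = 80 s`).  An optional
  `min_cluster_size` argument restricts the average to filaments in
  cross-linked components of at least that size — the sliding speed
  of the bundled population.
* **Bundle/aster size**: filaments are graph nodes, every doubly-bound
  cross-linker of a type contributes an edge; the largest connected
  component over the filament count is the bundle size (KIF11) or
  aster size (HSET).

## Scenario presets and problem sizes

Presets reproduce the published compositions exactly at `scale = 1`
(e.g. 60x60x0.2 µm, 0.8 MT/µm² = 2,880 filaments, 16 KIF11 per MT =
46,080 motors).  `scale` shrinks the linear box dimensions at fixed
density and scales durations and analysis windows proportionally.
Full-scale runs are cluster-sized; the test suite exercises the
emergent regimes at `scale = 0.15` (29–65 filaments), 240–320 s runs,
80-s analysis windows and five seeds per condition.  Because bundles
continuously break and reform, cluster order parameters are
time-averaged over the second half of each run.  This size separates
the qualitative regimes cleanly — minus-end asters versus extensile
bundling versus the inert motor-free control, HSET-cluster dominance
and sliding suppression at high HSET excess — but it cannot reproduce
full-scale *speed-curve shapes*: the dense KIF11 network slides while
bundling and then polarity-sorts into static parallel bundles, so its
mean speed peaks early and decays instead of rising as at full scale,
where sorted bundles keep encountering antiparallel partners.  The
two speed comparisons that hinge on that late-time behavior are
expected to fail at this problem size and are kept in the suite as an
explicit record of the model's finite-size limit.

## What the synthetic scenarios do and do not capture

The generator emulates the full-scale study conditions: thin-box
geometry, fixed nucleator count, pool-limited growth with speed
heterogeneity, and the printed linker-per-filament ratios.  It does
not model dynamic instability, hydrodynamic coupling, motor
oligomerization, or lattice-site exclusion; passing tests demonstrate
the stated mechanics and kinetics of the model, not quantitative
agreement with any in-vitro measurement beyond the printed constants.

## Known limitations

* Kinetic constants absent from the main text are reconstructions;
  network-level observables (absolute sliding speeds, cluster growth
  rates) depend on them quantitatively.
* Reduced-scale boxes hold only tens of filament lengths; cluster
  fractions are correspondingly noisy and finite-size limited.
* The first-order integrator under-resolves bending fluctuations at
  the production `dt` (by design, matching the time step of the
  reference simulations); equilibrium statistics are validated at
  reduced `dt`.
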