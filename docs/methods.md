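# Methods

This note documents the model, the numerical choices, and the known
limits of `veinmorph`, at the level of detail a user needs to judge
what a simulation or a descriptor value means.

## Mechanical model

The vein network is a planar graph on a torus (periodic rectangle
W x H); digitized leaves are the open-domain variant.  Each edge is a
straight viscoelastic rod: a spring of Young modulus `mu` and
thickness `h` in series with a dashpot of viscosity `nu`.  The elastic
state is fully described by node positions, the box, and the rod rest
lengths `l0`; the tension is `T = mu h (l/l0 - 1)`.  Rods are linear
springs in both directions, so a compressed rod pushes — the model has
no buckling and no excluded volume (see Limitations).  Ground tissue
is ignored entirely: veins are assumed to carry all load.

The energy is

    E = sum_i 1/2 mu h_i l0_i (l_i/l0_i - 1)^2
        - P_tur W H
        - H0 (W - W0) sigma_xx - W0 (H - H0) sigma_yy

* The spring prefactor uses `l0`, so dE/dl reproduces the tension
  exactly; the alternative prefactor `l` differs only at cubic order
  in strain (strains here are ~0.02).
* Turgor acts through the box area: with a periodic tiling, network
  area and box area coincide, and interior nodes feel the pressure
  through the rods.
* The anisotropic term applies an external stress relative to the
  reference box (W0, H0), defined as the equilibrium with
  `sigma = 0`; it is linear, i.e. a true constant-stress (dead-load)
  term, not a constraint on the box shape.

### Equilibration

Quasi-static growth requires a tight force balance after every
increment.  Energy is minimized jointly over all node coordinates and
(W, H); internally the nodes are parametrized as box fractions, so a
change of box rescales the network affinely before the nodes relax.
The solver is damped Newton with the exact sparse Hessian of the rod
energy (longitudinal stiffness `mu h / l0`, transverse stiffness
`T / l`, plus the box-coupling terms), with a tiny diagonal shift to
absorb the two rigid translation modes, backtracking line search, and
L-BFGS-B as a fallback for starts far from equilibrium.  Convergence
is declared when every force component (dE/dx in model units, and
dE/dW, dE/dH) is below `tol` (default 1e-8); non-convergence raises
with the residual.  Warm-started equilibrations during growth
typically need 2–5 Newton steps.

### Growth

Rest lengths evolve by an explicit Euler step of the chosen law,
written for the relative rate `(1/l0) dl0/dt` with `s = T/h` and
yield stress `eta = eta* . eta0`:

| kind       | rate                    | shape                      |
|------------|-------------------------|----------------------------|
| linear     | `s / nu`                | proportional               |
| threshold  | `max(0, s - eta) / nu`  | Lockhart-like yield        |
| quadratic  | `s^2 / (eta nu)`        | convex                     |
| maximum    | `s e^{1 - s/eta} / nu`  | peaked at `s = eta`        |
| saturation | `s / ((1 + s/eta) nu)`  | concave, saturating        |

The threshold law is the model's centerpiece: below yield a rod does
not grow at all, so a state with all tensions under threshold is an
exact (bitwise) fixed point, and a run whose area stops increasing is
aborted with a stall diagnostic.  The quadratic/maximum/saturation
forms are interpretive surrogates: only their qualitative shapes are
specified by the alternative-law comparison they serve, and these are
the simplest forms with the named features.

`eta0` — the reference stress that normalizes the threshold — is
measured at run time as the mean `T/h` of the unstressed turgor
equilibrium (recorded by `compute_reference_dims`, i.e. after
thickness noise, before external loading).  One `eta0` is shared
across a stress sweep so that `eta*` means the same physical threshold
in every condition.

The default growth step is `dt = 1e-5` in model time.  The package's
own simulated experiments use `dt = 5e-4` (~100 steps to area
doubling); at mean rates of order `eta0` this gives per-step
rest-length increments of ~0.3% and trajectory-level Euler errors far
below the seed-to-seed spread of every statistic asserted about those
runs.  Contract tests (stop rule, Euler increment, Richardson
halving) use their own documented steps.

Negative tensions are passed to the growth laws unclipped; the
threshold law ignores them by construction, while under the linear law
a compressed rod shrinks its rest length.  Simulations here operate in
a regime where rods are almost all in tension.

## Synthetic networks

Real creation-stage dynamics (auxin canalization, cell-scale
mechanics) are out of scope; the generator is a geometric surrogate
that reproduces the features the downstream statistics depend on:

1. a scaffold of one horizontal loop (the primary vein, always the
   thickest, spanning the box along x) and one vertical loop;
2. sequential insertion: the largest areole is split by a chord
   between two random points on its boundary; among up to 24 valid
   candidates the chord with the best child quality (isoperimetric
   ratio `4 pi A / P^2`, required >= 0.22) is kept.  Greedy
   largest-face splitting keeps the areole size distribution tight
   (area cv ~0.65) and the quality floor prevents sliver areoles,
   which otherwise collapse and entangle the embedding under strong
   external stress;
3. thickness by creation order, `h = rank^(-beta)` (default
   `beta = 0.25`), normalized to unit mean — the creation hierarchy;
4. thickness-weighted Laplacian smoothing of node positions
   (Lloyd-style, default 25 sweeps at step 0.3), rejecting any sweep
   that would invert a face; primary-vein nodes keep their y so the
   dominant vein stays straight.

Rest lengths are set to the as-built lengths, so the network is
unstressed until equilibrated.  A `mode="grid"` escape hatch produces
plain square lattices for analytic tests.

### Calibration

The standard parameter set is "everything 1 except `mu = 300`".  The
remaining free scale is the areole linear dimension `a` of the
creation stage.  At equilibrium the virial of the energy fixes the
mean vein stress to `eta0 ~ 2 P W H / sum(h l)`, i.e. stress grows
linearly with areole size; the frozen default `a = 5.3` model units
makes the emergent reference stress `eta0 = 6.0 +- 0.03` across seeds
and hence typical strains `eta0/mu ~ 0.02`.  This single constant was
fixed once, from the virial relation, and is never re-fit.

### Thickness optimization

The "ideal" initial condition has tension proportional to thickness
(the force model of vein networks).  The update `h <- T`, renormalized
to preserve mean thickness, is alternated with re-equilibration.  The
bare alternation is unstable: tension condenses onto a stiff backbone
while rods left slack by their frozen rest lengths pin the residual
scatter.  Physically, the rods are viscoelastic during the creation
stage — their rest lengths track the slowly changing geometry — so
each iteration also relaxes rest lengths to the current lengths at the
current mean strain.  With that damping the iteration converges in a
handful of sweeps to cv(T/h) below the 0.05 default tolerance
(`corr(T, h) > 0.999`).  The `h` update is floored at `0.02 mean(T)`
so near-slack rods keep enough transverse stiffness for the embedding
to survive later loading.

### Thickness noise

`apply_thickness_noise(net, r, seed)` multiplies every thickness by an
independent draw from `U[1-r, 1+r]` — `r` is the half-width of the
multiplier, and `r = 0.4` is the default study condition.  The noise
is frozen: applied once to the initial state, never during growth.

## Texture quantification

Areoles are the faces of the embedded graph, enumerated by half-edge
traversal; on the torus the face areas tile the box exactly
(`V - E + F = 0` is checked), on open domains the outer face is
discarded and areoles touching it are flagged (their tensor is
undefined).  Face identity is stable over time because growth freezes
the topology.

* Areole center = polygon centroid (area-weighted).
* The local tensor averages outer products of centroid-to-neighbor
  vectors (minimum-image on the torus); neighbors are areoles sharing
  at least one rod, each counted once.
* Anisotropy is the ratio of eigenvalues of M (not of ellipse axes,
  which would be its square root).  Rank-one tensors report infinite
  anisotropy and are excluded from summaries, never clipped.
  Orientations of near-isotropic tensors are flagged unreliable.
* Gaussian averaging uses `pi sigma^2 = 30 x mean areole area`,
  includes the areole's own tensor, and is recomputed per time point —
  which is what makes `q = 1` an exact identity under dilation.
* The whole-network tensor (used for the anisotropy-vs-stress curves)
  is the unweighted mean of the local tensors, i.e. the
  `sigma -> infinity` limit of the averaged field.  The alternative
  reading (mean of per-areole anisotropies) is available from the
  descriptor table.
* The areal non-affinity variant smooths the relative areal growth
  rates `a_i = ln[S_i(t2)/S_i(t1)]/(t2-t1)` with the same kernel on
  the t1 geometry.
* The dual graph (junctions as nodes) is intentionally not the
  default; it is noisier and nothing downstream needs it.
* Orientation histograms use 18 bins of 10 degrees, unweighted by
  default (length-weighting available).

## What the synthetic experiments do and do not show

The simulated experiment replicas (test suite and experiment runner)
use 64-areole networks, ~10 seeds per condition and `dt = 5e-4` —
deliberately small.  They reproduce, with comfortable margins, the
qualitative phenomenology: anisotropy of the texture field grows with
external stress and aligns with it (with the initial dip when pulling
along the dominant vein, which must first be overcome); thickness
noise makes growth non-affine; external stress broadens the
non-affinity distribution under the linear, quadratic, maximum and
saturation laws but narrows it under the threshold law; heterogeneity
decreases with surrounding vein thickness; growth stalls when the
normalized threshold exceeds ~1.3.

They do not show: quantitative agreement with any real leaf (the
generator is a statistical surrogate, not a fitted creation model);
behavior at strains far beyond ~10%, where the linear rod law and the
no-contact assumption both fail; or anything about the biology the
model abstracts away (auxin transport, differentiation, ground-tissue
mechanics, left/right leaf asymmetry).

## Numerical edge cases

* About 5% of 100-areole realizations entangle (a face collapses
  through a rod) when loaded suddenly at `sigma = 2 P_tur`; this is a
  genuine fold of the energy landscape, not a solver artifact (stress
  ramping does not avoid it).  Such runs raise, are recorded as failed
  in the experiment manifest, and are excluded from pooled statistics.
* Equilibration tolerance 1e-8 (forces); face-tiling checks at 1e-6
  relative; the dilation identity holds to 1e-12 in practice.
* All randomness flows from explicit integer seeds (generation, noise,
  experiment grid); reruns are bit-identical including the descriptor
  CSVs.  Snapshot JSON stores full-precision floats and round-trips
  exactly.
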