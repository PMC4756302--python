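# Methods

## Model

`graphsh` implements a single-species excitation model on a simple,
connected, undirected graph.  Each node carries an activation potential
u_i driven by a local double-well force and by interaction currents
exchanged with its first- and second-order neighbourhood:

    du_i/dt = f(u_i, mu) + I_i,
    f(u, mu) = -(1 + mu) u + b u^2 - u^3,
    I = -(2 L2 + L4) u,

where L2 = A − diag(k) is the graph Laplacian and L4 = L2·L2 the
bi-Laplacian.  Collecting terms, the system is the network analogue of
the quadratic–cubic Swift–Hohenberg equation

    du/dt = -mu u - (Id + L2)^2 u + b u^2 - u^3,

with the Laplacian standing in for the continuum ∇².  The Laplacian
coupling is diffusive; the bi-Laplacian induces short-range
anti-correlation with nearest neighbours and longer-range correlation
with the two-jump neighbourhood — the activator–inhibitor structure that
makes stationary patterns possible.  Both operators are symmetric with
zero row sums, so the currents conserve total potential; all dynamical
statements reduce to normal modes along the shared Laplacian eigenbasis.

The explicit form of the on-node force is a reconstruction: it is the
minimal quadratic–cubic double-well force consistent with (a) the model
being exactly the Swift–Hohenberg analogue above and (b) the full set of
flat-state bifurcation values that the stability analysis must reproduce
(below).  The quadratic coefficient b is configurable; b = 3/2 is the
validated default and is assumed everywhere unless stated.

## Flat states and linear stability

Uniform states solve f(u, mu) = 0: u0 = 0 always, and
u± = [b ± sqrt(b² − 4(1+mu))]/2 below the saddle-node mu1 = b²/4 − 1.
Linearizing about a flat state and expanding over the Laplacian
eigenbasis gives one growth rate per mode,

    lambda(Lambda) = f'(u, mu) - 2 Lambda - Lambda²,

maximized, over continuous Lambda ≤ 0, at Lambda = −1 where
lambda = f'(u) + 1.  In this dense-spectrum idealization the bifurcation
set for b = 3/2 is

    mu0 = 0        trivial state destabilizes (Turing onset),
    mu1 = −0.4375  flat saddle-node,
    mu+ ≈ −0.6185  upper flat branch changes stability,
    mu− ≈ −1.8190  lower flat branch changes stability,

which round to 0, −0.44, −0.62 and −1.82 at two decimals.
Note the orientation at mu+: the upper branch u+ is *stable below* mu+
and unstable between mu+ and mu1 (f'(u+) + 1 = b u − 2u² + 1 is +0.5 at
mu = −0.5 and −1.25 at mu = −1).  On a finite graph the realized
thresholds use the actual discrete spectrum (`max_growth_rate`), which
can miss Lambda = −1; the dense-spectrum values are exposed separately
(`flat_bifurcation_points`) because they are the network-size-converged
quantities.

The "topological eigenvalues" are the four roots s of (1 + s²)² = −mu,
the network counterpart of the spatial eigenvalues of a homoclinic
linearization about rest.  Their collision sequence — complex quartet
for mu > 0, pairwise collision at ±i at mu = 0 (reversible 1:1
resonance), four imaginary roots for −1 < mu < 0, collision at the
origin at mu = −1, a real pair below — delimits where localized
(homoclinic) states can exist: small positive mu.

## Time integration and steady states

The bi-Laplacian makes the system stiff (explicit stepping would need
dt ~ 1/Lambda_max²), so `integrate` uses first-order IMEX splitting: the
linear coupling −(2L2+L4) is treated implicitly, the local force
explicitly.  The matrix I − dt·C is LU-factorized once per (graph, dt);
dt defaults to 0.05.  A run terminates when ‖du/dt‖∞ < 1e−8 (or the
experiment-level 1e−6, where the endpoint is anyway polished) and the
endpoint is refined by a Newton iteration on the full nonlinear system
(Jacobian diag(f'(u)) + C), so reported equilibria have residuals below
1e−10 regardless of the integrator tolerance.  A trajectory exceeding
‖u‖∞ = 1e6 raises a blow-up error carrying the last finite state.

Stationary patterns are tagged stable/unstable by the most-positive
eigenvalue of the (symmetric) Jacobian — dense solves up to N = 1500,
iterative largest-algebraic solves above.

**Stabilization of symmetric equilibria.**  A noiseless step stimulus is
constant on its support, so when the stimulated neighbourhood has
non-trivial graph automorphisms the trajectory is confined to the
symmetric invariant manifold and can converge to a saddle that attracts
within that manifold but is unstable to symmetry-breaking perturbations
(on the BA N=200 tree fixture the saddle has a four-fold degenerate
unstable eigenvalue from interchangeable branches).  `relax_to_stable`
therefore checks the leading Jacobian eigenvalue after relaxation and,
if positive, nudges the state by 1e−3 along the unstable eigenvector
(sign fixed deterministically) and re-relaxes, so the robustness
protocols always measure attractors.  The kick size only needs to break
the symmetry; results are insensitive to it across several orders of
magnitude.

## Stimuli

The step stimulus sets amplitude ũ on the one- and two-jump
neighbourhood of a centre node (the best-connected node by default, ties
broken by lowest id).  The centre itself is included by default; the
support convention is configurable because the verbal description
("nearest and next-nearest neighbours") leaves the centre ambiguous.
Noise is per-node uniform on [−a, a], restricted to the support and
seeded; no distribution is prescribed by the source material, and the
uniform choice keeps the perturbation bounded relative to the step.

## Pseudo-arclength continuation and snaking

`continue_branch` traces stationary states in (u, mu) with a
secant predictor (first step: tangent from the bordered Jacobian null
space, direction selectable) and a Newton corrector on the bordered
system [F(u, mu) = 0; t·Δx = ds].  The arclength metric weights u and mu
equally.  The step halves on corrector failure, doubles after fast
convergence (≤3 iterations), and is clamped to [ds/256, 4·ds]; a
corrector solution landing farther than 2·ds from the previous point is
rejected as a branch jump.  Repeated failure at the minimum step
truncates the branch with a flag.  Folds are sign changes of consecutive
Δmu; every accepted point satisfies the bordered system to 1e−8 and is
stability-tagged.

Branches are seeded from the equilibrium of a step stimulus at the
target mu (the construction used for the robustness experiments), with
ds = 0.5/√N on networks and 0.05 on the scalar test problem.  On the
BA(200, m=1) study network the branch snakes: activation energy
E = Σ u_i² (the standard snaking-diagram measure, exposed as a pluggable
functional) climbs as folds alternate between mu ≈ 0.30 and mu ≈ −0.08
(seed mu = 0.15), each pair of folds recruiting a new neighbourhood into
the activated cluster, and the stable segments crossing a fixed mu carry
well-separated, quantized energies.

Two network-specific departures from textbook (continuum) snaking are
worth recording.  First, the branch extends below mu = 0, where the
resting background is itself Turing-unstable; segments there are
uniformly unstable no matter what the snaking mode does, so the coarse
stable/unstable flag does not alternate across folds that dip below
zero.  The invariant that survives on the network is that the count of
unstable Jacobian modes changes by exactly one across every fold — the
saddle-node exchange — which the tests verify for folds whose
neighbourhood stays inside mu > 0 (elsewhere the background modes cross
simultaneously and the count jumps by many).  Second, the branch can
close into finite loops (isolas) which the continuation then retraces
periodically; traces are therefore bounded by a step budget and a mu
window rather than run to exhaustion.

## Robustness experiments

`amplitude_sweep` stimulates, relaxes to a stable equilibrium, and
records the final energy over an increasing amplitude grid.  Rows are
classified: *relaxed* (energy < 1e−6), *robust* (on the terminal energy
plateau — the plateau containing the largest amplitude, with at least
two members — where further amplitude increments leave the final pattern
unchanged), *fragile* otherwise (a quantized state formed, but not yet
the amplitude-insensitive one).  Plateau segmentation uses a 1e−3
relative tolerance.  `threshold_estimate` brackets the relaxed→robust
transition from the sweep and refines it by bisection (rerunning the
full protocol at each midpoint) to an eighth of the grid step.

`noise_monte_carlo` fixes a base amplitude in the robust regime and, per
noise-to-signal ratio, runs seeded realizations (default 100; child
seeds spawned from the master seed via `numpy` seed sequences and
recorded).  It reports mean and standard deviation of the final energy
and the fraction matching the noise-free quantized state within 1e−3
relative.  The table carries both the noise-to-signal ratio and its
reciprocal, since both conventions are in circulation.  Default study
conditions: BA(200, m=1), mu = 0.3, base amplitude 2.0 — a parameter
point deep enough in the localized regime that the quantized state is
insensitive to 5% noise, with breakdown setting in near ratio 0.2 and
the departure growing monotonically beyond.

## Degree-based mean-field approximation

For mu < 0 the resting state is unstable and global Turing patterns
form.  Nodes are classified by (alpha, beta) = (k, k2) — degree and
two-jump degree — with the two-walk count s = Σ_j A_ij k_j carried
alongside (k2 counts *distinct* distance-2 nodes; s counts two-step
walks with multiplicity; they differ off trees).  The neighbour fields
are closed on two global mean fields, H_u (degree-weighted mean of u)
and H_uu (two-jump-degree-weighted; a k²-weighted alternative sits
behind a flag), via Σ_j A_ij u_j ≈ k_i H_u, (A²u)_i ≈ k_i u_i + k2_i
H_uu, Σ_j A_ij k_j u_j ≈ s_i H_uu.  Propagating through the coupling
gives one cubic per node class,

    g(u) = f(u, mu) + (alpha − alpha²) u + (alpha² − 2 alpha) H_u
           + (s − beta) H_uu,

whose roots are stable iff g'(u) = f'(u) + alpha − alpha² < 0.  With the
tree-consistent substitution s = alpha + beta, every flat state of the
full model is an exact fixed point of the reduced equation.  The overlay
(`mfa_overlay`) measures H_u, H_uu from a simulated stationary pattern
(no self-consistent iteration), solves the cubic per node, and reports
each node's distance to its nearest stable root, sorted by (k, k2).

**Known limitation.**  On the study networks at mu = −1/4 the simulated
patterns are domain-type: the unstable band Lambda ∈ (−1.5, −0.5) sits
at the smooth upper edge of the Laplacian spectrum, so neighbours are
strongly correlated (the measured neighbour field tracks k_i·u_i, not
the closure's k_i·H_u) and nodes of the same class land on different
domains.  The closure's single stable branch tracks the central cluster
of the pattern — about 63% of ER(1000, ⟨k⟩=6) nodes fall within 15% of
the pattern range of a stable root, and the fraction cannot reach the
upper and lower domains: any closure of the form f(u) + linear(u) +
constant leaves the cubic's root sum fixed at b (Vieta), while the
empirical per-class branch positions sum to well below b.  The
qualitative topology contrast survives intact: the degree-ordered
stable-branch profile on the ER network has markedly smaller normalized
total variation than on a BA network of equal size and mean degree
(narrower degree distribution ⇒ smoother pattern), which the acceptance
suite asserts.  The corresponding quantitative fit threshold is asserted
as specified and currently fails; the tests keep it visible rather than
relaxing it.

## Synthetic networks

All experiments run on synthetic graphs.  The Barabási–Albert generator
is implemented in-package with a documented seed convention — a single
edge for m = 1, a clique on m+1 nodes for m > 1, then preferential
attachment with m draws without replacement per new node — so that a
given (n, m, seed) always yields the same edge set.  BA(m=1) grows
trees, matching the minimum-degree-1 study network.  Erdős–Rényi graphs
are drawn as G(n, p) with p = ⟨k⟩/(n−1); disconnected draws keep the
giant component (relabelled, logged) because the dynamics assume a
single connected system.  Mean degrees are configuration, not ground
truth: defaults are m = 1 for the snaking/robustness network and ⟨k⟩ = 6
for the ER/BA pair in the mean-field study.  What these graphs do not
emulate: degree correlations, clustering, communities, or weighted and
directed edges — conclusions from the tests transfer to real networks
only insofar as those features are irrelevant.

## Problem sizes and numerical defaults

The test and acceptance workloads use N = 200 for snaking and
robustness (150-step branches, 30-point amplitude grids, 100 Monte-Carlo
realizations) and N = 1000 for the mean-field overlay; dense eigensolves
are used throughout these sizes, with sparse LU factorizations for all
linear solves.  Key tolerances: steady-state residual 1e−10 (Newton),
integrator settling 1e−8 (1e−6 in sweep protocols, where Newton
polishing follows), corrector acceptance 1e−8, stability tolerance
1e−8, plateau segmentation 1e−3 relative, energy match 1e−3 relative.
Ties in best-connected-node selection break to the lowest node id;
degenerate double roots (e.g. u = 0 at mu = −1) converge linearly in
Newton but still meet the residual contract.
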