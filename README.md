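# graphsh

Swift–Hohenberg pattern formation on complex networks: localized
quantized activation states, homoclinic-snaking continuation, stimulus
robustness protocols, and a degree-based mean-field theory of global
Turing patterns.

## The problem

How do small, robust assemblies of co-active units — cell assemblies, in
the neural reading — emerge in a network without any synaptic
reinforcement?  One minimal answer is self-organization: give every node
a double-well excitation potential and couple nodes so that nearest
neighbours anti-correlate while second neighbours correlate.  `graphsh`
implements exactly that model, the network analogue of the
Swift–Hohenberg equation,

    du_i/dt = f(u_i, mu) + I_i,
    f(u, mu) = -(1 + mu) u + (3/2) u^2 - u^3,
    I = -(2 L2 + L4) u            (L2 = A - diag(k),  L4 = L2·L2),

equivalently du/dt = -mu·u - (Id + L2)²u + (3/2)u² - u³, where A is the
adjacency matrix of a simple connected graph, L2 its Laplacian and L4
the bi-Laplacian.  The bifurcation parameter mu organizes three regimes:
for mu > 0 the resting state u = 0 is linearly stable but a sufficiently
strong local stimulus locks the network into a *localized quantized
state* — a small activated cluster whose energy E = Σ u_i² sits on a
discrete plateau, insensitive to the stimulus amplitude and to small
noise; for mu < 0 the resting state is Turing-unstable and *global*
stationary patterns form, which a per-node cubic mean-field theory in
the degree k and two-jump degree k² describes.

The package is aimed at researchers in network dynamics and
computational neuroscience who want a working, tested implementation of
the full analysis pipeline: generators and I/O for the study networks,
the coupling operators and their spectra, flat-state stability and the
dispersion relation, topological eigenvalues, stiff (IMEX) time
integration and Newton steady-state solving, pseudo-arclength
continuation with fold detection and stability tagging, amplitude/noise
robustness sweeps, and the mean-field overlay.

## Worked example

```python
import numpy as np
import graphsh as g
from graphsh.dynamics import relax_to_stable
from graphsh.continuation import stable_plateau_energies

# flat-state bifurcation set for the default nonlinearity (b = 3/2)
bp = g.flat_bifurcation_points(1.5)
print(f"mu0={bp.mu0:+.4f}  mu1={bp.mu1:+.4f}  "
      f"mu+={bp.mu_plus:+.4f}  mu-={bp.mu_minus:+.4f}")

# stimulate the hub neighbourhood of a scale-free network at mu = 0.15
net = g.generate_ba(200, 1, seed=7)
params = g.ModelParams(mu=0.15)
u0 = g.make_stimulus(net, "best-connected", g.Stimulus(amplitude=1.0))
pattern, lead = relax_to_stable(net, u0, params, settle_tol=1e-6)
print(f"localized state: energy={pattern.energy:.3f}  "
      f"active nodes={np.sum(np.abs(pattern.u) > 0.1)}  leading eig={lead:.3f}")

# continue it in mu: the branch snakes through folds, and the stable
# segments crossing mu = 0.15 carry discrete ("quantized") energies
branch = g.continue_branch(net, pattern, params, ds=0.5/np.sqrt(200),
                           n_steps=100, direction=+1, mu_range=(-0.5, 0.6))
print(f"branch: {len(branch)} points, {len(g.detect_folds(branch))} folds, "
      f"energy {branch.energies.min():.2f}..{branch.energies.max():.2f}")
print("stable plateau energies at mu=0.15:",
      np.round(stable_plateau_energies(branch, 0.15, 0.05), 2))
```

prints

```
mu0=+0.0000  mu1=-0.4375  mu+=-0.6185  mu-=-1.8190
localized state: energy=5.543  active nodes=12  leading eig=-0.143
branch: 101 points, 8 folds, energy 1.85..5.54
stable plateau energies at mu=0.15: [3.58 3.86 5.54]
```

Reading the output: the four bifurcation values are the trivial-state
threshold, the flat saddle-node, and the stability changes of the two
nonzero flat branches (they print as 0, −0.44, −0.62, −1.82 at two
decimals).  The stimulus recruits a 12-node cluster around the hub into
a stable equilibrium (negative leading Jacobian eigenvalue) with energy
5.54; continuation winds that state through 8 saddle-node folds while
the activated cluster grows and shrinks, and at the seed parameter three
distinct stable energy levels coexist — the quantized states.

## Command line

A thin CLI wraps the same pipeline; every run writes its artifacts plus
a `manifest.json` sufficient to regenerate them:

```sh
graphsh snaking         --network ba:n=200,m=1,seed=7 --mu 0.15 --out-dir out/
graphsh sweep-amplitude --network ba:n=200,m=1,seed=7 --mu 0.3  --out-dir out/
graphsh sweep-noise     --network ba:n=200,m=1,seed=7 --mu 0.3  --out-dir out/
graphsh stability-scan  --network er:n=1000,k=6,seed=3          --out-dir out/
graphsh mfa-overlay     --network er:n=1000,k=6,seed=3 --mu -0.25 --out-dir out/
```

Configuration can also come from a flat key-value file
(`--config run.cfg`, keys like `model.mu = 0.15`); flags override the
file.  Exit codes: 0 success, 2 invalid configuration, 3 numerical
failure.

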