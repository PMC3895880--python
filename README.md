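# eigenlocal

Tools for predicting **when and where the eigenvectors of a locally
connected linear network localize** — and hence how a network with purely
local wiring can exhibit different dynamical timescales in different
places.

In a linear rate network `dφ/dt = W φ + I(t)`, each eigenvalue λ of the
coupling matrix W contributes a timescale τ = 1/Re(−λ), present at every
node where the corresponding eigenvector v_λ is appreciable.  If the
connectivity profile is the same around every node (a ring with
`W(j,k) = e^{−|j−k|/l_c}`, say), the eigenvectors are Fourier waves
`v_λ(j) = e^{iωj}` — maximally delocalized — and all nodes share all
timescales no matter how short-range the coupling is.  Heterogeneity
changes this.  Writing the coupling in a relative coordinate,
`c(j, p) = W(j, j−p)`, and expanding around a putative center j₀, a
localized candidate eigenvector is a modulated Gaussian

    v_λ(j) = exp( −(j−j₀)² / 2α²(j₀,ω) + iωj ),

with eigenvalue `λ(j₀,ω) = Σ_p c(j₀,p) e^{−iωp}` and squared width

    α²(j₀,ω) = − [Σ_p p c(j₀,p) e^{−iωp}] / [Σ_p ∂c/∂j|_{j₀,p} e^{−iωp}]
             = −i (∂λ/∂ω) / (∂λ/∂j₀)        (the "twist" form),

accepted only where Re α² > 0.  For a chain with exponentially decaying
coupling and a linear gradient of self-excitation
(`W(j,j) = μ₀ + Δ_r j`, feedforward scale μ_f, feedback scale μ_b) this
closes in analytic form, `α² = (μ_f − μ_b) / (2Δ_r (1 + cosh 1/l_c))`.
When μ_f ≈ μ_b the Gaussian fails and a second-order expansion yields an
exponential × Airy profile `e^{β₂(j−j₀)} Ai(β₁^{1/3}(j−j₀) + β₂²β₁^{−2/3})`.
The package builds these network families (plus a connectivity-range
gradient, random self-couplings and long-range perturbations), computes
the numerical spectra with localization diagnostics (decay time, center,
width, participation ratio), evaluates the analytic predictions, and
simulates the dynamics both by direct integration and through the
eigenmode expansion.

Intended users: computational/systems neuroscientists and network
scientists studying how structural gradients, disorder and sparse
long-range links shape the spatial distribution of timescales.

## Worked example

```python
import numpy as np
import eigenlocal as el
from eigenlocal import localization_theory as lt
from eigenlocal.network_models import GradientSelfCouplingParams

params = GradientSelfCouplingParams(mu0=-1.9, delta_r=0.01,
                                    mu_f=0.2, mu_b=0.1, l_c=4)
net = el.build_gradient_self_coupling(100, params)
dec = el.decompose(net)
interior = [m for m in dec.modes if not m.edge]

alpha_sq = lt.gradient_model_alpha_sq(0.2, 0.1, 0.01, 4)
print(f"localized modes: {sum(m.localized for m in dec.modes)}/100")
print(f"closed-form width alpha = {np.sqrt(alpha_sq):.3f} nodes")
print(f"median fitted width     = {np.nanmedian([m.width for m in interior]):.3f} nodes")

m = interior[len(interior) // 2]
pred = lt.predict_gaussian_for_mode(m, 0.2, 0.1, 0.01, 4, 100)
rep = lt.match_prediction(m, pred)
print(f"sample mode: tau={m.tau:.2f}, center={m.center:.1f}, "
      f"PR={m.pr:.1f}, theory similarity={rep['similarity']:.3f}")
```

prints

```
localized modes: 100/100
closed-form width alpha = 1.569 nodes
median fitted width     = 1.585 nodes
sample mode: tau=0.66, center=51.1, PR=4.1, theory similarity=0.998
```

Every eigenvector of this strong-gradient chain is a localized Gaussian
about 1.6 nodes wide (the closed form and the numerical fits agree to
~1%), slower modes sit deeper in the chain (center tracks τ), and the
analytic profile overlaps the numerical one at cosine similarity 0.998.

A command-line interface mirrors the library:

```
eigenlocal build --family gradient-self --n 100 \
    --param mu0=-1.9 --param delta_r=0.01 --param mu_f=0.2 \
    --param mu_b=0.1 --param l_c=4 -o W.mtx
eigenlocal decompose W.mtx -o modes/
eigenlocal predict W.mtx -o predictions/
eigenlocal simulate W.mtx --protocol uniform-pulse -o traj/
eigenlocal run --all -o out/
```

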