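# Methods

## Model

The package studies linear rate networks on one-dimensional lattices,

    dφ_j/dt = Σ_k W(j,k) φ_k(t) + I_j(t),      j = 0 … N−1,

where `W(j,k)` is the coupling from node k to node j (each node's
intrinsic leak is absorbed into the diagonal).  The solution decomposes
over the eigenmodes of W: `φ_j(t) = Σ_λ A_λ(t) v_λ(j)`, each amplitude
evolving as `ã_λ e^{λt}` plus an input convolution.  A stable mode
contributes the timescale τ = 1/Re(−λ) at every node where |v_λ| is
appreciable, so the spatial structure of the eigenvectors decides whether
different parts of the network can respond with different timescales.
All indices are 0-based, including in file outputs.

Four connectivity families are provided:

| family | structure | localization mechanism |
|---|---|---|
| `ring` | `W(j,k) = e^{−d(j,k)/l_c}`, d = circular distance | none (translation invariant ⇒ Fourier modes) |
| `gradient_self_coupling` | chain; diagonal μ₀ + Δ_r·j; bands μ_f e^{−(j−k)/l_c}, μ_b e^{(j−k)/l_c} | gradient of local excitability |
| `gradient_range` | chain; diagonal μ₀; rates f₀+f₁k (feedforward), b₀−b₁k (feedback); optional Gaussian connection noise | opposing gradients of connection range |
| `random_self_coupling` | chain; diagonal ~ N(μ₀, σ²); symmetric band μ_c e^{−|j−k|/l_c} | disorder (the classic random-potential route) |

plus `add_long_range_links`, which sprinkles strong sparse entries between
distant nodes.  Constructors are pure functions of (parameters, seed); a
single `numpy.random.Generator` per construction makes every matrix
bit-reproducible, and all seeds are recorded in metadata and file outputs.

The ring uses circular distance `min(|j−k|, N−|j−k|)` so that the matrix
is exactly circulant; only then is translation invariance, and with it the
constant-magnitude Fourier structure of the eigenvectors, exact.

## Analytic mode-shape theory

The coupling is rewritten in the relative coordinate `c(j,p) = W(j,j−p)`.
For a candidate eigenvector `g_λ(j) e^{iωj}` localized near j₀, expanding
c in j around j₀ and the envelope g to first order in the offset gives

* zeroth order — `λ(j₀,ω) = Σ_p c(j₀,p) e^{−iωp}` (a windowed Fourier
  transform of the local profile; exact on the DFT grid for
  translation-invariant networks);
* first order — a Gaussian envelope of complex squared width
  `α²(j₀,ω) = −F₁/D₁` with `F₁ = Σ_p p·c(j₀,p) e^{−iωp}` and
  `D₁ = Σ_p ∂c/∂j|_{j₀,p} e^{−iωp}`.

`D₁` measures local heterogeneity: it vanishes identically for a
translation-invariant network, and the functions then return the
distinguished `DELOCALIZED` value rather than raising.  A candidate is a
valid localized solution only if Re α² > 0; sweeping (j₀, ω) and recording
(λ(j₀,ω), Re α²) traces the localization region in the complex eigenvalue
plane.  An equivalent derivative route, `α² = −i(∂λ/∂ω)/(∂λ/∂j₀)`, is
implemented with centered finite differences and serves as an internal
consistency check (the two routes agree to <1% on interior nodes of the
gradient chain).

Carrying the expansion to second order in the envelope yields
`(F₂/2) g'' − F₁ g' + D₁ (j−j₀) g = 0` with
`F₂ = Σ_p p² c(j₀,p) e^{−iωp}`, whose bounded solution is an
exponential × Airy profile

    v_λ(j) = e^{β₂ x} Ai(β₁^{1/3} x + β₂² β₁^{−2/3}) e^{iωj},   x = j−j₀,

with β₂ = F₁/F₂ and β₁ = −2D₁/F₂.  For the gradient-of-self-coupling
chain the modes sit at ω = π and everything closes in elementary form:

    α² = (μ_f − μ_b) / (2 Δ_r (1 + cosh 1/l_c)),
    β₁ = Δ_r csch⁴(1/2l_c) sinh³(1/l_c) / (μ_f + μ_b)
       = 8 Δ_r cosh³(1/2l_c) / (sinh(1/2l_c) (μ_f + μ_b)),
    β₂ = (μ_f − μ_b) coth(1/2l_c) / (μ_f + μ_b).

These are mutually consistent: expanding the Airy profile in the
steep-envelope limit recovers the Gaussian with α² = 2β₂/β₁ exactly.  The
cube-root placement in the Airy argument is fixed by this consistency (the
derivation admits no other grouping); `airy_mode` retains an
`arg_convention="linear"` variant for comparison.

## Numerical choices

* **Sums over offsets.**  For chains the offset sums use the true signed
  range p = j₀−(N−1) … j₀ (a chain has no wraparound entries); for rings
  the centered window (−N/2, N/2].  The periodic extension of c in p is
  kept only as an indexing convenience.
* **∂c/∂j** is a centered difference over one node — the native grid.
  Near a chain end the difference picks up boundary truncation of order
  (μ_f/Δ_r)·e^{−j₀/l_c}, which can exceed the true gradient for
  j₀ ≲ l_c·ln(μ_f/(Δ_r l_c)); localization-region maps in the presets and
  reproduction script therefore use j₀ on the central half of the chain.
* **Eigendecomposition** is dense (`scipy.linalg.eig`; networks have
  ≤ a few hundred nodes), residual-checked per mode
  (‖Wv−λv‖ ≤ tol·‖W‖₂‖v‖) and sorted by decay time, ties broken by
  Im λ then dominant frequency.  Eigenvectors are scaled so the
  largest-magnitude component is exactly 1 (real, positive) — the phase
  itself is a convention, fixed only for reproducibility.  Verified
  circulant rings are decomposed in the exact Fourier basis: inside the
  degenerate eigenspaces of a symmetric circulant a generic solver returns
  arbitrary cos/sin mixtures that would hide the constant-magnitude
  structure; the residual check applies unchanged, and tests compare the
  eigenvalues against an independent dense solve.
* **Localization diagnostics.**  Participation ratio
  PR = (Σ|v|²)²/Σ|v|⁴ (1 = one node, N = uniform); a mode counts as
  localized when PR < 0.5·N (the threshold is a recorded, overridable
  parameter — the qualitative transition is far from the threshold in all
  families studied).  Center and width come from a quadratic fit to
  log|v| over the contiguous support around the peak with |v| ≥ 0.01 of
  the peak.  The floor delimits the first-order (Gaussian) core: further
  out the tails are governed by the second-order exponential–Airy
  correction, which would bias the fit — this is a physical cutoff, not a
  numerical one.  Modes whose fitted center lies within 2·l_c of a chain
  end are flagged `edge` and excluded from Gaussian-shape statistics
  (boundary modes are still localized, but as modulated exponentials).
* **Matching theory to a numerical mode.**  The theory does not invert
  λ → (j₀, ω); predictions are anchored observably: ω from the mode's DFT
  peak, j₀ from the fitted center (Gaussian) or by aligning the envelope
  peak to sub-node precision (Airy, where the fitted center is biased by
  the one-sided tail).  Region membership of a numerical eigenvalue is by
  nearest predicted λ(j₀,ω) in the complex plane.
* **Dynamics.**  Direct route: LSODA with rtol 1e-10 / atol 1e-12
  (linear right-hand sides make tight tolerances cheap, and the
  non-normal families amplify transients ~10³–10⁴, so absolute accuracy
  requires resolving large intermediate amplitudes).  Modal route: solve
  V ã = φ₀ and propagate each amplitude analytically; for asymmetric
  nearest-neighbor chains that a diagonal similarity renders symmetric,
  the expansion is evaluated in the symmetrized coordinates where the
  eigenbasis is orthogonal.  Matrices with exponential (multi-range)
  asymmetric bands admit no such symmetrizer — their eigenvector overlap
  is intrinsic — and when the eigenbasis condition number exceeds 1e8 the
  result carries an `IllConditionedBasisWarning` rather than silently
  losing digits.  The weak-gradient chain (Gaussian modes of width ≈ 4
  spaced one node apart, cond(V) ≈ 5·10¹⁴) is the canonical case: its
  modal expansion is mathematically exact but numerically meaningless in
  double precision, which is itself a finding about near-parallel
  eigenbases in heterogeneous networks.
* **Pulse protocols.**  "Response to an input pulse" is implemented as an
  initial condition (uniform or single-node, amplitude 1 by default) with
  zero ongoing input; arbitrary I(j,t) is supported through the
  `custom_function` protocol.  Per-node timescales are the late-time
  slopes of log|φ_j|, fitted on a window running from when the fastest
  mode has decayed by 10³ to when the slowest has decayed by 10¹.

## Preset experiments

`experiments.run_preset` regenerates each figure-level analysis from the
published caption parameters (N = 100 chains/rings, N = 50 for the
range-gradient network), writes all artifacts with fixed float formatting
(re-runs are byte-identical), and evaluates an assertion suite.  Choices
worth noting:

* The printed ring kernel has diagonal 1 and spectral abscissa ≈ +2.16,
  yet its published dynamical response decays, so a leak is evidently
  implicit; the `fig2` preset simulates `W − 3I`, a uniform diagonal
  shift that changes no eigenvector and shifts every timescale equally.
* The range-gradient network at its printed parameters is marginally
  unstable (spectral abscissa ≈ +0.035).  Stability is not enforced at
  construction; presets warn.  Its localization structure and transient
  amplification (gain ≈ 2×10³ under a uniform pulse) are unaffected.
* "Long-range connections added between 10% of the nodes" admits several
  readings; all are implemented (`pair_mode` = `node_pairs`,
  `node_subset`, `pair_fraction`).  Only the pair-fraction reading (10%
  of eligible ordered pairs) reproduces the delocalization of a small
  subset of modes on the strong-gradient base, so the `fig7` preset uses
  it; on the range-gradient base even this reading delocalizes no mode
  past the PR < N/2 threshold with strength 0.05 (1% of that network's
  μ_f = 5) — links that weak can at most hybridize resonant pairs, which
  doubles rather than destroys the participation ratio.
* Disorder sweep: σ ∈ {0, 0.1, 0.33, 1.0}, 20 realizations each, seeds
  drawn from the experiment seed.  The median PR falls strictly with σ
  while the Spearman correlation between mode decay time and mode center
  collapses to ≈ 0 — timescales localize but lose spatial order.

## What the generated data do and do not show

All inputs are generated by the package's own constructors at the
published parameter values; there is no external data.  Passing tests
therefore demonstrate internal consistency of theory and numerics for
one-dimensional exponential-profile networks with at most ~100 nodes:
they do not establish anything about two-dimensional or graph topologies,
spatially correlated disorder, nonlinear rate dynamics, or the
large-N limits of the perturbative arguments.  Gaussian-shape statistics
deliberately exclude boundary modes, so edge behavior is characterized
only qualitatively (localized, non-Gaussian).

## Known limitations

* Dense eigensolvers only; the intended regime is N ≲ a few hundred.
* The first-order theory degrades exactly where it predicts its own
  failure (Re α² ≤ 0, or μ_f ≈ μ_b); the Airy branch covers the latter
  but not fully delocalized modes.
* Modal amplitudes for strongly non-normal matrices are intrinsically
  ill-conditioned (see above); trajectory-level results from
  `modal_solution` should be trusted only when no warning is attached,
  or cross-checked against `simulate`.
* The localization-region membership test is a nearest-neighbor match in
  the eigenvalue plane; for spectra with large gaps a matched eigenvalue
  can be genuinely distant.
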