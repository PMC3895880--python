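"""Eigendecomposition and localization diagnostics.

The timescale of an eigenmode with eigenvalue lambda is tau = 1/Re(-lambda):
stable modes (Re lambda < 0) decay with that e-folding time wherever their
eigenvector has appreciable magnitude.  A mode is *localized* when its
eigenvector occupies a contiguous fraction of the network, quantified here
by the participation ratio PR = (sum |v|^2)^2 / sum |v|^4, which runs from
1 (single node) to N (uniform).

Eigenvectors are normalized so that the component of largest magnitude is
exactly 1 (real and positive); this fixes the otherwise arbitrary phase and
matches how mode profiles are usually plotted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .network_models import ConnectivityMatrix

__all__ = [
    "EigenMode",
    "SpectralDecomposition",
    "UnstableModeError",
    "DegenerateSupportError",
    "decompose",
    "decay_time",
    "participation_ratio",
    "estimate_center_width",
    "classify_localized",
    "dominant_spatial_frequency",
    "mode_heatmap",
]

DEFAULT_PR_FRACTION = 0.5
# Support floor for the Gaussian log-fit.  The first-order (Gaussian) theory
# describes the mode core; below ~1e-2 of the peak the tails are governed by
# the second-order exponential-Airy correction and would bias the fit.
DEFAULT_FIT_FLOOR = 1e-2


class UnstableModeError(ValueError):
    """Raised for Re(lambda) >= 0: the mode grows, there is no decay time."""


class DegenerateSupportError(ValueError):
    """Too few points above the magnitude floor to fit a Gaussian profile."""


class EigensolverError(RuntimeError):
    """Decomposition failed the residual check; carries the worst residual."""

    def __init__(self, message: str, worst_residual: float):
        super().__init__(message)
        self.worst_residual = worst_residual


@dataclass(frozen=True)
class EigenMode:
    """One eigenvalue/eigenvector pair with derived diagnostics."""

    lam: complex
    v: np.ndarray
    tau: float                 # 1/Re(-lam); inf if the mode does not decay
    omega: float               # dominant spatial frequency, radians/node
    center: float              # vertex of the quadratic log-magnitude fit
    width: float               # implied Gaussian width in nodes (nan if none)
    fit_r2: float              # r^2 of the log-magnitude fit
    pr: float                  # participation ratio
    localized: bool
    edge: bool = False         # center within 2 l_c of a chain end

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.v)


@dataclass(frozen=True)
class SpectralDecomposition:
    """All N modes of a connectivity matrix, sorted by increasing decay time.

    Ties (conjugate pairs share tau) break by ascending Im(lambda), then by
    ascending dominant frequency, so the ordering is deterministic.
    """

    modes: tuple
    source: ConnectivityMatrix
    tol: float

    @property
    def N(self) -> int:
        return self.source.N

    def eigenvalues(self) -> np.ndarray:
        return np.array([m.lam for m in self.modes])

    def eigenvector_matrix(self) -> np.ndarray:
        """Columns are the (max-normalized) eigenvectors, in mode order."""
        return np.column_stack([m.v for m in self.modes])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(len(self.modes)),
            "re_lambda": [m.lam.real for m in self.modes],
            "im_lambda": [m.lam.imag for m in self.modes],
            "tau": [m.tau for m in self.modes],
            "center": [m.center for m in self.modes],
            "width": [m.width for m in self.modes],
            "fit_r2": [m.fit_r2 for m in self.modes],
            "pr": [m.pr for m in self.modes],
            "omega": [m.omega for m in self.modes],
            "localized": [m.localized for m in self.modes],
            "edge": [m.edge for m in self.modes],
        })

    def save(self, outdir: str | Path, float_format: str = "%.12g") -> None:
        """Write the mode table and the complex eigenvector matrix as CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "modes.csv", index=False,
                               float_format=float_format)
        V = self.eigenvector_matrix()
        np.savetxt(outdir / "eigenvectors_real.csv", V.real, delimiter=",",
                   fmt=float_format)
        np.savetxt(outdir / "eigenvectors_imag.csv", V.imag, delimiter=",",
                   fmt=float_format)


def decay_time(lam: complex) -> float:
    """Decay time 1/Re(-lambda) of a stable mode; oscillation is ignored."""
    if lam.real >= 0:
        raise UnstableModeError(
            f"mode with eigenvalue {lam} does not decay (Re >= 0)")
    return 1.0 / (-lam.real)


def participation_ratio(v: np.ndarray) -> float:
    """Effective number of nodes occupied: (sum|v|^2)^2 / sum|v|^4."""
    v = np.asarray(v)
    a2 = np.abs(v) ** 2
    s2 = a2.sum()
    if s2 == 0:
        raise ValueError("participation ratio of the zero vector is undefined")
    return float(s2 ** 2 / (a2 ** 2).sum())


def dominant_spatial_frequency(v: np.ndarray) -> float:
    """Location of the DFT magnitude peak, in radians/node on (-pi, pi]."""
    v = np.asarray(v)
    if not np.any(v):
        raise ValueError("zero vector has no dominant frequency")
    spec = np.abs(np.fft.fft(v))
    k = int(np.argmax(spec))
    N = len(v)
    omega = 2.0 * np.pi * k / N
    if omega > np.pi:
        omega -= 2.0 * np.pi
    return float(omega)


def estimate_center_width(v: np.ndarray, floor: float = DEFAULT_FIT_FLOOR
                          ) -> tuple[float, float, float]:
    """Fit log|v(j)| to a parabola over the support above ``floor * max|v|``.

    Returns (center, width, r2): the parabola vertex, the Gaussian width
    implied by its curvature (nan when the fit curves the wrong way), and
    the coefficient of determination of the fit.
    """
    mag = np.abs(np.asarray(v, dtype=complex))
    peak = mag.max()
    if peak == 0:
        raise ValueError("cannot fit the zero vector")
    # contiguous support containing the peak: distant points that clear the
    # floor (noise, secondary lobes) must not enter the fit
    above = mag >= floor * peak
    k = int(np.argmax(mag))
    lo = k
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(mag) - 1 and above[hi + 1]:
        hi += 1
    support = np.arange(lo, hi + 1)
    if len(support) < 4:
        raise DegenerateSupportError(
            f"only {len(support)} points above the fit floor; need >= 4")
    x = support.astype(float)
    y = np.log(mag[support])
    coeffs = np.polyfit(x, y, 2)
    a, b, _ = coeffs
    resid = y - np.polyval(coeffs, x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    if a >= 0:
        # log-magnitude curves upward: no Gaussian bump; report the peak
        return float(np.argmax(mag)), float("nan"), float(r2)
    center = -b / (2.0 * a)
    width = float(np.sqrt(-1.0 / (2.0 * a)))
    return float(center), width, float(r2)


def classify_localized(pr: float, N: int,
                       pr_fraction: float = DEFAULT_PR_FRACTION) -> bool:
    """A mode is localized when its participation ratio is below
    ``pr_fraction * N`` (default half the network)."""
    return bool(pr < pr_fraction * N)


def _diagnose(lam: complex, v: np.ndarray, N: int, pr_fraction: float,
              floor: float, edge_margin: Optional[float]) -> EigenMode:
    pr = participation_ratio(v)
    omega = dominant_spatial_frequency(v)
    try:
        center, width, r2 = estimate_center_width(v, floor=floor)
    except DegenerateSupportError:
        center, width, r2 = float(np.argmax(np.abs(v))), float("nan"), float("nan")
    tau = 1.0 / (-lam.real) if lam.real < 0 else float("inf")
    edge = False
    if edge_margin is not None:
        edge = bool(center < edge_margin or center > N - 1 - edge_margin)
    return EigenMode(lam=complex(lam), v=v, tau=tau, omega=omega,
                     center=center, width=width, fit_r2=r2, pr=pr,
                     localized=classify_localized(pr, N, pr_fraction),
                     edge=edge)


def normalize_eigenvector(v: np.ndarray) -> np.ndarray:
    """Scale so the largest-magnitude component is exactly 1 + 0j."""
    k = int(np.argmax(np.abs(v)))
    return v / v[k]


def _is_circulant(W: np.ndarray, rtol: float = 1e-12) -> bool:
    N = W.shape[0]
    shifts = np.array([np.roll(W[0], j) for j in range(N)])
    return bool(np.allclose(W, shifts, rtol=0, atol=rtol * np.abs(W).max()))


def decompose(cm: ConnectivityMatrix, tol: float = 1e-8,
              pr_fraction: float = DEFAULT_PR_FRACTION,
              floor: float = DEFAULT_FIT_FLOOR) -> SpectralDecomposition:
    """Dense eigendecomposition with per-mode localization diagnostics.

    Each returned mode satisfies ||W v - lam v|| <= tol * ||W|| * ||v||;
    a worse residual (e.g. a defective matrix) raises
    :class:`EigensolverError`.  Modes are sorted by increasing decay time.

    Circulant ring matrices are decomposed in their exact Fourier eigenbasis
    (v_k(j) = e^{2 pi i k j / N}): inside the degenerate eigenspaces of a
    symmetric circulant a generic dense solver returns arbitrary real
    cos/sin mixtures, which would mask the constant-magnitude structure the
    translation invariance dictates.  The residual check applies either way.
    """
    W = cm.W
    N = cm.N
    if cm.topology == "ring" and _is_circulant(W):
        j = np.arange(N)
        # lambda_k = sum_m W(0, m) e^{2 pi i k m / N}: apply W to the wave
        lams = np.array([np.sum(W[0] * np.exp(2j * np.pi * k * j / N))
                         for k in range(N)])
        V = np.exp(2j * np.pi * np.outer(j, j) / N)
    else:
        lams, V = scipy.linalg.eig(W)
    scale = np.linalg.norm(W, 2)
    worst = 0.0
    l_c = cm.decay_length
    edge_margin = 2.0 * l_c if (cm.topology == "chain" and l_c) else None
    modes = []
    for i in range(N):
        v = normalize_eigenvector(V[:, i])
        resid = np.linalg.norm(W @ v - lams[i] * v) / (scale * np.linalg.norm(v))
        worst = max(worst, resid)
        modes.append(_diagnose(lams[i], v, N, pr_fraction, floor, edge_margin))
    if worst > tol:
        raise EigensolverError(
            f"eigendecomposition residual {worst:.3e} exceeds tol {tol:.3e}",
            worst)
    modes.sort(key=lambda m: (m.tau, m.lam.imag, m.omega))
    return SpectralDecomposition(modes=tuple(modes), source=cm, tol=tol)


def mode_heatmap(dec: SpectralDecomposition, floor: float = 1e-6) -> np.ndarray:
    """N x N matrix of log10(max(|v(j)|, floor)); rows are modes in tau
    order, columns are nodes — the standard localization heat map."""
    return np.array([np.log10(np.maximum(m.magnitude, floor))
                     for m in dec.modes])
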