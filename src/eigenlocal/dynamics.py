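"""Linear network dynamics and its modal decomposition.

The node activities obey  d/dt phi_j = sum_k W(j,k) phi_k + I_j(t).  Two
solution routes are provided and must agree: direct adaptive ODE
integration (:func:`simulate`) and the eigenmode expansion

    phi_j(t) = sum_lam ( a_lam e^{lam t}
                         + int_0^t e^{lam (t-t')} I_lam(t') dt' ) v_lam(j)

(:func:`modal_solution`), where a_lam and I_lam are the initial condition
and input expressed in eigenvector coordinates.  For non-normal W the
eigenbasis can be badly conditioned; the modal route then attaches a
warning rather than failing, since transient amplification is exactly the
regime of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.stats

from .network_models import ConnectivityMatrix, spectral_abscissa
from .spectral import SpectralDecomposition

__all__ = [
    "InputProtocol",
    "TrajectorySet",
    "ModalAmplitudes",
    "IllConditionedBasisWarning",
    "simulate",
    "modal_solution",
    "node_timescales",
]

# Tight tolerances: the systems are linear (cheap right-hand sides) and the
# non-normal families amplify transients by ~1e4, so absolute accuracy of the
# trajectory requires resolving large intermediate amplitudes.
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12


class IllConditionedBasisWarning(UserWarning):
    """The eigenbasis condition number is large (non-normal matrix);
    modal amplitudes may be inaccurate in absolute terms."""


@dataclass(frozen=True)
class InputProtocol:
    """External drive / initial condition protocol.

    ``uniform_pulse`` and ``node_pulse`` are implemented as initial
    conditions (phi0 = amplitude everywhere, or at one node) with zero
    ongoing input; ``custom_function`` supplies I(node_index_array, t).
    """

    kind: str = "none"                 # none | uniform_pulse | node_pulse | custom_function
    amplitude: float = 1.0
    node: int = 0
    I: Optional[Callable[[np.ndarray, float], np.ndarray]] = None

    def __post_init__(self):
        if self.kind not in ("none", "uniform_pulse", "node_pulse",
                             "custom_function"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.kind == "custom_function" and self.I is None:
            raise ValueError("custom_function protocol requires I")

    def initial_condition(self, N: int,
                          phi0: Optional[np.ndarray] = None) -> np.ndarray:
        if self.kind == "uniform_pulse":
            return np.full(N, self.amplitude, dtype=float)
        if self.kind == "node_pulse":
            out = np.zeros(N)
            out[self.node] = self.amplitude
            return out
        if phi0 is None:
            return np.zeros(N)
        return np.asarray(phi0, dtype=float)

    def drive(self, j: np.ndarray, t: float) -> np.ndarray:
        if self.kind == "custom_function":
            return np.asarray(self.I(j, t), dtype=float)
        return np.zeros(len(j))


@dataclass(frozen=True)
class TrajectorySet:
    """Node activities phi_j(t) on a time grid, with provenance."""

    t: np.ndarray
    phi: np.ndarray                    # N x T
    protocol: InputProtocol
    source: Optional[ConnectivityMatrix] = None
    integrator: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.phi.shape[0]

    def total_activity(self) -> np.ndarray:
        """Sum over nodes of |phi_j(t)| — the transient-growth observable."""
        return np.abs(self.phi).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (t, node)."""
        T = len(self.t)
        return pd.DataFrame({
            "t": np.repeat(self.t, self.N),
            "node": np.tile(np.arange(self.N), T),
            "value": self.phi.T.reshape(-1),
        })

    def save(self, outdir: str | Path, float_format: str = "%.12g") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "trajectories.csv", index=False,
                               float_format=float_format)
        np.savetxt(outdir / "phi_wide.csv", self.phi, delimiter=",",
                   fmt=float_format)


@dataclass(frozen=True)
class ModalAmplitudes:
    """Initial condition and input in eigenvector coordinates."""

    a_tilde: np.ndarray
    lam: np.ndarray
    condition_number: float


def simulate(cm: ConnectivityMatrix, phi0: Optional[np.ndarray],
             protocol: InputProtocol, t: np.ndarray,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
             ) -> TrajectorySet:
    """Integrate the network ODE on the given (increasing) time grid."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be an increasing 1-D grid")
    N = cm.N
    W = cm.W
    x0 = protocol.initial_condition(N, phi0)
    if len(x0) != N:
        raise ValueError(f"phi0 has length {len(x0)}, expected {N}")
    nodes = np.arange(N)

    def rhs(ti, x):
        return W @ x + protocol.drive(nodes, ti)

    sol = scipy.integrate.solve_ivp(rhs, (t[0], t[-1]), x0, t_eval=t,
                                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            "integration failed or blew up; spectral abscissa = "
            f"{spectral_abscissa(cm):.4g}")
    return TrajectorySet(t=t, phi=sol.y, protocol=protocol, source=cm,
                         integrator={"method": "LSODA", "rtol": rtol,
                                     "atol": atol})


def _chain_symmetrizer(W: np.ndarray) -> Optional[np.ndarray]:
    """Diagonal t with t_j/t_{j-1} = sqrt(W(j-1,j)/W(j,j-1)), if it exists.

    For asymmetric nearest-neighbor (tridiagonal-type) chains the
    similarity diag(t)^-1 W diag(t) is symmetric, so its eigenbasis is
    orthogonal even though W itself is strongly non-normal.  Chains with
    longer-range coupling generally fail the consistency requirement
    (the ratio W(j,k)/W(k,j) must be multiplicative along the chain);
    the symmetry check below then returns None and the caller falls back
    to the plain eigenbasis.
    """
    N = W.shape[0]
    up = np.array([W[j - 1, j] for j in range(1, N)])
    dn = np.array([W[j, j - 1] for j in range(1, N)])
    if np.any(up * dn <= 0):
        return None
    log_t = np.concatenate([[0.0], 0.5 * np.cumsum(np.log(dn / up))])
    if log_t.max() - log_t.min() > 600:     # exp() would overflow
        return None
    t = np.exp(log_t - log_t.mean())
    B = (W / t[:, None]) * t[None, :]
    if np.max(np.abs(B - B.T)) > 1e-8 * np.max(np.abs(B)):
        return None
    return t


def modal_solution(dec: SpectralDecomposition, phi0: Optional[np.ndarray],
                   protocol: InputProtocol, t: np.ndarray,
                   cond_threshold: float = 1e8,
                   imag_tol: float = 1e-9
                   ) -> tuple[TrajectorySet, ModalAmplitudes]:
    """Evaluate the eigenmode expansion of the solution on the grid.

    The initial condition is decomposed by solving V a = phi0; each
    amplitude then evolves as a e^{lam t} (pulse protocols carry no ongoing
    input; a custom input is handled by integrating the decoupled modal
    ODEs).  Trajectories are returned as real parts, with a check that the
    imaginary residue is negligible for real inputs.

    When the eigenbasis is badly conditioned but the matrix is an
    asymmetric chain that a diagonal similarity makes symmetric, the same
    eigen-expansion is evaluated in the symmetrized coordinates, where the
    eigenbasis is orthogonal and the expansion is numerically exact; the
    reported amplitudes are still those of the original basis.
    """
    t = np.asarray(t, dtype=float)
    N = dec.N
    V = dec.eigenvector_matrix()
    lam = dec.eigenvalues()
    W = dec.source.W
    x0 = protocol.initial_condition(N, phi0)
    cond = float(np.linalg.cond(V))
    if cond > cond_threshold:
        warnings.warn(
            f"eigenbasis condition number {cond:.3g} exceeds {cond_threshold:.3g}; "
            "modal amplitudes of this non-normal matrix may be inaccurate",
            IllConditionedBasisWarning)
    a = np.linalg.solve(V, x0.astype(complex))

    sym_t = _chain_symmetrizer(W) if (cond > 1e4 and
                                      protocol.kind != "custom_function") else None
    if sym_t is not None:
        B = (W / sym_t[:, None]) * sym_t[None, :]
        lamB, VB = np.linalg.eigh((B + B.T) / 2.0)
        psi0 = VB.T @ (x0 / sym_t)
        A_t = psi0[:, None] * np.exp(lamB[:, None] * t[None, :])
        phi = sym_t[:, None] * (VB @ A_t)
        traj = TrajectorySet(t=t, phi=phi, protocol=protocol,
                             source=dec.source,
                             integrator={"method": "modal-symmetrized",
                                         "cond": cond})
        return traj, ModalAmplitudes(a_tilde=a, lam=lam,
                                     condition_number=cond)

    if protocol.kind == "custom_function":
        nodes = np.arange(N)
        Vinv = np.linalg.inv(V)

        def rhs(ti, y):
            A = y[:N] + 1j * y[N:]
            dA = lam * A + Vinv @ protocol.drive(nodes, ti)
            return np.concatenate([dA.real, dA.imag])

        y0 = np.concatenate([a.real, a.imag])
        sol = scipy.integrate.solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t,
                                        method="LSODA", rtol=DEFAULT_RTOL,
                                        atol=DEFAULT_ATOL)
        A_t = sol.y[:N] + 1j * sol.y[N:]
    else:
        A_t = a[:, None] * np.exp(lam[:, None] * t[None, :])

    phi = V @ A_t
    if np.isrealobj(dec.source.W) and np.isrealobj(x0):
        residue = np.max(np.abs(phi.imag)) / max(np.max(np.abs(phi)), 1.0)
        if residue > imag_tol:
            warnings.warn(
                f"imaginary residue {residue:.3g} above {imag_tol:.1g} "
                "(ill-conditioned eigenbasis)", IllConditionedBasisWarning)
    traj = TrajectorySet(t=t, phi=phi.real, protocol=protocol,
                         source=dec.source,
                         integrator={"method": "modal", "cond": cond})
    return traj, ModalAmplitudes(a_tilde=a, lam=lam, condition_number=cond)


def default_fit_window(dec: SpectralDecomposition, fast_decades: float = 3.0,
                       slow_decades: float = 1.0) -> tuple[float, float]:
    """Late-time window for timescale fits: from when the fastest mode has
    decayed by 10^fast_decades to when the slowest has decayed by
    10^slow_decades — past the non-normal transient, before underflow."""
    taus = np.array([m.tau for m in dec.modes if np.isfinite(m.tau)])
    if len(taus) == 0:
        raise ValueError("no decaying modes to define a window")
    t0 = taus.min() * fast_decades * np.log(10.0)
    t1 = taus.max() * slow_decades * np.log(10.0)
    if t1 <= t0:
        t1 = 2.0 * t0
    return float(t0), float(t1)


def node_timescales(traj: TrajectorySet,
                    window: Optional[tuple[float, float]] = None,
                    floor: float = 1e-12) -> pd.DataFrame:
    """Per-node decay time from the late-time slope of log|phi_j(t)|.

    Nodes whose activity dips below ``floor`` inside the window are
    flagged ``below_floor`` and given a NaN timescale.
    """
    t = traj.t
    if window is None:
        window = (t[0] + 0.5 * (t[-1] - t[0]), t[-1])
    t0, t1 = window
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 2:
        raise ValueError(f"window {window} covers fewer than 2 grid points")
    rows = []
    for j in range(traj.N):
        y = np.abs(traj.phi[j, mask])
        ok = np.all(y > floor)
        if ok:
            slope = np.polyfit(t[mask], np.log(y), 1)[0]
            tau = -1.0 / slope if slope < 0 else float("inf")
        else:
            tau = float("nan")
        rows.append((j, tau, not ok))
    return pd.DataFrame(rows, columns=["node", "tau", "below_floor"])


def spatial_timescale_correlation(df: pd.DataFrame) -> float:
    """Spearman correlation between node index and fitted decay time."""
    ok = df[~df["below_floor"] & np.isfinite(df["tau"])]
    rho, _ = scipy.stats.spearmanr(ok["node"], ok["tau"])
    return float(rho)
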