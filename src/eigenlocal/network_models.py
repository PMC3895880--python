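"""Constructors for the connectivity-matrix families.

All networks are one-dimensional: either a ring (periodic) or a chain
(open boundaries) of ``N`` nodes.  ``W[j, k]`` is the coupling from node
``k`` onto node ``j`` (rate per unit time), and node indices are 0-based
everywhere, including in file outputs.

Every constructor is a pure function of its parameters and seed: calling
it twice returns bit-identical matrices.  Randomness always flows through
a single :class:`numpy.random.Generator` created from the recorded seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "InvalidParameterError",
    "ConnectivityMatrix",
    "GradientSelfCouplingParams",
    "GradientRangeParams",
    "RandomSelfCouplingParams",
    "build_ring",
    "build_gradient_self_coupling",
    "build_gradient_range",
    "build_random_self_coupling",
    "add_long_range_links",
    "spectral_abscissa",
    "save_matrix",
    "load_matrix",
]


class InvalidParameterError(ValueError):
    """A network parameter violates its domain constraint."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """An N-by-N coupling matrix together with its provenance.

    Attributes
    ----------
    W : numpy.ndarray
        Real coupling matrix; entry ``(j, k)`` couples node ``k`` to ``j``.
    family : str
        One of ``ring``, ``gradient_self_coupling``, ``gradient_range``,
        ``random_self_coupling``, ``custom``.
    params : dict
        The parameter record the matrix was built from.
    seed : int or None
        Seed of the generator used for any random entries.
    topology : str
        ``ring`` or ``chain``.
    """

    W: np.ndarray
    family: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None
    topology: str = "chain"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidParameterError(f"W must be square, got shape {W.shape}")
        if not np.all(np.isfinite(W)):
            raise InvalidParameterError("W contains non-finite entries")
        object.__setattr__(self, "W", W)

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def decay_length(self) -> Optional[float]:
        """Characteristic decay length l_c of the family, if it has one."""
        return self.params.get("l_c")

    def with_matrix(self, W: np.ndarray, family: Optional[str] = None,
                    params: Optional[dict] = None) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            W=W,
            family=self.family if family is None else family,
            params=dict(self.params) if params is None else params,
            seed=self.seed,
            topology=self.topology,
        )


@dataclass(frozen=True)
class GradientSelfCouplingParams:
    """Chain with exponentially decaying coupling and a linear gradient of
    self-excitation: W(j,j) = mu0 + delta_r * j."""

    mu0: float
    delta_r: float
    mu_f: float
    mu_b: float
    l_c: float

    def validate(self) -> None:
        if self.l_c <= 0:
            raise InvalidParameterError(f"l_c must be positive, got {self.l_c}")
        if self.mu0 >= 0:
            raise InvalidParameterError(f"mu0 is a leak and must be negative, got {self.mu0}")
        if self.delta_r < 0:
            raise InvalidParameterError(f"delta_r must be >= 0, got {self.delta_r}")


@dataclass(frozen=True)
class GradientRangeParams:
    """Chain with position-dependent connection ranges: feedforward decay
    rate f0 + f1*k grows with the source node while the feedback rate
    b0 - b1*k shrinks, plus optional Gaussian noise on the connections."""

    mu0: float
    mu_f: float
    mu_b: float
    f0: float
    f1: float
    b0: float
    b1: float
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self, N: int) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for k in range(N):
            if self.f0 + self.f1 * k <= 0:
                raise InvalidParameterError(
                    f"feedforward decay rate f0 + f1*k is non-positive at node k={k}")
            if self.b0 - self.b1 * k <= 0:
                raise InvalidParameterError(
                    f"feedback decay rate b0 - b1*k is non-positive at node k={k}")


@dataclass(frozen=True)
class RandomSelfCouplingParams:
    """Chain with translation-invariant off-diagonal coupling and i.i.d.
    Gaussian self-couplings, N(mu0, sigma^2)."""

    mu0: float
    mu_c: float
    l_c: float
    sigma: float
    seed: int = 0

    def validate(self) -> None:
        if self.l_c <= 0:
            raise InvalidParameterError(f"l_c must be positive, got {self.l_c}")
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")


def _check_N(N: int, minimum: int = 1) -> None:
    if not isinstance(N, (int, np.integer)) or N < minimum:
        raise InvalidParameterError(f"N must be an integer >= {minimum}, got {N!r}")


def build_ring(N: int, l_c: float) -> ConnectivityMatrix:
    """Ring of N nodes with coupling exp(-d/l_c) in circular distance d.

    The matrix is circulant (every row is a cyclic shift of row 0), so its
    eigenvectors are the discrete Fourier modes and every mode is maximally
    delocalized regardless of how sharply the coupling decays.
    """
    _check_N(N, 3)
    if l_c <= 0:
        raise InvalidParameterError(f"l_c must be positive, got {l_c}")
    idx = np.arange(N)
    diff = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(diff, N - diff)
    W = np.exp(-d / l_c)
    return ConnectivityMatrix(W, family="ring", params={"l_c": float(l_c)},
                              topology="ring")


def build_gradient_self_coupling(N: int, p: GradientSelfCouplingParams) -> ConnectivityMatrix:
    """Chain whose self-coupling increases linearly along the chain.

    W(j,j) = mu0 + delta_r*j; feedforward entries (j > k) are
    mu_f*exp(-(j-k)/l_c) and feedback entries mu_b*exp(-(k-j)/l_c).
    The gradient breaks translation invariance and is what allows
    Gaussian-localized eigenvectors.
    """
    _check_N(N, 2)
    p.validate()
    j = np.arange(N)
    diff = j[:, None] - j[None, :]  # j - k
    W = np.where(diff > 0, p.mu_f * np.exp(-diff / p.l_c), 0.0)
    W = np.where(diff < 0, p.mu_b * np.exp(diff / p.l_c), W)
    W[j, j] = p.mu0 + p.delta_r * j
    return ConnectivityMatrix(W, family="gradient_self_coupling",
                              params=dataclasses.asdict(p), topology="chain")


def build_gradient_range(N: int, p: GradientRangeParams,
                         noise_on_diagonal: bool = False) -> ConnectivityMatrix:
    """Chain with opposing gradients of connection range.

    Feedforward range shrinks along the chain (rate f0 + f1*k) while
    feedback range grows (rate b0 - b1*k); the diagonal is a uniform leak
    mu0.  Zero-mean Gaussian noise of standard deviation ``noise_sd`` is
    added to every off-diagonal connection (and to the diagonal too if
    ``noise_on_diagonal``), drawn from the recorded seed.
    """
    _check_N(N, 2)
    p.validate(N)
    j = np.arange(N)
    diff = j[:, None] - j[None, :]  # j - k
    ff_rate = p.f0 + p.f1 * j[None, :]   # depends on source node k
    fb_rate = p.b0 - p.b1 * j[None, :]
    W = np.where(diff > 0, p.mu_f * np.exp(-ff_rate * diff), 0.0)
    W = np.where(diff < 0, p.mu_b * np.exp(fb_rate * diff), W)
    W[j, j] = p.mu0
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        noise = rng.normal(0.0, p.noise_sd, size=(N, N))
        if not noise_on_diagonal:
            noise[j, j] = 0.0
        W = W + noise
    return ConnectivityMatrix(W, family="gradient_range",
                              params=dataclasses.asdict(p), seed=p.seed,
                              topology="chain")


def build_random_self_coupling(N: int, p: RandomSelfCouplingParams) -> ConnectivityMatrix:
    """Chain with random self-couplings, the discrete-disorder route to
    localization: W(j,j) ~ N(mu0, sigma^2) i.i.d., off-diagonal
    mu_c*exp(-|j-k|/l_c)."""
    _check_N(N, 2)
    p.validate()
    j = np.arange(N)
    dist = np.abs(j[:, None] - j[None, :])
    W = p.mu_c * np.exp(-dist / p.l_c)
    rng = np.random.default_rng(p.seed)
    W[j, j] = rng.normal(p.mu0, p.sigma, size=N)
    return ConnectivityMatrix(W, family="random_self_coupling",
                              params=dataclasses.asdict(p), seed=p.seed,
                              topology="chain")


def add_long_range_links(base: ConnectivityMatrix, strength: float,
                         fraction: float, seed: int = 0,
                         symmetric: bool = False,
                         pair_mode: str = "node_pairs",
                         min_separation: Optional[float] = None) -> ConnectivityMatrix:
    """Return a copy of ``base`` with sparse long-range links added.

    Links are placed only between nodes whose separation exceeds
    ``min_separation`` (default three decay lengths of the base family);
    ``strength`` is added to each selected directed entry, and with
    ``symmetric=True`` to the reciprocal entry as well.  "A fraction of the
    nodes" admits several readings, all seeded and recorded in metadata:

    ``node_pairs``
        ceil(fraction * N) ordered node pairs drawn uniformly without
        replacement (a sprinkling of individual links).
    ``node_subset``
        a subset of ceil(fraction * N) nodes is drawn and every eligible
        ordered pair within the subset is linked.
    ``pair_fraction``
        ceil(fraction * #eligible ordered pairs) links — a dense random
        long-range background.

    The base matrix is never modified.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidParameterError(f"fraction must lie in [0, 1], got {fraction}")
    if pair_mode not in ("node_pairs", "node_subset", "pair_fraction"):
        raise InvalidParameterError(f"unknown pair_mode {pair_mode!r}")
    N = base.N
    if min_separation is None:
        l_c = base.decay_length
        min_separation = 3.0 * l_c if l_c is not None else 3.0
    W = base.W.copy()
    pairs: list[tuple[int, int]] = []
    if fraction > 0:
        rng = np.random.default_rng(seed)
        jj, kk = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
        eligible = np.argwhere(np.abs(jj - kk) > min_separation)
        if len(eligible) == 0:
            raise InvalidParameterError(
                "no node pairs with separation above the long-range cutoff")
        if pair_mode == "node_subset":
            nodes = rng.choice(N, size=math.ceil(fraction * N), replace=False)
            chosen = set(int(n) for n in nodes)
            selected = [(j, k) for j, k in eligible
                        if j in chosen and k in chosen]
        else:
            n_links = math.ceil(fraction * (len(eligible)
                                            if pair_mode == "pair_fraction"
                                            else N))
            take = rng.choice(len(eligible), size=min(n_links, len(eligible)),
                              replace=False)
            selected = [tuple(e) for e in eligible[take]]
        for j, k in selected:
            W[j, k] += strength
            pairs.append((int(j), int(k)))
            if symmetric:
                W[k, j] += strength
    params = dict(base.params)
    params.update({
        "long_range_strength": float(strength),
        "long_range_fraction": float(fraction),
        "long_range_seed": int(seed),
        "long_range_symmetric": bool(symmetric),
        "long_range_pair_mode": pair_mode,
        "long_range_pairs": pairs,
        "base_family": base.family,
    })
    return ConnectivityMatrix(W, family="custom", params=params, seed=seed,
                              topology=base.topology)


def spectral_abscissa(cm: ConnectivityMatrix | np.ndarray) -> float:
    """Maximum real part of the spectrum; negative means asymptotically stable."""
    W = cm.W if isinstance(cm, ConnectivityMatrix) else np.asarray(cm)
    return float(np.max(np.linalg.eigvals(W).real))


# -- Matrix Market I/O -------------------------------------------------------

def save_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Write W in Matrix Market coordinate format plus a JSON sidecar
    (same stem, ``.json``) carrying family, params, seed and topology."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.W))
    meta = {
        "family": cm.family,
        "params": _jsonable(cm.params),
        "seed": cm.seed,
        "topology": cm.topology,
        "N": cm.N,
        "index_base": 0,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a Matrix Market file (and its JSON sidecar if present)."""
    path = Path(path)
    M = scipy.io.mmread(str(path))
    if scipy.sparse.issparse(M):
        M = M.toarray()
    W = np.asarray(M, dtype=float)
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        return ConnectivityMatrix(W, family=meta.get("family", "custom"),
                                  params=meta.get("params", {}),
                                  seed=meta.get("seed"),
                                  topology=meta.get("topology", "chain"))
    return ConnectivityMatrix(W, family="custom", topology="chain")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
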