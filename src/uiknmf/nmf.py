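"""Nonnegative matrix factorization by multiplicative updates.

Approximates a nonnegative target ``V`` (m x n) as a product ``W @ H`` of a
nonnegative basis ``W`` (m x r, the "metagenes" or signatures) and nonnegative
mixture coefficients ``H`` (r x n), with rank ``r <= min(m, n)``.  Three
classical update rules are provided:

``lee``
    Multiplicative updates for the Frobenius objective ``||V - WH||_F^2``.
``brunet``
    Multiplicative updates for the generalized Kullback-Leibler divergence
    ``D(V || WH)``.
``nsnmf``
    Nonsmooth NMF: a doubly stochastic smoothing matrix ``S(theta)`` is
    interposed (``V ~ W S H``) during KL updates, driving sparseness into the
    factors; ``S`` is absorbed into the returned basis so that ``W @ H`` is
    always the model reconstruction.

Both update rules are monotone: the corresponding objective never increases,
which the test suite checks to a 1e-9 relative tolerance.  Convergence is
declared when the sample-to-cluster assignment (argmax coefficient per
column) has not changed for a configurable number of consecutive checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArgumentError, DimensionError, RankError, ValidationError
from .matrix import TargetMatrix

__all__ = [
    "EPS_DEFAULT",
    "AlgorithmSpec",
    "Factorization",
    "init_random",
    "update_frobenius",
    "update_kl",
    "smoothing_matrix",
    "fit",
    "fit_restarts",
    "rss",
    "derive_seed",
    "frobenius_objective",
    "kl_objective",
]

#: Denominator guard: one unit in the last place of 1.0.
EPS_DEFAULT = 2.0**-52

_ALGORITHMS = ("lee", "brunet", "nsnmf")


def derive_seed(*parts: int) -> int:
    """Deterministically fold integer keys into a single seed below 2**31.

    Used to give every (rank, restart) pair its own independent stream while
    keeping whole surveys reproducible from one base seed.
    """
    seq = np.random.SeedSequence([int(p) for p in parts])
    return int(seq.generate_state(1, dtype=np.uint32)[0] >> 1)


@dataclass(frozen=True)
class AlgorithmSpec:
    """Configuration of a single NMF run.

    Parameters
    ----------
    name
        ``lee`` (Frobenius), ``brunet`` (KL), or ``nsnmf`` (nonsmooth KL).
    theta
        Smoothing weight in [0, 1]; only consulted by ``nsnmf``.
    max_iter
        Hard iteration cap.
    conn_stall
        Number of consecutive unchanged connectivity checks (one check every
        ``check_every`` iterations) that declares convergence.
    objective_tol
        When set, convergence is instead declared once the relative
        objective improvement per check falls below this value — the right
        criterion for completion/regression-style fits, where the
        cluster-assignment stall can trigger long before the objective has
        converged.
    eps
        Additive guard on update denominators.
    seed
        Seed for the random initialization.
    """

    name: str = "brunet"
    theta: float = 0.5
    max_iter: int = 2000
    conn_stall: int = 40
    check_every: int = 10
    objective_tol: float | None = None
    eps: float = EPS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in _ALGORITHMS:
            raise ArgumentError(f"unknown algorithm {self.name!r}; expected one of {_ALGORITHMS}")
        if not 0.0 <= self.theta <= 1.0:
            raise ArgumentError(f"theta must lie in [0, 1], got {self.theta}")
        if self.max_iter < 1:
            raise ArgumentError("max_iter must be >= 1")
        if self.eps <= 0:
            raise ArgumentError("eps must be positive")
        if self.conn_stall < 1 or self.check_every < 1:
            raise ArgumentError("conn_stall and check_every must be >= 1")
        if self.objective_tol is not None and self.objective_tol <= 0:
            raise ArgumentError("objective_tol must be positive when set")


@dataclass
class Factorization:
    """Result of one NMF run: ``V ~ W @ H`` plus convergence metadata."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    algorithm: AlgorithmSpec
    n_iter: int
    objective_trace: list[float]
    rss: float
    converged: bool = field(default=False)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def _as_array(V) -> np.ndarray:
    return V.values if isinstance(V, TargetMatrix) else np.asarray(V, dtype=float)


def init_random(
    m: int, n: int, r: int, seed: int, scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Strictly positive i.i.d. uniform-(0, scale] starting matrices W, H.

    Identical (seed, shape, scale) always yields bitwise-identical output.
    """
    if r > min(m, n):
        raise RankError(f"rank {r} exceeds min(m, n) = {min(m, n)}")
    if r < 1:
        raise RankError("rank must be >= 1")
    if not scale > 0:
        raise ArgumentError(f"scale must be positive, got {scale}")
    rng = np.random.default_rng(seed)
    # 1 - U[0,1) lies in (0, 1]; keeps entries strictly positive.
    W = (1.0 - rng.random((m, r))) * scale
    H = (1.0 - rng.random((r, n))) * scale
    return W, H


def _check_shapes(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1] or W.shape[1] != H.shape[0]:
        raise DimensionError(
            f"shapes do not conform: V {V.shape}, W {W.shape}, H {H.shape}"
        )


def update_frobenius(V, W, H, eps: float = EPS_DEFAULT, mask: np.ndarray | None = None):
    """One multiplicative step for the Frobenius objective (H first, then W).

    With ``mask`` (0/1 weights), held-out entries exert zero gradient:
    numerators and denominators use ``mask * V`` and ``mask * (W @ H)``.  The
    unmasked path evaluates denominators with the same association
    ``W.T @ (W @ H)`` so an all-ones mask reproduces it bitwise.
    """
    V = _as_array(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    _check_shapes(V, W, H)
    if mask is None:
        H = H * (W.T @ V) / (W.T @ (W @ H) + eps)
        W = W * (V @ H.T) / ((W @ H) @ H.T + eps)
    else:
        H = H * (W.T @ (mask * V)) / (W.T @ (mask * (W @ H)) + eps)
        W = W * ((mask * V) @ H.T) / ((mask * (W @ H)) @ H.T + eps)
    return W, H


def update_kl(V, W, H, eps: float = EPS_DEFAULT, mask: np.ndarray | None = None):
    """One multiplicative step for the KL divergence (H first, then W)."""
    V = _as_array(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    _check_shapes(V, W, H)
    if mask is None:
        H = H * (W.T @ (V / (W @ H + eps))) / (W.sum(axis=0)[:, None] + eps)
        W = W * ((V / (W @ H + eps)) @ H.T) / (H.sum(axis=1)[None, :] + eps)
    else:
        H = H * (W.T @ (mask * V / (W @ H + eps))) / (W.T @ mask + eps)
        W = W * ((mask * V / (W @ H + eps)) @ H.T) / (mask @ H.T + eps)
    return W, H


def smoothing_matrix(r: int, theta: float) -> np.ndarray:
    """Nonsmooth-NMF smoothing matrix ``S = (1 - theta) I + (theta / r) 11^T``.

    Doubly stochastic and symmetric; ``theta = 0`` is the identity (plain KL
    NMF) and ``theta = 1`` replaces every factor by the uniform mixture.
    """
    if r < 1:
        raise ArgumentError("r must be >= 1")
    if not 0.0 <= theta <= 1.0:
        raise ArgumentError(f"theta must lie in [0, 1], got {theta}")
    return (1.0 - theta) * np.eye(r) + (theta / r) * np.ones((r, r))


def frobenius_objective(V, W, H, mask: np.ndarray | None = None) -> float:
    """Residual sum of squares ``sum((V - WH)^2)``, restricted to mask if given."""
    V = _as_array(V)
    R = V - W @ H
    if mask is not None:
        R = mask * R
    return float(np.sum(R * R))


def kl_objective(V, W, H, eps: float = EPS_DEFAULT, mask: np.ndarray | None = None) -> float:
    """Generalized KL divergence ``D(V || WH)`` with the 0*log(0) = 0 convention."""
    V = _as_array(V)
    WH = W @ H + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(V > 0, V * np.log(V / WH), 0.0)
    d = t - V + WH
    if mask is not None:
        d = mask * d
    return float(np.sum(d))


def _assignments(H: np.ndarray) -> np.ndarray:
    return np.argmax(H, axis=0)


def fit(
    V: TargetMatrix | np.ndarray,
    r: int,
    spec: AlgorithmSpec = AlgorithmSpec(),
    mask: np.ndarray | None = None,
) -> Factorization:
    """Run one seeded NMF until the connectivity assignment stalls.

    Initialization is i.i.d. uniform on ``(0, sqrt(max V)]`` so that the
    initial product has the magnitude of the data and the whole trajectory is
    equivariant under rescaling of ``V`` (scaling V by ``c`` scales the fitted
    RSS by ``c**2``).  The ``rss`` field always holds the unmasked Frobenius
    residual of ``W @ H``; for ``nsnmf`` the smoothing matrix has been
    absorbed into ``W``.
    """
    if isinstance(V, np.ndarray):
        V = TargetMatrix(V)
    A = V.values
    m, n = A.shape
    if r < 1 or r > min(m, n):
        raise RankError(f"rank {r} invalid for shape {A.shape} (need 1 <= r <= {min(m, n)})")
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if mask.shape != A.shape:
            raise DimensionError(f"mask shape {mask.shape} != V shape {A.shape}")

    eps = spec.eps
    scale = float(np.sqrt(A.max()))
    W, H = init_random(m, n, r, spec.seed, scale=scale)
    S = smoothing_matrix(r, spec.theta) if spec.name == "nsnmf" else None

    def objective() -> float:
        if spec.name == "lee":
            return frobenius_objective(A, W, H, mask=mask)
        B = W @ S if S is not None else W
        return kl_objective(A, B, H, eps=eps, mask=mask)

    trace: list[float] = [objective()]
    prev_assign = _assignments(H)
    stall = 0
    converged = False
    it = 0
    for it in range(1, spec.max_iter + 1):
        if spec.name == "lee":
            W, H = update_frobenius(A, W, H, eps=eps, mask=mask)
        elif spec.name == "brunet":
            W, H = update_kl(A, W, H, eps=eps, mask=mask)
        else:  # nsnmf: smooth the basis for the H step, the coefficients for the W step
            WS = W @ S
            if mask is None:
                H = H * (WS.T @ (A / (WS @ H + eps))) / (WS.sum(axis=0)[:, None] + eps)
                SH = S @ H
                W = W * ((A / (W @ SH + eps)) @ SH.T) / (SH.sum(axis=1)[None, :] + eps)
            else:
                H = H * (WS.T @ (mask * A / (WS @ H + eps))) / (WS.T @ mask + eps)
                SH = S @ H
                W = W * ((mask * A / (W @ SH + eps)) @ SH.T) / (mask @ SH.T + eps)
        if it % spec.check_every == 0 or it == spec.max_iter:
            trace.append(objective())
            if spec.objective_tol is not None:
                prev, cur = trace[-2], trace[-1]
                if prev - cur <= spec.objective_tol * max(abs(prev), 1e-300):
                    converged = True
                    break
            else:
                assign = _assignments(H)
                if np.array_equal(assign, prev_assign):
                    stall += 1
                else:
                    stall = 0
                    prev_assign = assign
                if stall >= spec.conn_stall:
                    converged = True
                    break

    if S is not None:
        W = W @ S  # absorb smoothing so W @ H is the reconstruction
    final_rss = frobenius_objective(A, W, H)
    return Factorization(
        W=W,
        H=H,
        rank=r,
        algorithm=spec,
        n_iter=it,
        objective_trace=trace,
        rss=final_rss,
        converged=converged,
    )


def fit_restarts(
    V: TargetMatrix | np.ndarray,
    r: int,
    spec: AlgorithmSpec = AlgorithmSpec(),
    n_run: int = 10,
) -> list[Factorization]:
    """Run ``n_run`` restarts with per-restart seeds derived from ``spec.seed``.

    Restart ``k`` uses the seed ``derive_seed(spec.seed, r, k)``, so results
    are reproducible and independent of execution order.
    """
    if n_run < 1:
        raise ArgumentError("n_run must be >= 1")
    return [
        fit(V, r, replace(spec, seed=derive_seed(spec.seed, r, k))) for k in range(n_run)
    ]


def best_fit(fits: list[Factorization]) -> Factorization:
    """The restart with the smallest residual sum of squares."""
    if not fits:
        raise ArgumentError("no factorizations given")
    return min(fits, key=lambda f: f.rss)


def rss(V: TargetMatrix | np.ndarray, F: Factorization) -> float:
    """Residual sum of squares ``sum_ij (V_ij - (WH)_ij)^2``."""
    A = _as_array(V)
    if F.W.shape[0] != A.shape[0] or F.H.shape[1] != A.shape[1]:
        raise DimensionError(
            f"factorization {F.W.shape[0]}x{F.H.shape[1]} does not match V {A.shape}"
        )
    return frobenius_objective(A, F.W, F.H)
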