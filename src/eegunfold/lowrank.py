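"""Classical low-rank + sparse decomposition of windowed 1-D signals.

A noisy segment ``R`` is modeled as the sum of a clean component ``D``
whose window embedding is (approximately) low rank and a sparse artifact
``N``.  With nuclear-norm and l1 relaxations and a quadratic penalty in
place of the equality constraint, the objective is

    min_{D,N}  ||D||_* + mu * ||N||_1 + (beta/2) * ||R - D - N||_F^2

solved by alternating the exact proximal steps

    D <- SVT_{1/beta}(R - N)          (singular value thresholding)
    N <- soft_{mu/beta}(R - D)        (elementwise shrinkage)

Each step minimizes the objective exactly in its block, so the objective
is monotonically nonincreasing.  This solver is both a standalone baseline
denoiser and the numerical reference for the unfolded network's algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import hankel

from .segments import Segment1D

__all__ = [
    "WindowEmbedding",
    "LRRSolverConfig",
    "DecompositionResult",
    "embed",
    "unembed",
    "svt",
    "soft_threshold",
    "rpca_decompose",
    "surrogate_update_n",
    "classical_denoise",
]


@dataclass(frozen=True)
class WindowEmbedding:
    """How a length-L segment becomes a matrix.

    ``reshape`` stacks consecutive time windows as rows (rows*cols == L);
    ``hankel`` uses the trajectory matrix (rows + cols - 1 == L).
    """

    rows: int
    cols: int
    mode: str = "reshape"

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be positive")
        if self.mode not in ("reshape", "hankel"):
            raise ValueError(f"mode must be 'reshape' or 'hankel', got {self.mode!r}")

    def expected_length(self) -> int:
        if self.mode == "reshape":
            return self.rows * self.cols
        return self.rows + self.cols - 1

    def check(self, length: int) -> None:
        if self.expected_length() != length:
            raise ValueError(
                f"embedding {self.mode} ({self.rows}x{self.cols}) expects "
                f"length {self.expected_length()}, got {length}"
            )


@dataclass(frozen=True)
class LRRSolverConfig:
    mu: float = 0.15
    beta: float = 5.0
    max_iter: int = 500
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.beta <= 0 or self.tol <= 0:
            raise ValueError("mu, beta and tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class DecompositionResult:
    D: np.ndarray
    N: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def embed(s: Segment1D | np.ndarray, spec: WindowEmbedding) -> np.ndarray:
    v = s.samples if isinstance(s, Segment1D) else np.asarray(s, dtype=np.float64)
    spec.check(v.size)
    if spec.mode == "reshape":
        return v.reshape(spec.rows, spec.cols)
    return hankel(v[: spec.rows], v[spec.rows - 1 :])


def unembed(M: np.ndarray, spec: WindowEmbedding, fs: float = 256.0) -> Segment1D:
    M = np.asarray(M, dtype=np.float64)
    if M.shape != (spec.rows, spec.cols):
        raise ValueError(f"matrix shape {M.shape} does not match spec ({spec.rows}, {spec.cols})")
    if spec.mode == "reshape":
        return Segment1D(M.ravel(), fs=fs)
    # hankel: average over anti-diagonals i + j = const
    L = spec.rows + spec.cols - 1
    sums = np.zeros(L)
    counts = np.zeros(L)
    idx = np.add.outer(np.arange(spec.rows), np.arange(spec.cols))
    np.add.at(sums, idx.ravel(), M.ravel())
    np.add.at(counts, idx.ravel(), 1.0)
    return Segment1D(sums / counts, fs=fs)


def svt(M: np.ndarray, alpha: float) -> np.ndarray:
    """Singular value thresholding: the proximal operator of ``alpha*||.||_*``."""
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("svt input must be finite")
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    if alpha == 0.0:
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s_shrunk = np.maximum(s - alpha, 0.0)
    return (U * s_shrunk) @ Vt


def soft_threshold(v: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage: the proximal operator of ``tau*||.||_1``."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    v = np.asarray(v, dtype=np.float64)
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def _objective(R: np.ndarray, D: np.ndarray, N: np.ndarray, mu: float, beta: float) -> float:
    nuc = float(np.linalg.svd(D, compute_uv=False).sum())
    l1 = float(np.abs(N).sum())
    pen = 0.5 * beta * float(np.sum((R - D - N) ** 2))
    return nuc + mu * l1 + pen


def rpca_decompose(R: np.ndarray, config: LRRSolverConfig = LRRSolverConfig()) -> DecompositionResult:
    """Alternating proximal minimization of the penalized low-rank + sparse objective."""
    R = np.asarray(R, dtype=np.float64)
    if not np.all(np.isfinite(R)):
        raise ValueError("input matrix must be finite")
    D = np.zeros_like(R)
    N = np.zeros_like(R)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        D_new = svt(R - N, 1.0 / config.beta)
        N_new = soft_threshold(R - D_new, config.mu / config.beta)
        history.append(_objective(R, D_new, N_new, config.mu, config.beta))
        denom = max(np.linalg.norm(D) + np.linalg.norm(N), 1.0)
        delta = (np.linalg.norm(D_new - D) + np.linalg.norm(N_new - N)) / denom
        D, N = D_new, N_new
        if delta < config.tol:
            converged = True
            break
    return DecompositionResult(
        D=D, N=N, objective_history=history, iterations_run=it, converged=converged
    )


def surrogate_update_n(
    N_prev: np.ndarray,
    R_prev: np.ndarray,
    D_cur: np.ndarray,
    mu: float,
    beta: float,
    ls: float,
    grad_s: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Closed-form noise update from the Lipschitz-gradient (majorizer) surrogate.

    Replacing the sparsity prior S(N) by its quadratic Taylor majorizer
    around the previous iterate and zeroing the derivative gives

        N = delta*N_prev + (1 - delta)*(R_prev - D_cur) - rho*grad_S(N_prev)

    with ``delta = mu*ls/(mu*ls + beta)`` and ``rho = mu/(mu*ls + beta)``.
    This is the arithmetic skeleton each unfolded stage's noise estimator
    learns around.
    """
    N_prev = np.asarray(N_prev, dtype=np.float64)
    R_prev = np.asarray(R_prev, dtype=np.float64)
    D_cur = np.asarray(D_cur, dtype=np.float64)
    if not (N_prev.shape == R_prev.shape == D_cur.shape):
        raise ValueError(
            f"shape mismatch: {N_prev.shape}, {R_prev.shape}, {D_cur.shape}"
        )
    if mu <= 0 or beta <= 0 or ls <= 0:
        raise ValueError("mu, beta and ls must be positive")
    denom = mu * ls + beta
    delta = mu * ls / denom
    rho = mu / denom
    return delta * N_prev + (1.0 - delta) * (R_prev - D_cur) - rho * grad_s(N_prev)


def classical_denoise(
    y: Segment1D,
    spec: WindowEmbedding | None = None,
    config: LRRSolverConfig = LRRSolverConfig(),
) -> tuple[Segment1D, Segment1D]:
    """Denoise one segment with the iterative solver.

    Returns ``(x_hat, n_hat)`` with ``x_hat`` the low-rank reconstruction
    and ``n_hat = y - x_hat`` (the noise estimate absorbs the small penalty
    residual so that additivity holds exactly).
    """
    if spec is None:
        # default: 16 windows of 32 samples for the canonical 512-sample segment
        if len(y) % 32 == 0:
            spec = WindowEmbedding(rows=len(y) // 32, cols=32, mode="reshape")
        else:
            raise ValueError(
                f"no default embedding for length {len(y)}; pass a WindowEmbedding"
            )
    M = embed(y, spec)
    result = rpca_decompose(M, config)
    x_hat = unembed(result.D, spec, fs=y.fs)
    n_hat = y.with_samples(y.samples - x_hat.samples)
    return x_hat, n_hat
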