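"""Discrete-time LQR control of the expression dynamics.

The system is ``x(t) = A x(t-1) + u(t-1)`` with unit state and control costs
(``Q = R = I``) and identity control matrix, so the algebraic Riccati
equation specializes to::

    A' P A - P - A' P (P + I)^-1 P A + I = 0

It is solved by fixed-point iteration from ``P = I``; the optimal first
control ``u(0) = -(I + P)^-1 P A x(0)`` is the stabilizing intervention
whose sign pattern drugs are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RiccatiSolution",
    "HypoTreatment",
    "Trajectory",
    "DareConvergenceError",
    "solve_dare",
    "hypo_treatment",
    "lqr_policy",
    "zero_policy",
    "gain_policy",
    "simulate_trajectory",
]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000
DEFAULT_SIGN_TOL = 1e-12
DEFAULT_HORIZON = 500

# states beyond this norm are declared divergent; the truncated cost is +inf
_DIVERGENCE_NORM = 1e150


class DareConvergenceError(RuntimeError):
    """Riccati iteration failed to converge; carries the last residual."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"Riccati iteration did not converge in {iterations} steps "
            f"(last residual {residual:.3e})"
        )


@dataclass
class RiccatiSolution:
    """Converged Riccati matrix P with solver diagnostics."""

    P: np.ndarray
    residual: float
    iterations: int
    closed_loop_radius: float

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if not np.allclose(P, P.T, atol=1e-8):
            raise ValueError("Riccati solution is not symmetric within 1e-8")
        if np.min(np.linalg.eigvalsh(P)) <= 0:
            raise ValueError("Riccati solution is not positive definite")
        if not self.closed_loop_radius < 1:
            raise ValueError(
                f"closed-loop spectral radius {self.closed_loop_radius} >= 1"
            )
        self.P = P


@dataclass
class HypoTreatment:
    """Optimal first control u(0) for an initial condition, plus its sign pattern."""

    u0: np.ndarray
    x0: np.ndarray
    sign_pattern: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.u0) == len(self.x0) == len(self.sign_pattern)):
            raise ValueError("hypo-treatment vector lengths disagree")


@dataclass
class Trajectory:
    """Simulated states x(0..T), controls u(0..T-1) and truncated quadratic cost."""

    states: list[np.ndarray]
    controls: list[np.ndarray]
    cost: float


def _riccati_residual(A: np.ndarray, P: np.ndarray) -> float:
    n = A.shape[0]
    lhs = A.T @ P @ A - P - A.T @ P @ np.linalg.solve(P + np.eye(n), P @ A) + np.eye(n)
    return float(np.max(np.abs(lhs)))


def solve_dare(
    A: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RiccatiSolution:
    """Solve the Riccati fixed point by iteration from P = I.

    Each step applies ``P <- A'PA - A'P(P+I)^-1 PA + I`` until the max-abs
    update falls below ``tol``.  With identity control and cost matrices the
    pair is always stabilizable and observable, so a unique stabilizing
    solution exists even at spectral radius exactly 1 (the default
    normalization); non-convergence is an error, never a silent fallback.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"dynamics matrix must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("dynamics matrix contains non-finite entries")
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if radius > 1 + 1e-9:
        raise ValueError(f"spectral radius {radius} exceeds 1; normalize the model first")
    n = A.shape[0]
    eye = np.eye(n)
    P = eye.copy()
    for iteration in range(1, max_iter + 1):
        PA = P @ A
        P_next = A.T @ PA - A.T @ P @ np.linalg.solve(P + eye, PA) + eye
        P_next = (P_next + P_next.T) / 2.0
        update = float(np.max(np.abs(P_next - P)))
        P = P_next
        if update < tol:
            break
    else:
        raise DareConvergenceError(max_iter, _riccati_residual(A, P))
    closed_loop = A - np.linalg.solve(eye + P, P @ A)
    return RiccatiSolution(
        P=P,
        residual=_riccati_residual(A, P),
        iterations=iteration,
        closed_loop_radius=float(np.max(np.abs(np.linalg.eigvals(closed_loop)))),
    )


def hypo_treatment(
    P: np.ndarray,
    A: np.ndarray,
    x0: np.ndarray,
    sign_tol: float = DEFAULT_SIGN_TOL,
) -> HypoTreatment:
    """Compute u(0) = -(I + P)^-1 P A x(0) and its thresholded sign pattern."""
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n = P.shape[0]
    if A.shape != (n, n) or x0.shape != (n,):
        raise ValueError("dimension mismatch between P, A and x0")
    # I + P is positive definite for any positive semidefinite P
    assert np.min(np.linalg.eigvalsh(P)) > -1e-9, "P must be positive semidefinite"
    u0 = -np.linalg.solve(np.eye(n) + P, P @ (A @ x0))
    sign = np.where(np.abs(u0) <= sign_tol, 0.0, np.sign(u0))
    return HypoTreatment(u0=u0, x0=x0, sign_pattern=sign)


def zero_policy(x: np.ndarray) -> np.ndarray:
    """No-control policy u = 0."""
    return np.zeros_like(x)


def lqr_policy(P: np.ndarray, A: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Feedback policy u(t) = -(I + P)^-1 P A x(t)."""
    n = np.asarray(P).shape[0]
    K = np.linalg.solve(np.eye(n) + P, P @ A)

    def policy(x: np.ndarray) -> np.ndarray:
        return -K @ x

    return policy


def gain_policy(K: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Linear state-feedback policy u(t) = -K x(t)."""
    K = np.asarray(K, dtype=float)

    def policy(x: np.ndarray) -> np.ndarray:
        return -K @ x

    return policy


def simulate_trajectory(
    A: np.ndarray,
    x0: np.ndarray,
    policy: Callable[[np.ndarray], np.ndarray] | None = None,
    horizon: int = DEFAULT_HORIZON,
) -> Trajectory:
    """Iterate x(t) = A x(t-1) + u(t-1) under a policy and total the cost.

    The cost is the sum of ``x'x`` over all recorded states plus ``u'u`` over
    all controls (the infinite-horizon objective truncated at ``horizon``).
    Divergent trajectories stop early with cost +inf.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    A = np.asarray(A, dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    if policy is None:
        policy = zero_policy
    states = [x.copy()]
    controls: list[np.ndarray] = []
    cost = float(x @ x)
    for _ in range(horizon):
        u = policy(x)
        x = A @ x + u
        if float(np.linalg.norm(x)) > _DIVERGENCE_NORM:
            return Trajectory(states=states, controls=controls, cost=float("inf"))
        controls.append(u)
        states.append(x.copy())
        cost += float(x @ x) + float(u @ u)
    return Trajectory(states=states, controls=controls, cost=cost)
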