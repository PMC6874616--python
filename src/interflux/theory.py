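"""Closed-form predictions: x(t), the population flux, and timing.

First-order perturbation theory in the connector weight reduces the whole
coupled dynamics to four scalars (lam_A1, lam_B1, eps*F, x0).  The
population distribution then relaxes as

    x(t) = (K^t L + a) / (1 - K^t L a),      a = eps*F / dlam,

monotonically in t, towards the equilibrium x_eq = a, with per-step
contraction K and initial-condition constant L (see
:func:`interflux.spectral.theory_constants`).  The flux dx/dt follows by
differentiation and keeps one sign for all t: populations flow
monotonically towards the equilibrium for any fixed connector config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import OutOfRegimeError
from .spectral import TheorySummary

__all__ = ["x_of_t", "flux_of_t", "initial_projection", "InitialProjection", "time_to_reach"]


def _check_regime(ts: TheorySummary) -> None:
    if ts.K <= 0:
        raise OutOfRegimeError(
            f"K = {ts.K:.4g} <= 0: (eps*F)^2 >= lamB1*dlam, outside the "
            "first-order perturbative regime"
        )


def x_of_t(ts: TheorySummary, t):
    """Closed-form population distribution x(t) for real t >= 0.

    Exactly x0 at t = 0 (algebraic identity) and -> x_eq = eps*F/dlam as
    t -> inf.  Accepts scalars or arrays of t; t = inf is mapped to x_eq.
    """
    _check_regime(ts)
    t = np.asarray(t, dtype=float)
    Kt = np.where(np.isinf(t), 0.0, ts.K ** np.where(np.isinf(t), 0.0, t))
    num = Kt * ts.L + ts.a
    den = 1.0 - Kt * ts.L * ts.a
    if np.any(den <= 0):
        raise ValueError("denominator of x(t) crossed zero: inconsistent inputs")
    out = num / den
    return float(out) if out.ndim == 0 else out


def flux_of_t(ts: TheorySummary, t):
    """Closed-form population flux dx/dt at real t >= 0.

    ``K^t ln(K) L (1 + a^2) / (1 - K^t L a)^2``: one sign for all t
    (negative when x0 > x_eq, i.e. population flowing from the weak to the
    strong network), zero for all t iff the system starts at equilibrium.
    """
    _check_regime(ts)
    t = np.asarray(t, dtype=float)
    Kt = np.where(np.isinf(t), 0.0, ts.K ** np.where(np.isinf(t), 0.0, t))
    den = (1.0 - Kt * ts.L * ts.a) ** 2
    out = Kt * np.log(ts.K) * ts.L * (1.0 + ts.a**2) / den
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InitialProjection:
    """Projection coefficients of an initial state on the two leading modes.

    ``C_A`` and ``C_B`` satisfy C_A^2 + C_B^2 = 1 after rescaling the state
    onto the two-eigenvector manifold; x0 = C_B / C_A (inf when C_A = 0).
    """

    C_A: float
    C_B: float
    x0: float


def initial_projection(
    n0: np.ndarray, uA1_emb: np.ndarray, uB1_emb: np.ndarray
) -> InitialProjection:
    """Project an initial state on the embedded isolated leading eigenvectors.

    The projections are rescaled so C_A^2 + C_B^2 = 1, matching the
    convention in which each network starts internally at its own
    equilibrium and only the balance between the two networks varies.
    """
    n0 = np.asarray(n0, dtype=float)
    cA = float(n0 @ uA1_emb)
    cB = float(n0 @ uB1_emb)
    norm = np.hypot(cA, cB)
    if norm == 0.0:
        raise ValueError("state orthogonal to both leading eigenvectors")
    cA, cB = cA / norm, cB / norm
    x0 = np.inf if cA == 0.0 else cB / cA
    return InitialProjection(C_A=cA, C_B=cB, x0=x0)


def time_to_reach(ts: TheorySummary, x_target: float, tol: float = 0.0) -> float:
    """Smallest real t with x(t) = x_target, by inverting the closed form.

    Only targets strictly between x0 and x_eq are reachable (the relaxation
    is monotone); x_target = x0 gives 0, x_target = x_eq gives inf.
    """
    _check_regime(ts)
    if x_target == ts.x0:
        return 0.0
    if x_target == ts.x_eq:
        return np.inf
    lo, hi = sorted((ts.x0, ts.x_eq))
    if not (lo < x_target < hi):
        raise ValueError(
            f"x_target={x_target} outside the monotone range ({lo}, {hi})"
        )
    # solve K^t L = (x - a) / (1 + x a)
    v = (x_target - ts.a) / ((1.0 + x_target * ts.a) * ts.L)
    t = np.log(v) / np.log(ts.K)
    if tol > 0:
        # |x(t') - x_target| <= tol may be satisfied slightly earlier
        for t_try in (t - 1e-9, t):
            if t_try >= 0 and abs(x_of_t(ts, t_try) - x_target) <= tol:
                return float(t_try)
    return float(t)
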