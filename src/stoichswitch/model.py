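"""Nonsmooth vector field of the stoichiometric producer-grazer model.

The grazer equation carries a Liebig minimum ``min{x, p - y}``: growth is
limited by food quantity (``x``) left of the line ``x + y = p`` and by food
quality (phosphorus, ``p - y``) right of it.  The field is continuous but
only piecewise C^1; the Jacobian jumps across the branch line.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .params import StoichParams

X_LIMITED = "x_limited"
P_LIMITED = "P_limited"


class Branch(str, Enum):
    """Which side of the Liebig minimum is active."""

    x_limited = X_LIMITED
    P_limited = P_LIMITED


class NonsmoothPointError(ValueError):
    """Raised when a Jacobian is requested exactly on the branch line x+y=p."""


def mineral_branch(state, params: StoichParams) -> Branch:
    """Active branch of the Liebig minimum at ``state``.

    Ties (x + y == p) are assigned to the x-limited branch; the drift is
    continuous there so only labels and Jacobians depend on this rule.
    """
    x, y = state
    return Branch.x_limited if x + y <= params.p else Branch.P_limited


def drift(state, params: StoichParams) -> np.ndarray:
    """Deterministic vector field (dx/dt, dy/dt) in mg C/(l*day).

    F1 = b x (1 - x/K) - c x y / (a + x)
    F2 = (c e y / (a + x)) * min{x, p - y} - d y
    """
    x, y = state
    b, K, c, a = params.b, params.K, params.c, params.a
    f1 = b * x * (1.0 - x / K) - c * x * y / (a + x)
    f2 = (params.c * params.e * y / (a + x)) * min(x, params.p - y) - params.d * y
    return np.array([f1, f2])


def jacobian(state, params: StoichParams, branch: Branch | None = None) -> np.ndarray:
    """Branch-appropriate Jacobian of :func:`drift` at ``state``.

    Parameters
    ----------
    branch
        Force a branch (needed exactly on the line x+y=p, where the
        Jacobian is discontinuous).  If None, the branch is inferred from
        the state; a state on the line raises :class:`NonsmoothPointError`.
    """
    x, y = state
    b, K, c, a, e, d_, p = (params.b, params.K, params.c, params.a,
                            params.e, params.d, params.p)
    if branch is None:
        if x + y == p:
            raise NonsmoothPointError(
                f"state ({x}, {y}) lies on the branch line x+y=p; "
                "pass branch= explicitly"
            )
        branch = mineral_branch(state, params)

    ax = a + x
    j11 = b - 2.0 * b * x / K - a * c * y / ax**2
    j12 = -c * x / ax
    if branch == Branch.x_limited:
        j21 = a * c * e * y / ax**2
        j22 = c * e * x / ax - d_
    else:
        j21 = -c * e * y * (p - y) / ax**2
        j22 = c * e * (p - 2.0 * y) / ax - d_
    return np.array([[j11, j12], [j21, j22]])


def in_domain(state, params: StoichParams) -> bool:
    """True iff the state lies in the open invariant trapezoid Omega:
    0 < x < K, 0 < y < p, q*x + theta*y < P_total."""
    x, y = state
    return (
        0.0 < x < params.K
        and 0.0 < y < params.p
        and params.q * x + params.theta * y < params.P_total
    )
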