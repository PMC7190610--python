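"""Critical carrying-capacity thresholds, equilibria and bistability regimes.

The grazer nullcline inside the invariant set is a polygonal line: the
vertical segment l1 (x = x*, 0 <= y <= p - x*) joined to the slanted
segment l2 (d x + c e y = c e p - a d).  The producer nullcline is the
parabola y = (b/c)(1 - x/K)(a + x).  Interior equilibria are intersections
of the parabola with l1 (one candidate) or l2 (a quadratic: up to two).

Five critical values of K organise the dynamics:

* K1 = x*                     -- interior equilibria exist only for K > K1;
* K2 = a + 2 x*               -- the parabola's peak crosses l1 (Hopf point
                                 of the l1 equilibrium);
* K3 = x* / (1 - (c/b)(p-x*)/(a+x*))
                              -- the parabola passes through the nullcline
                                 corner (x*, p - x*); the l1 equilibrium
                                 leaves the domain above it;
* K4                          -- l2 is tangent to the parabola (birth of the
                                 l2 pair); solved from a zero-discriminant
                                 condition, not always existing;
* K5 = c e p / d - a          -- l2 leaves the domain.

For K1 < K4 < K2 < K3 < K5: K in (K4, K2) gives bistability between two
stable equilibria; K in (K2, K3) gives bistability between a stable limit
cycle (around the now-unstable l1 focus) and the stable l2 equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Branch, drift, jacobian
from .params import StoichParams, validate_params

#: classification margin: |Re lambda| below this is refused a hard label
MARGINAL_TOL = 1e-8
#: strict-inequality margin for accepting a candidate as inside Omega
OMEGA_MARGIN = 1e-12


@dataclass(frozen=True)
class CriticalKs:
    K1: float
    K2: float
    K3: float
    K4: float | None
    K5: float
    K4_exists: bool

    @property
    def ordered(self) -> bool:
        """True iff K1 < K4 < K2 < K3 < K5 (the bistability ordering)."""
        if not self.K4_exists:
            return False
        return self.K1 < self.K4 < self.K2 < self.K3 < self.K5

    def as_dict(self) -> dict:
        return {"K1": self.K1, "K2": self.K2, "K3": self.K3, "K4": self.K4,
                "K5": self.K5, "K4_exists": self.K4_exists, "ordered": self.ordered}


@dataclass(frozen=True)
class Equilibrium:
    """A located steady state with its branch label and linear stability."""

    x: float
    y: float
    branch: str                     # origin | mono_culture | l1 | l2
    eigenvalues: tuple[complex, complex]
    stability: str                  # stable | unstable | saddle | marginal

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def as_dict(self) -> dict:
        return {
            "x": self.x, "y": self.y, "branch": self.branch,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "stability": self.stability,
        }


def parabola(x, params: StoichParams):
    """Producer nullcline y = (b/c)(1 - x/K)(a + x)."""
    return (params.b / params.c) * (1.0 - x / params.K) * (params.a + x)


def _l2_y(x, params: StoichParams) -> float:
    """Grazer nullcline segment l2: y = p - d(a+x)/(c e)."""
    return params.p - params.d * (params.a + x) / (params.c * params.e)


def _l2_quadratic_coeffs(params: StoichParams, K: float | None = None):
    """Coefficients (1, -s, q0) of the l2/parabola intersection written as a
    quadratic u^2 - s u + q0 = 0 in u = a + x."""
    K = params.K if K is None else K
    s = K + params.a + params.d * K / (params.b * params.e)
    q0 = params.p * params.c * K / params.b
    return s, q0


def critical_Ks(params: StoichParams) -> CriticalKs:
    """Compute K1, K2, K3, K5 in closed form and K4 from the tangency
    (zero-discriminant) condition of the l2/parabola quadratic."""
    if params.c * params.e <= params.d:
        raise ValueError("c*e must exceed d for x* (and K1..K5) to exist")
    xs = params.x_star
    a, b, c, d, p = params.a, params.b, params.c, params.d, params.p
    K1 = xs
    K2 = a + 2.0 * xs
    K3 = xs / (1.0 - (c / b) * (p - xs) / (a + xs))
    K5 = c * params.e * p / d - a

    # Tangency: disc(K) = s(K)^2 - 4 q0(K) = 0 with s = alpha*K + a,
    # alpha = 1 + d/(b e), q0 = p c K / b  ->  quadratic in K.
    alpha = 1.0 + d / (b * params.e)
    A = alpha * alpha
    B = 2.0 * a * alpha - 4.0 * p * c / b
    C = a * a
    disc = B * B - 4.0 * A * C
    K4: float | None = None
    if disc >= 0.0:
        r = math.sqrt(disc)
        for root in sorted(((-B + r) / (2 * A), (-B - r) / (2 * A)), reverse=True):
            if root <= K1:
                continue
            u_t = (alpha * root + a) / 2.0   # double root of the quadratic
            x_t = u_t - a
            y_t = _l2_y(x_t, params)
            cand = params.with_K(root)
            ok = (
                x_t >= xs
                and 0.0 < x_t < root
                and 0.0 < y_t < p
                and cand.q * x_t + cand.theta * y_t < cand.P_total
            )
            if ok:
                K4 = root
                break
    return CriticalKs(K1=K1, K2=K2, K3=K3, K4=K4, K5=K5, K4_exists=K4 is not None)


def _classify(J: np.ndarray) -> tuple[tuple[complex, complex], str]:
    ev = np.linalg.eigvals(J)
    ev = tuple(sorted((complex(v) for v in ev), key=lambda z: (z.real, z.imag)))
    re = [v.real for v in ev]
    if any(abs(r) < MARGINAL_TOL for r in re):
        return ev, "marginal"
    if all(r < 0 for r in re):
        return ev, "stable"
    if all(abs(v.imag) < MARGINAL_TOL for v in ev) and re[0] < 0 < re[1]:
        return ev, "saddle"
    return ev, "unstable"


def classify_equilibrium(location, params: StoichParams,
                         branch_hint: Branch | None = None) -> tuple[tuple[complex, complex], str]:
    """Eigenvalues and stability label of the branch Jacobian at a steady state.

    l1 equilibria sit in the x-limited region; a state exactly on the
    branch line must come with an explicit ``branch_hint``.
    """
    J = jacobian(location, params, branch=branch_hint)
    return _classify(J)


def find_equilibria(params: StoichParams) -> list[Equilibrium]:
    """All equilibria: the origin, the grazer-free state (K, 0), and 0-3
    interior intersections of the parabola with the grazer nullcline.

    Interior candidates are accepted only strictly inside Omega (margin
    1e-12); l2 candidates additionally require x >= x*.  Sorted by x,
    boundary equilibria first.
    """
    problems = [v for v in validate_params(params) if "K <=" not in v]
    if problems:
        raise ValueError("invalid parameters: " + "; ".join(problems))

    out: list[Equilibrium] = []
    for loc, name in ([0.0, 0.0], "origin"), ([params.K, 0.0], "mono_culture"):
        ev, lab = classify_equilibrium(np.asarray(loc), params,
                                       branch_hint=Branch.x_limited)
        out.append(Equilibrium(loc[0], loc[1], name, ev, lab))

    xs = params.x_star
    interior: list[tuple[float, float, str, Branch]] = []

    # l1 candidate: x = x*, parabola height; valid while below the corner.
    y1 = parabola(xs, params)
    if OMEGA_MARGIN < y1 < params.p - xs - OMEGA_MARGIN:
        interior.append((xs, y1, "l1", Branch.x_limited))

    # l2 candidates: quadratic in u = a + x.
    s, q0 = _l2_quadratic_coeffs(params)
    disc = s * s - 4.0 * q0
    if disc > 0.0:
        r = math.sqrt(disc)
        for u in ((s - r) / 2.0, (s + r) / 2.0):
            x = u - params.a
            y = _l2_y(x, params)
            inside = (
                x >= xs - OMEGA_MARGIN
                and OMEGA_MARGIN < x < params.K - OMEGA_MARGIN
                and OMEGA_MARGIN < y < params.p - OMEGA_MARGIN
                and params.q * x + params.theta * y < params.P_total - OMEGA_MARGIN
            )
            if inside:
                interior.append((x, y, "l2", Branch.P_limited))

    for x, y, name, br in sorted(interior):
        ev, lab = classify_equilibrium(np.array([x, y]), params, branch_hint=br)
        out.append(Equilibrium(x, y, name, ev, lab))
    return out


def interior_equilibria(params: StoichParams) -> list[Equilibrium]:
    return [eq for eq in find_equilibria(params) if eq.branch in ("l1", "l2")]


def bistability_regime(params: StoichParams, check_cycle: bool = True) -> dict:
    """Classify the bistability regime from K's position among the thresholds.

    Returns a dict with keys ``regime`` (no_bistability | eq_eq | cycle_eq |
    other) and the interval bounds used.  ``eq_eq``: K in (K4, K2), two
    stable interior equilibria separated by a saddle.  ``cycle_eq``: K in
    (K2, K3) and a stable limit cycle is numerically detected around the
    unstable l1 focus (detection delegated to :mod:`stoichswitch.geometry`;
    skipped if ``check_cycle`` is False, in which case the interval alone
    decides).
    """
    ks = critical_Ks(params)
    info = {"critical_Ks": ks.as_dict(), "K": params.K}
    if not ks.ordered:
        info["regime"] = "other"
        return info
    K = params.K
    if K <= ks.K4 or K >= ks.K3:
        n_int = len(interior_equilibria(params))
        info["regime"] = "no_bistability" if n_int < 3 else "other"
        return info
    if ks.K4 < K < ks.K2:
        info["regime"] = "eq_eq"
        info["interval"] = (ks.K4, ks.K2)
        return info
    # K in (K2, K3): expect an unstable l1 focus with a surrounding cycle
    info["interval"] = (ks.K2, ks.K3)
    if not check_cycle:
        info["regime"] = "cycle_eq"
        return info
    from .geometry import find_limit_cycle  # deferred: geometry imports this module

    focus = next((eq for eq in interior_equilibria(params)
                  if eq.branch == "l1" and eq.stability == "unstable"), None)
    if focus is None:
        info["regime"] = "other"
        return info
    try:
        cyc = find_limit_cycle(params, focus)
    except RuntimeError:
        info["regime"] = "other"
        return info
    info["regime"] = "cycle_eq"
    info["cycle_period"] = cyc.period
    return info


def residuals(eq: Equilibrium, params: StoichParams) -> dict:
    """Defining-equation residuals of an interior equilibrium (diagnostics)."""
    res = {"drift": float(np.linalg.norm(drift(eq.location, params)))}
    if eq.branch == "l1":
        res["line"] = abs(eq.x - params.x_star)
    elif eq.branch == "l2":
        res["line"] = abs(params.d * eq.x + params.c * params.e * eq.y
                          - (params.c * params.e * params.p - params.a * params.d))
    if eq.branch in ("l1", "l2"):
        res["parabola"] = abs(eq.y - parabola(eq.x, params))
    return res
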