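"""Model parameters for the stoichiometric producer-grazer system.

The model tracks producer (algal) carbon ``x`` and grazer carbon ``y``
(both mg C/l) under a fixed total phosphorus pool.  Liebig's Law of the
Minimum makes grazer growth limited by either food quantity (``x``) or
food quality (phosphorus content, expressed through ``p - y`` where
``p = P_total / theta`` is total phosphorus in producer-carbon units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class StoichParams:
    """Constants of the producer-grazer model, in the units of the source data.

    Parameters
    ----------
    b : float
        Producer intrinsic growth rate (/day).
    K : float
        Producer carrying capacity (mg C/l); proxy for light intensity.
    e : float
        Maximal grazer production efficiency (dimensionless, < 1).
    d : float
        Grazer specific loss rate (/day).
    q : float
        Minimal phosphorus:carbon quota of the producer (mg P / mg C).
    theta : float
        Constant phosphorus:carbon quota of the grazer (mg P / mg C).
    c : float
        Maximal grazer ingestion rate (/day).
    a : float
        Half-saturation constant of the Holling type II response (mg C/l).
    P_total : float
        Total phosphorus in the closed system (mg P/l).
    """

    b: float
    K: float
    e: float
    d: float
    q: float
    theta: float
    c: float
    a: float
    P_total: float

    @property
    def p(self) -> float:
        """Total phosphorus expressed in producer-carbon units, P_total/theta (mg C/l)."""
        return self.P_total / self.theta

    @property
    def x_star(self) -> float:
        """Producer density where grazer net growth vanishes on the
        food-quantity-limited branch: a*d/(c*e - d) (mg C/l)."""
        return self.a * self.d / (self.c * self.e - self.d)

    @classmethod
    def from_p(cls, *, b, K, e, d, q, theta, c, a, p) -> "StoichParams":
        """Construct with the phosphorus pool given as p (mg C/l); P_total = p*theta."""
        return cls(b=b, K=K, e=e, d=d, q=q, theta=theta, c=c, a=a, P_total=p * theta)

    def with_K(self, K: float) -> "StoichParams":
        return replace(self, K=K)

    def as_dict(self) -> dict:
        return {
            "b": self.b, "K": self.K, "e": self.e, "d": self.d,
            "q": self.q, "theta": self.theta, "c": self.c, "a": self.a,
            "P_total": self.P_total, "p": self.p, "x_star": self.x_star,
        }


def validate_params(params: StoichParams) -> list[str]:
    """Check the structural assumptions of the simplified model.

    Returns a list of human-readable violations (empty list = valid):
    positivity/finiteness of every field, c*e > d, and the standing
    assumptions e < 1, q < theta, x* < p,
    K <= min{P_total/q, (theta/q) * x*}.
    """
    report: list[str] = []
    for name in ("b", "K", "e", "d", "q", "theta", "c", "a", "P_total"):
        v = getattr(params, name)
        if not math.isfinite(v):
            report.append(f"parameter {name} is not finite: {v!r}")
        elif v <= 0:
            report.append(f"parameter {name} must be positive, got {v}")
    if report:
        return report

    if params.c * params.e <= params.d:
        report.append(
            f"c*e > d violated: c*e = {params.c * params.e} <= d = {params.d} "
            "(grazer cannot persist; x* undefined)"
        )
        return report

    if not params.e < 1:
        report.append(f"e < 1 violated: e = {params.e}")
    if not params.q < params.theta:
        report.append(f"q < theta violated: q = {params.q}, theta = {params.theta}")
    if not params.x_star < params.p:
        report.append(f"x* < p violated: x* = {params.x_star}, p = {params.p}")
    k_bound = min(params.P_total / params.q, (params.theta / params.q) * params.x_star)
    if params.K > k_bound:
        report.append(
            f"K <= min(P_total/q, (theta/q)*x*) violated: K = {params.K}, "
            f"bound = {k_bound}"
        )
    return report


#: Parameter set used throughout the source study (rates per day, densities mg C/l).
BASE_PARAMS = dict(e=0.8, b=1.2, d=0.25, theta=0.04, q=0.004, c=0.8, a=0.25)

#: Bistability between two stable coexistence equilibria (K in (K4, K2)).
SECTION3 = StoichParams.from_p(**BASE_PARAMS, K=0.567, p=0.615)

#: Bistability between a stable limit cycle and a stable equilibrium (K in (K2, K3)).
SECTION4 = StoichParams.from_p(**BASE_PARAMS, K=0.574, p=0.617)
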