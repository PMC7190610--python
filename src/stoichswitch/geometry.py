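"""Phase-plane geometry: separatrix, basins of attraction, limit cycle.

In the bistable regimes the stable manifold of the interior saddle is the
separatrix between the two attraction basins.  It is grown by integrating
the flow in reversed time from two small offsets along the saddle's stable
eigenvector.  Basin membership is a signed-side test against the resulting
polyline.  The limit cycle (cycle/equilibrium regime) is located by forward
integration onto the attractor and Poincare-section return analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium
from .model import drift, jacobian
from .params import StoichParams

_IVP_OPTS = dict(method="DOP853", rtol=1e-10, atol=1e-10)

#: offset along the stable eigenvector used to seed the manifold
EIGVEC_OFFSET = 1e-7
#: distance below which a point counts as lying on the separatrix
ON_SEP_TOL = 1e-9


def integrate(params: StoichParams, z0, t_end: float, *, t_eval=None,
              dense: bool = False, reverse: bool = False, events=None):
    """Integrate the deterministic flow with a tight-tolerance adaptive solver.

    The field is continuous but has a C^1 kink on x+y=p; the step control
    of the high-order solver handles it at these tolerances.
    """
    sgn = -1.0 if reverse else 1.0

    def rhs(t, z):
        return sgn * drift(z, params)

    return solve_ivp(rhs, (0.0, t_end), np.asarray(z0, float), t_eval=t_eval,
                     dense_output=dense, events=events, **_IVP_OPTS)


@dataclass(frozen=True)
class Separatrix:
    """Stable manifold of the interior saddle as an ordered polyline."""

    points: np.ndarray              # (n, 2), ordered by arc length
    saddle: np.ndarray              # (2,)
    stable_eigenvector: np.ndarray  # (2,), unit
    box: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    def nearest(self, point) -> tuple[float, int, np.ndarray]:
        """Distance to the polyline, index of nearest segment, foot point."""
        z = np.asarray(point, float)
        p0 = self.points[:-1]
        seg = self.points[1:] - p0
        L2 = np.einsum("ij,ij->i", seg, seg)
        t = np.clip(np.einsum("ij,ij->i", z - p0, seg) / np.maximum(L2, 1e-300), 0.0, 1.0)
        feet = p0 + t[:, None] * seg
        d2 = np.einsum("ij,ij->i", z - feet, z - feet)
        i = int(np.argmin(d2))
        return float(np.sqrt(d2[i])), i, feet[i]

    def side(self, point) -> float:
        """Signed side of the oriented polyline (cross product at the nearest
        segment); 0.0 within ON_SEP_TOL of the polyline."""
        d, i, foot = self.nearest(point)
        if d < ON_SEP_TOL:
            return 0.0
        seg = self.points[i + 1] - self.points[i]
        z = np.asarray(point, float) - foot
        return float(np.sign(seg[0] * z[1] - seg[1] * z[0]))


def stable_manifold(saddle: Equilibrium, params: StoichParams,
                    arc_cap: float = 10.0, t_cap: float = 400.0) -> Separatrix:
    """Grow the separatrix by reversed-time integration from the saddle.

    Two half-branches start at saddle +/- 1e-7 * v_s (v_s the unit stable
    eigenvector) and stop on leaving the box [0, 1.5K] x [0, p] or after an
    arc-length cap; they are concatenated through the saddle.
    """
    if saddle.stability != "saddle":
        raise ValueError(f"stable_manifold needs a saddle, got {saddle.stability}")
    z_s = saddle.location
    J = jacobian(z_s, params)
    lam, vec = np.linalg.eig(J)
    i_stable = int(np.argmin(lam.real))
    if lam[i_stable].real >= 0:
        raise ValueError("no stable eigenvalue at the supplied saddle")
    v_s = np.real(vec[:, i_stable])
    v_s = v_s / np.linalg.norm(v_s)

    box = (0.0, 1.5 * params.K, 0.0, params.p)

    def outside(t, z):
        return min(z[0] - box[0], box[1] - z[0], z[1] - box[2], box[3] - z[1])
    outside.terminal = True

    halves = []
    for sign in (+1.0, -1.0):
        sol = integrate(params, z_s + sign * EIGVEC_OFFSET * v_s, t_cap,
                        reverse=True, dense=True, events=outside)
        ts = np.asarray(sol.t)
        # resample densely in time, then prune to monotone arc length
        tt = np.unique(np.concatenate([ts, np.linspace(ts[0], ts[-1], 4000)]))
        pts = sol.sol(tt).T
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        pts = pts[arc <= arc_cap]
        # drop numerically coincident consecutive points
        keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-13])
        halves.append(pts[keep])

    polyline = np.vstack([halves[0][::-1], z_s[None, :], halves[1]])
    keep = np.concatenate([[True], np.linalg.norm(np.diff(polyline, axis=0), axis=1) > 1e-13])
    return Separatrix(points=polyline[keep], saddle=z_s,
                      stable_eigenvector=v_s, box=box)


def basin_label(state, sep: Separatrix, attractors: dict[str, np.ndarray]) -> str:
    """Deterministic basin membership by the side-of-polyline test.

    ``attractors`` maps labels (e.g. ``"basin_A"``/``"basin_B"``) to the
    attractor locations; the label whose attractor shares the point's side
    is returned, or ``"on_separatrix"`` within tolerance of the polyline.
    By convention basin_A holds the smaller-x attractor.
    """
    s = sep.side(state)
    if s == 0.0:
        return "on_separatrix"
    for label, loc in attractors.items():
        if sep.side(loc) == s:
            return label
    raise ValueError("no attractor lies on the point's side of the separatrix")


@dataclass(frozen=True)
class Cycle:
    """A sampled stable limit cycle."""

    period: float
    times: np.ndarray               # (N,), in [0, T)
    samples: np.ndarray             # (N, 2)
    section_point: np.ndarray       # state on the Poincare section used
    crosses_branch_line: bool       # does the orbit cross x + y = p?

    def closure_error(self, params: StoichParams) -> float:
        sol = integrate(params, self.samples[0], self.period)
        return float(np.linalg.norm(sol.y[:, -1] - self.samples[0]))


def find_limit_cycle(params: StoichParams, near: Equilibrium, n_samples: int = 2000,
                     t_max: float = 8000.0, return_tol: float = 1e-8,
                     section_x: float | None = None) -> Cycle:
    """Locate the stable limit cycle around the unstable focus ``near``.

    Integrates forward from a small offset off the focus, collecting
    crossings of the Poincare section {x = section_x, dx/dt > 0} (default
    section through the focus).  The transient is discarded once successive
    returns differ by less than ``return_tol``; the period is the final
    return time.  Spiral-in to a stable focus (returns converging onto the
    focus itself) and failure to settle raise ``RuntimeError``.
    """
    z_f = near.location
    x_sec = z_f[0] if section_x is None else float(section_x)

    def section(t, z):
        return z[0] - x_sec
    section.direction = 1.0

    sol = solve_ivp(lambda t, z: drift(z, params), (0.0, t_max),
                    z_f + np.array([1e-3, 0.0]), events=section, **_IVP_OPTS)
    t_ev = sol.t_events[0]
    z_ev = sol.y_events[0]
    if len(t_ev) < 3:
        raise RuntimeError("no cycle found: too few section returns")

    diffs = np.linalg.norm(np.diff(z_ev, axis=0), axis=1)
    settled = np.nonzero(diffs < return_tol)[0]
    if len(settled) == 0:
        raise RuntimeError("no cycle found: returns did not settle "
                           f"(best {diffs.min():.2e} > {return_tol:.0e})")
    # the latest returns are the most converged; average the final few
    # return times to suppress residual transient drift in the period
    i = int(settled[-1]) + 1
    z0 = z_ev[i]
    n_avg = min(5, i - int(settled[0]))
    period = (t_ev[i] - t_ev[i - n_avg]) / n_avg

    # a genuine cycle has nonzero amplitude; spiral-in collapses onto the focus
    if np.linalg.norm(z0 - z_f) < 1e-4:
        raise RuntimeError("no cycle found: returns collapse onto the focus")

    ts = np.linspace(0.0, period, n_samples, endpoint=False)
    orbit = solve_ivp(lambda t, z: drift(z, params), (0.0, period), z0,
                      dense_output=True, **_IVP_OPTS)
    samples = orbit.sol(ts).T
    crosses = bool((samples.sum(axis=1) > params.p).any()
                   and (samples.sum(axis=1) <= params.p).any())
    return Cycle(period=float(period), times=ts, samples=samples,
                 section_point=z0, crosses_branch_line=crosses)


def attractor_of(params: StoichParams, z0, t_end: float = 2000.0) -> np.ndarray:
    """Forward-integrate and return the final state (oracle for basin tests)."""
    return integrate(params, z0, t_end).y[:, -1]


def rk4_ensemble(params: StoichParams, z0: np.ndarray, t_end: float,
                 h: float = 0.005) -> np.ndarray:
    """Fixed-step classical RK4 applied to a whole (n, 2) ensemble at once.

    Independent long-integration oracle for basin membership: much faster
    than per-point adaptive solves and free of any separatrix knowledge.
    """
    z = np.array(z0, float)
    p, K, b, c, a, ce, d_ = (params.p, params.K, params.b, params.c,
                             params.a, params.c * params.e, params.d)

    def f(z):
        x, y = z[:, 0], z[:, 1]
        ax = a + x
        f1 = b * x * (1 - x / K) - c * x * y / ax
        f2 = (ce * y / ax) * np.minimum(x, p - y) - d_ * y
        return np.stack([f1, f2], axis=1)

    n = int(round(t_end / h))
    for _ in range(n):
        k1 = f(z)
        k2 = f(z + 0.5 * h * k1)
        k3 = f(z + 0.5 * h * k2)
        k4 = f(z + h * k3)
        z = z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return z
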