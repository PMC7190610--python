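"""Stochastic sensitivity functions and confidence domains.

For weak multiplicative noise of intensity eps, fluctuations around a
stable hyperbolic equilibrium z_bar are asymptotically Gaussian with
covariance eps^2 W, where the stochastic sensitivity matrix W solves the
stationary Lyapunov equation

    F W + W F^T + S = 0,   S = G G^T,   G = diag(x_bar, y_bar),

with F the branch-correct Jacobian.  The confidence ellipse at fiducial
probability P is the level set

    <(z - z_bar), W^{-1} (z - z_bar)> = 2 eps^2 ln(1/(1-P)).

Around a stable limit cycle Gamma(t) the sensitivity reduces to a scalar
function mu(t) of the phase, the periodic solution of

    d(mu)/dt = a(t) mu + b(t),   mu(0) = mu(T),

with a(t) = 2 f11 p1^2 + 2 (f12 + f21) p1 p2 + 2 f22 p2^2 and
b(t) = g11^2 p1^2 + g22^2 p2^2, where p(t) is the unit normal to the
cycle.  (b uses the *squared* diffusion entries, consistent with S = GG^T;
some printed accounts drop the squares.)  The confidence band is
Gamma(t) +/- eps k sqrt(2 mu(t)) p(t) with k = erfinv(P).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfinv

from .equilibria import Equilibrium
from .geometry import Cycle, Separatrix
from .model import Branch, drift, jacobian, mineral_branch
from .params import StoichParams

LYAPUNOV_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class ConfidenceSpec:
    """Fiducial probability and noise intensity of a confidence domain."""

    P_fid: float
    eps: float

    def __post_init__(self):
        if not 0.0 < self.P_fid < 1.0:
            raise ValueError("fiducial probability must lie in (0, 1)")
        if self.eps < 0:
            raise ValueError("noise intensity must be nonnegative")


@dataclass(frozen=True)
class SensitivityMatrix:
    """Stationary stochastic sensitivity of a stable equilibrium."""

    W: np.ndarray          # (2, 2) symmetric positive definite
    equilibrium: np.ndarray
    F: np.ndarray          # branch Jacobian used
    S: np.ndarray          # diffusion matrix diag(x^2, y^2)

    @property
    def residual(self) -> float:
        return float(np.abs(self.F @ self.W + self.W @ self.F.T + self.S).max())


def lyapunov_solve_3eq(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Solve F W + W F^T + S = 0 for symmetric W via the explicit
    three-unknown linear system in (w11, w12, w22)."""
    f11, f12 = F[0]
    f21, f22 = F[1]
    A = np.array([
        [2.0 * f11, 2.0 * f12, 0.0],
        [f21, f11 + f22, f12],
        [0.0, 2.0 * f21, 2.0 * f22],
    ])
    rhs = -np.array([S[0, 0], S[0, 1], S[1, 1]])
    w11, w12, w22 = np.linalg.solve(A, rhs)
    return np.array([[w11, w12], [w12, w22]])


def equilibrium_ssf(eq: Equilibrium, params: StoichParams) -> SensitivityMatrix:
    """Sensitivity matrix W at a stable hyperbolic equilibrium.

    Uses the Jacobian of the branch actually containing the equilibrium
    (P-limited entries where x + y > p).  Rejects non-Hurwitz Jacobians.
    """
    branch = Branch.x_limited if eq.branch in ("l1", "origin", "mono_culture") \
        else mineral_branch(eq.location, params)
    F = jacobian(eq.location, params, branch=branch)
    lam = np.linalg.eigvals(F)
    if lam.real.max() >= 0:
        raise ValueError(
            "no stationary sensitivity: Jacobian is not Hurwitz "
            f"(eigenvalues {lam})")
    S = np.diag([eq.x**2, eq.y**2])
    W = lyapunov_solve_3eq(F, S)
    out = SensitivityMatrix(W=W, equilibrium=eq.location, F=F, S=S)
    if out.residual > LYAPUNOV_RESIDUAL_TOL:
        raise ArithmeticError(f"Lyapunov residual {out.residual:.2e} too large")
    return out


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Level set of the Mahalanobis form around a stable equilibrium."""

    center: np.ndarray
    Q: np.ndarray           # W^{-1}
    level: float            # 2 eps^2 ln(1/(1-P))
    boundary: np.ndarray    # (M, 2) sampled boundary points
    spec: ConfidenceSpec

    def mahalanobis2(self, points) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ni,ij,nj->n", d, self.Q, d)

    def contains(self, points) -> np.ndarray:
        return self.mahalanobis2(points) <= self.level

    @property
    def area(self) -> float:
        return float(np.pi * self.level / np.sqrt(np.linalg.det(self.Q)))


def confidence_ellipse(eq, W: np.ndarray | SensitivityMatrix,
                       spec: ConfidenceSpec, n_boundary: int = 256) -> ConfidenceEllipse:
    """Confidence ellipse at fiducial probability P and intensity eps."""
    Wm = W.W if isinstance(W, SensitivityMatrix) else np.asarray(W, float)
    center = eq.location if isinstance(eq, Equilibrium) else np.asarray(eq, float)
    if np.linalg.det(Wm) <= 0:
        raise ValueError("W must be positive definite")
    Q = np.linalg.inv(Wm)
    level = 2.0 * spec.eps**2 * np.log(1.0 / (1.0 - spec.P_fid))
    L = np.linalg.cholesky(Wm)
    phi = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    circle = np.column_stack([np.cos(phi), np.sin(phi)])
    boundary = center + np.sqrt(level) * circle @ L.T
    return ConfidenceEllipse(center=center, Q=Q, level=level,
                             boundary=boundary, spec=spec)


def _golden_min(f, lo, hi, tol=1e-10):
    g = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - g * (b - a)
    d = a + g * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def tangency_threshold(eq, W: np.ndarray | SensitivityMatrix, P_fid: float,
                       sep: Separatrix) -> float:
    """Noise intensity eps* at which the P-confidence ellipse first touches
    the separatrix.

    The squared Mahalanobis distance from the ellipse centre to the
    separatrix polyline is minimised by a vertex scan refined with
    golden-section search on the two adjacent segments;
    eps* = d_min / sqrt(2 ln(1/(1-P))).
    """
    Wm = W.W if isinstance(W, SensitivityMatrix) else np.asarray(W, float)
    center = eq.location if isinstance(eq, Equilibrium) else np.asarray(eq, float)
    Q = np.linalg.inv(Wm)
    if sep.side(center) == 0.0:
        return 0.0

    d = sep.points - center
    m2 = np.einsum("ni,ij,nj->n", d, Q, d)
    i0 = int(np.argmin(m2))

    def seg_m2(i, t):
        z = sep.points[i] + t * (sep.points[i + 1] - sep.points[i]) - center
        return z @ Q @ z

    best = m2[i0]
    for i in (i0 - 1, i0):
        if 0 <= i < len(sep.points) - 1:
            t = _golden_min(lambda t: seg_m2(i, t), 0.0, 1.0)
            best = min(best, seg_m2(i, t))
    dmin = float(np.sqrt(best))
    return dmin / np.sqrt(2.0 * np.log(1.0 / (1.0 - P_fid)))


@dataclass(frozen=True)
class CycleSSF:
    """Scalar stochastic sensitivity mu(t) along a stable limit cycle."""

    cycle: Cycle
    mu: np.ndarray          # (N,), positive
    p: np.ndarray           # (N, 2) unit normals to the cycle
    a: np.ndarray           # (N,) coefficient a(t)
    b: np.ndarray           # (N,) coefficient b(t)
    lyapunov_exponent: float   # A = integral of a over one period (< 0)
    periodicity_residual: float


def _segment_maps(a_seg: np.ndarray, b_seg: np.ndarray, dt_seg: np.ndarray):
    """Affine step maps mu -> phi*mu + psi of the exponential integrator
    for d(mu)/dt = a mu + b with coefficients frozen per segment."""
    phi = np.exp(a_seg * dt_seg)
    small = np.abs(a_seg) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(small, b_seg * dt_seg, b_seg * (phi - 1.0) / a_seg)
    return phi, psi


def periodic_scalar_solve(a_t: np.ndarray, b_t: np.ndarray, period: float,
                          segments: tuple | None = None):
    """Periodic solution of d(mu)/dt = a(t) mu + b(t) on a uniform grid.

    ``a_t``, ``b_t`` sample t_i = i * period / N, i = 0..N-1.  Each
    segment is propagated by the exponential integrator with
    endpoint-averaged coefficients (exact for constant coefficients);
    pre-split segment coefficient arrays (a_seg, b_seg, dt_seg lists per
    segment, as produced by the cycle machinery to handle coefficient
    jumps) can be supplied via ``segments``.  Returns (mu, A, residual)
    where A = int_0^period a dt (< 0 for an attracting periodic solution)
    and residual is the relative periodicity defect.
    """
    N = len(a_t)
    if segments is None:
        dt = period / N
        a_seg = 0.5 * (a_t + np.roll(a_t, -1))
        b_seg = 0.5 * (b_t + np.roll(b_t, -1))
        seg_maps = [_segment_maps(np.array([a]), np.array([b]), np.array([dt]))
                    for a, b in zip(a_seg, b_seg)]
        A = float(a_seg.sum() * dt)
    else:
        seg_maps = [_segment_maps(np.asarray(a), np.asarray(b), np.asarray(d))
                    for a, b, d in segments]
        A = float(sum((np.asarray(a) * np.asarray(d)).sum()
                      for a, _, d in segments))
    if A >= 0:
        raise ValueError(f"not orbitally stable (int a = {A:.3e} >= 0)")

    # cumulative affine map from node 0 to node i
    Phi = np.empty(N + 1)
    Psi = np.empty(N + 1)
    Phi[0], Psi[0] = 1.0, 0.0
    for i, (phi, psi) in enumerate(seg_maps):
        f, p = Phi[i], Psi[i]
        for ph, ps in zip(phi, psi):        # sub-steps within a segment
            p = ph * p + ps
            f = ph * f
        Phi[i + 1], Psi[i + 1] = f, p
    mu0 = Psi[-1] / (1.0 - Phi[-1])
    mu = Phi[:-1] * mu0 + Psi[:-1]
    mu_T = Phi[-1] * mu0 + Psi[-1]
    residual = abs(mu_T - mu0) / abs(mu0)
    return mu, A, float(residual)


def cycle_ssf(cycle: Cycle, params: StoichParams) -> CycleSSF:
    """Solve the periodic boundary problem for mu(t) along the cycle.

    Coefficients are sampled with the branch-correct Jacobian at each
    cycle point (the orbit may straddle the Liebig branch line; occupancy
    is whatever the true orbit dictates).  With I(t) = int_0^t a ds and
    A = I(T) < 0, the periodic solution is

        mu(0) = e^A C / (1 - e^A),  C = int_0^T b(s) e^{-I(s)} ds,
        mu(t) = e^{I(t)} (mu(0) + int_0^t b e^{-I}).
    """
    N = len(cycle.times)
    dt = cycle.period / N

    def coeffs(z, branch):
        f = drift(z, params)
        nrm = np.linalg.norm(f)
        if nrm == 0:
            raise ValueError("drift vanishes on the cycle sample; not a cycle")
        p1, p2 = f[1] / nrm, -f[0] / nrm
        J = jacobian(z, params, branch=branch)
        a = (2.0 * J[0, 0] * p1**2
             + 2.0 * (J[0, 1] + J[1, 0]) * p1 * p2
             + 2.0 * J[1, 1] * p2**2)
        b = (z[0] * p1)**2 + (z[1] * p2)**2
        return a, b, (p1, p2)

    branches = [mineral_branch(z, params) for z in cycle.samples]
    a_t = np.empty(N)
    b_t = np.empty(N)
    p_t = np.empty((N, 2))
    for i, z in enumerate(cycle.samples):
        a_t[i], b_t[i], p_t[i] = coeffs(z, branches[i])

    # per-segment coefficients; segments straddling the Liebig branch line
    # (where the Jacobian, hence a(t), jumps) are split at the crossing
    segments = []
    for i in range(N):
        j = (i + 1) % N
        zi, zj = cycle.samples[i], cycle.samples[j]
        if branches[i] == branches[j]:
            segments.append(([0.5 * (a_t[i] + a_t[j])],
                             [0.5 * (b_t[i] + b_t[j])], [dt]))
        else:
            si, sj = zi.sum(), zj.sum()
            lam = np.clip((params.p - si) / (sj - si), 0.0, 1.0)
            zc = zi + lam * (zj - zi)
            aL, bL, _ = coeffs(zc, branches[i])
            aR, bR, _ = coeffs(zc, branches[j])
            segments.append(([0.5 * (a_t[i] + aL), 0.5 * (aR + a_t[j])],
                             [0.5 * (b_t[i] + bL), 0.5 * (bR + b_t[j])],
                             [lam * dt, (1.0 - lam) * dt]))

    try:
        mu, A, residual = periodic_scalar_solve(a_t, b_t, cycle.period,
                                                segments=segments)
    except ValueError as exc:
        raise ValueError(f"cycle SSF rejected: {exc}") from exc
    return CycleSSF(cycle=cycle, mu=mu, p=p_t, a=a_t, b=b_t,
                    lyapunov_exponent=A, periodicity_residual=residual)


@dataclass(frozen=True)
class ConfidenceBand:
    """Tube Gamma(t) +/- eps k sqrt(2 mu(t)) p(t) around the cycle."""

    cssf: CycleSSF
    gamma1: np.ndarray      # (N, 2) outer/inner boundary polylines
    gamma2: np.ndarray
    k: float
    spec: ConfidenceSpec

    def half_width(self) -> np.ndarray:
        return self.spec.eps * self.k * np.sqrt(2.0 * self.cssf.mu)

    def contains(self, points) -> np.ndarray:
        """Membership via the normal deviation at the nearest cycle phase."""
        pts = np.atleast_2d(points)
        samples = self.cssf.cycle.samples
        d2 = ((pts[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
        i = np.argmin(d2, axis=1)
        dev = pts - samples[i]
        normal_dev = np.abs(np.einsum("ni,ni->n", dev, self.cssf.p[i]))
        return normal_dev <= self.half_width()[i]


def confidence_band(cycle: Cycle, cssf: CycleSSF, spec: ConfidenceSpec) -> ConfidenceBand:
    """Confidence band at fiducial probability P: k = erfinv(P)."""
    if (cssf.mu <= 0).any():
        raise ValueError("mu must be positive along the cycle")
    k = float(erfinv(spec.P_fid))
    offset = (spec.eps * k * np.sqrt(2.0 * cssf.mu))[:, None] * cssf.p
    return ConfidenceBand(cssf=cssf, gamma1=cycle.samples + offset,
                          gamma2=cycle.samples - offset, k=k, spec=spec)


def coverage_check(points, region) -> dict:
    """Empirical coverage of a confidence region with its binomial SE."""
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) == 0:
        raise ValueError("empty point set")
    inside = region.contains(pts)
    frac = float(inside.mean())
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / len(pts)))
    return {"coverage": frac, "n": int(len(pts)), "binomial_se": se}
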