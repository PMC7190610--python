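"""Euler-Maruyama simulation of the stochastically forced model.

Multiplicative environmental noise enters each equation proportionally to
the respective population (eps * x dB1, eps * y dB2, independent Wiener
processes).  The intensity is regime-dependent: eps1 while the pre-step
state satisfies x + y <= p (food-quantity-limited side), eps2 otherwise.
The exact solution stays strictly positive; the numerical guard (step
halving, then a clamp at 1e-12 with an audit flag) enforces the analogue
under discretisation.

This module is the study's synthetic-data generator: ensembles produced
here are the "observations" against which the stochastic-sensitivity
predictions are checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import Separatrix
from .params import StoichParams

#: floor applied when 20 halvings still leave a component nonpositive
POSITIVITY_CLAMP = 1e-12
MAX_HALVINGS = 20


@dataclass(frozen=True)
class NoiseSpec:
    """Regime-dependent noise intensities (dimensionless multiplicative)."""

    eps1: float   # intensity while x + y <= p
    eps2: float   # intensity while x + y > p

    def __post_init__(self):
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValueError("noise intensities must be nonnegative")


@dataclass(frozen=True)
class Trajectory:
    """A simulated path on a fixed time grid with per-step metadata."""

    t: np.ndarray          # (n+1,)
    states: np.ndarray     # (n+1, 2), strictly positive
    regime: np.ndarray     # (n+1,) uint8: 0 = x_limited, 1 = P_limited
    clamped: np.ndarray    # (n+1,) bool: positivity clamp fired entering state i
    seed: int
    h: float

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "x": self.x, "y": self.y,
            "regime": np.where(self.regime == 0, "x_limited", "P_limited"),
            "clamped": self.clamped.astype(int),
        })


@njit(cache=False)
def _em_kernel(x0, y0, n_steps, h, b, K, c, a, ce, d, p, eps1, eps2, seed):
    """Seeded Euler-Maruyama loop with step-halving positivity guard."""
    np.random.seed(seed)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    regime = np.zeros(n_steps + 1, dtype=np.uint8)
    clamped = np.zeros(n_steps + 1, dtype=np.bool_)
    x = x0
    y = y0
    xs[0] = x
    ys[0] = y
    regime[0] = 0 if x + y <= p else 1
    for i in range(n_steps):
        remaining = h
        dt = h
        halvings = 0
        flag = False
        while remaining > 0.0:
            if dt > remaining:
                dt = remaining
            if x + y <= p:
                eps = eps1
            else:
                eps = eps2
            ax = a + x
            f1 = b * x * (1.0 - x / K) - c * x * y / ax
            mn = x if x <= p - y else p - y
            f2 = (ce * y / ax) * mn - d * y
            sq = np.sqrt(dt)
            xn = x + f1 * dt + eps * x * sq * np.random.normal()
            yn = y + f2 * dt + eps * y * sq * np.random.normal()
            if (xn <= 0.0 or yn <= 0.0) and halvings < MAX_HALVINGS:
                dt = dt * 0.5
                halvings += 1
                continue
            if xn <= 0.0:
                xn = POSITIVITY_CLAMP
                flag = True
            if yn <= 0.0:
                yn = POSITIVITY_CLAMP
                flag = True
            x = xn
            y = yn
            remaining -= dt
        xs[i + 1] = x
        ys[i + 1] = y
        regime[i + 1] = 0 if x + y <= p else 1
        clamped[i + 1] = flag
    return xs, ys, regime, clamped


def simulate(params: StoichParams, noise: NoiseSpec, init, t_end: float,
             h: float = 1e-3, seed: int = 0) -> Trajectory:
    """Euler-Maruyama path from ``init`` over [0, t_end] with step ``h``.

    The noise intensity of each (sub)step is chosen by the regime of its
    pre-step state.  A step driving a component nonpositive is retried with
    a halved substep (fresh Gaussian increments, up to 20 halvings per grid
    step) and finally clamped at 1e-12 with the ``clamped`` flag set.
    Bit-reproducible for fixed (seed, h).
    """
    x0, y0 = float(init[0]), float(init[1])
    if x0 <= 0 or y0 <= 0:
        raise ValueError("initial state must be strictly positive")
    if h <= 0:
        raise ValueError("h must be positive")
    n_steps = int(round(t_end / h))
    xs, ys, regime, clamped = _em_kernel(
        x0, y0, n_steps, h, params.b, params.K, params.c, params.a,
        params.c * params.e, params.d, params.p, noise.eps1, noise.eps2,
        int(seed))
    t = np.arange(n_steps + 1) * h
    return Trajectory(t=t, states=np.column_stack([xs, ys]), regime=regime,
                      clamped=clamped, seed=int(seed), h=h)


def _rep_seed(seed: int, i: int) -> int:
    return (int(seed) * 1000003 + 7919 * i + 1) % (2**31 - 1)


def ensemble_sample(params: StoichParams, noise: NoiseSpec, init, n_reps: int,
                    t_end: float, burn_in: float = 0.0, h: float = 1e-3,
                    seed: int = 0, thin: float | None = None) -> np.ndarray:
    """States from ``n_reps`` independent seeded runs, post burn-in.

    With ``thin`` None only each run's final state is kept (n_reps, 2);
    otherwise states are sampled every ``thin`` time units after
    ``burn_in`` and stacked across runs.
    """
    out = []
    for i in range(n_reps):
        traj = simulate(params, noise, init, t_end, h=h, seed=_rep_seed(seed, i))
        if thin is None:
            out.append(traj.states[-1:])
        else:
            stride = max(1, int(round(thin / h)))
            start = int(round(burn_in / h))
            out.append(traj.states[start::stride])
    return np.vstack(out)


@dataclass(frozen=True)
class TransitionStats:
    """Debounced basin-hopping statistics of one trajectory."""

    hop_count: int
    residence_times: dict[str, list[float]]
    occupancy: dict[str, float]
    debounce_time: float
    labels: tuple[str, ...] = ()      # accepted (debounced) run labels, in order
    warning: str | None = None


def _debounced_runs(labels: np.ndarray, dt: float, debounce: float):
    """Merge runs shorter than the debounce into their predecessor."""
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    runs = [(labels[s], (e - s) * dt) for s, e in zip(starts, ends)]

    accepted: list[tuple] = []
    for lab, dur in runs:
        if accepted and (dur < debounce or lab == accepted[-1][0]):
            # chatter (or a return to the current basin): absorb
            accepted[-1] = (accepted[-1][0], accepted[-1][1] + dur)
        elif not accepted and dur < debounce:
            accepted.append((lab, dur))   # leading transient kept as-is
        else:
            accepted.append((lab, dur))
    # merging may have created adjacent equal labels
    merged: list[tuple] = []
    for lab, dur in accepted:
        if merged and merged[-1][0] == lab:
            merged[-1] = (lab, merged[-1][1] + dur)
        else:
            merged.append((lab, dur))
    return merged


def transition_stats(traj: Trajectory, sep: Separatrix,
                     attractors: dict[str, np.ndarray], debounce_time: float,
                     label_stride: int = 10) -> TransitionStats:
    """Count noise-induced basin hops along a trajectory.

    Every ``label_stride``-th state is labelled by its basin (side of the
    separatrix); a hop is a label change that persists at least
    ``debounce_time``.  Residence times are the durations of the accepted
    runs; occupancy fractions are computed from the debounced series.
    """
    total_time = traj.t[-1] - traj.t[0]
    if total_time < debounce_time:
        return TransitionStats(
            hop_count=0, residence_times={}, occupancy={},
            debounce_time=debounce_time,
            warning="trajectory shorter than debounce time")

    pts = traj.states[::label_stride]
    dt = traj.h * label_stride
    sides = _sides_vectorized(sep, pts)
    keys = list(attractors)
    ref = {lab: sep.side(loc) for lab, loc in attractors.items()}
    lab_arr = np.where(sides == ref[keys[0]], 0, 1).astype(np.int8)
    # points exactly on the separatrix inherit the previous label
    on_sep = sides == 0.0
    if on_sep.any():
        idx = np.nonzero(on_sep)[0]
        for i in idx:
            lab_arr[i] = lab_arr[i - 1] if i > 0 else lab_arr[~on_sep][0]

    runs = _debounced_runs(lab_arr, dt, debounce_time)
    hop_count = len(runs) - 1
    residence: dict[str, list[float]] = {k: [] for k in keys}
    occupancy = {k: 0.0 for k in keys}
    for lab_i, dur in runs:
        residence[keys[lab_i]].append(dur)
        occupancy[keys[lab_i]] += dur
    tot = sum(occupancy.values())
    occupancy = {k: v / tot for k, v in occupancy.items()}
    return TransitionStats(hop_count=hop_count, residence_times=residence,
                           occupancy=occupancy, debounce_time=debounce_time,
                           labels=tuple(keys[i] for i, _ in runs))


def _sides_vectorized(sep: Separatrix, pts: np.ndarray,
                      max_vertices: int = 1200) -> np.ndarray:
    """Signed side of the separatrix for many points at once.

    The polyline is decimated to at most ``max_vertices`` vertices and the
    nearest vertex found by a KD-tree; the side test then uses the better
    of the two segments adjacent to that vertex.  Labelling error is
    confined to a band far thinner than any debounce scale of interest.
    """
    from scipy.spatial import cKDTree

    poly = sep.points
    if len(poly) > max_vertices:
        idx = np.unique(np.linspace(0, len(poly) - 1, max_vertices).astype(int))
        poly = poly[idx]
    n_seg = len(poly) - 1
    seg = poly[1:] - poly[:-1]
    L2 = np.maximum(np.einsum("ij,ij->i", seg, seg), 1e-300)

    _, iv = cKDTree(poly).query(pts)
    best_d2 = np.full(len(pts), np.inf)
    best_cross = np.zeros(len(pts))
    for i_seg in (np.clip(iv - 1, 0, n_seg - 1), np.clip(iv, 0, n_seg - 1)):
        p0 = poly[i_seg]
        sg = seg[i_seg]
        t = np.clip(np.einsum("ni,ni->n", pts - p0, sg) / L2[i_seg], 0.0, 1.0)
        foot = p0 + t[:, None] * sg
        dz = pts - foot
        d2 = np.einsum("ni,ni->n", dz, dz)
        better = d2 < best_d2
        best_d2 = np.where(better, d2, best_d2)
        cross = sg[:, 0] * dz[:, 1] - sg[:, 1] * dz[:, 0]
        best_cross = np.where(better, cross, best_cross)
    return np.sign(best_cross)


def extinction_time(traj: Trajectory, threshold: float = 1e-3) -> float | None:
    """First time both populations are simultaneously below ``threshold``
    (the operational extinction criterion), or None if never."""
    both = (traj.x < threshold) & (traj.y < threshold)
    idx = np.nonzero(both)[0]
    return float(traj.t[idx[0]]) if len(idx) else None


def estimate_extinction_threshold(params: StoichParams, init, *, eps_lo: float = 0.01,
                                  eps_hi: float = 0.3, t_end: float = 500.0,
                                  n_reps: int = 20, h: float = 1e-3, seed: int = 0,
                                  target: float = 0.5, iters: int = 6) -> dict:
    """Bisect over eps1 for the intensity at which the Monte-Carlo extinction
    frequency (both populations < 1e-3 before t_end) crosses ``target``.

    Returns the bracket and per-endpoint frequencies; the threshold is an
    interval estimate, never a sharp number.
    """
    def freq(eps):
        n_ext = 0
        for i in range(n_reps):
            traj = simulate(params, NoiseSpec(eps, eps), init, t_end, h=h,
                            seed=_rep_seed(seed, i))
            if extinction_time(traj) is not None:
                n_ext += 1
        return n_ext / n_reps

    lo, hi = eps_lo, eps_hi
    f_lo, f_hi = freq(lo), freq(hi)
    if not (f_lo < target <= f_hi):
        warnings.warn("extinction bisection bracket does not straddle target")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if freq(mid) >= target:
            hi = mid
        else:
            lo = mid
    se = np.sqrt(target * (1 - target) / n_reps)
    return {"eps_lo": lo, "eps_hi": hi, "freq_lo": freq(lo), "freq_hi": freq(hi),
            "n_reps": n_reps, "binomial_se": float(se)}
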