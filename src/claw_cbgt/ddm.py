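"""Drift-diffusion model: simulation and maximum-likelihood fitting.

The model: evidence x(t) starts at z*a between absorbing boundaries 0 and
a, drifts at rate v (signed toward the left/upper boundary) with unit
diffusion; the response time is the first-passage time plus the
non-decision (onset) time t.  Units: a in evidence units, v in
evidence/s, t in s, z in (0, 1) as a fraction of a.

The fitter maximizes the exact first-passage-time likelihood, evaluated
with the standard truncated-series density (small-time and large-time
expansions, switching by the accuracy criterion), initialized from
moment-based closed-form estimates and refined with a derivative-free
simplex search under bound-enforcing transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

_DENSITY_TOL = 1e-7


@dataclass
class DDMParams:
    a: float   # boundary height
    v: float   # drift rate (positive toward the left/upper boundary)
    t: float   # onset (non-decision) time, s
    z: float   # starting bias, fraction of a

    def validate(self) -> None:
        if not self.a > 0:
            raise ValueError("a must be > 0")
        if not self.t >= 0:
            raise ValueError("t must be >= 0")
        if not 0 < self.z < 1:
            raise ValueError("z must be in (0, 1)")


@dataclass
class BehaviorSample:
    """Choices ('left'/'right') and response times (s)."""

    choices: np.ndarray
    rts: np.ndarray

    def __post_init__(self):
        self.choices = np.asarray(self.choices)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.choices.shape != self.rts.shape:
            raise ValueError("choices and rts must be aligned")
        if self.n < 1:
            raise ValueError("need at least one trial")

    @property
    def n(self) -> int:
        return len(self.rts)

    @property
    def p_left(self) -> float:
        return float(np.mean(self.choices == "left"))


@dataclass
class FitResult:
    params: DDMParams
    loglik: float
    converged: bool
    flags: list = field(default_factory=list)


# --------------------------------------------------------------------- #
# simulation
# --------------------------------------------------------------------- #

def simulate_ddm(params: DDMParams, n: int, seed: int, dt_sim: float = 1e-4) -> BehaviorSample:
    """Euler-Maruyama simulation of n first-passage trials.

    The left choice is absorption at the upper boundary a; RT is the
    first-passage time plus the onset time.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if dt_sim > 1e-3:
        raise ValueError("dt_sim must be <= 1 ms")
    params.validate()
    rng = np.random.default_rng(seed)
    x = np.full(n, params.z * params.a)
    alive = np.arange(n)
    rts = np.empty(n)
    hit_upper = np.empty(n, dtype=bool)
    sq = np.sqrt(dt_sim)
    step = 0
    max_steps = int(60.0 / dt_sim)  # hard cap at 60 s of diffusion
    while alive.size and step < max_steps:
        step += 1
        x[alive] += params.v * dt_sim + sq * rng.standard_normal(alive.size)
        up = x[alive] >= params.a
        dn = x[alive] <= 0.0
        done = up | dn
        if done.any():
            idx = alive[done]
            rts[idx] = step * dt_sim
            hit_upper[idx] = up[done]
            alive = alive[~done]
    if alive.size:
        rts[alive] = max_steps * dt_sim
        hit_upper[alive] = x[alive] >= params.a / 2
    choices = np.where(hit_upper, "left", "right")
    return BehaviorSample(choices=choices, rts=rts + params.t)


def absorption_probability_upper(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-12:
        return z
    return float((np.exp(-2 * v * z * a) - 1) / (np.exp(-2 * v * a) - 1))


def mean_decision_time(params: DDMParams) -> float:
    """Mean RT for the symmetric case z = 0.5 (closed form)."""
    a, v = params.a, params.v
    if abs(v) < 1e-9:
        return a**2 / 4 + params.t
    return (a / (2 * v)) * np.tanh(v * a / 2) + params.t


# --------------------------------------------------------------------- #
# first-passage-time density
# --------------------------------------------------------------------- #

def _fpt_density_standard(tau: np.ndarray, w: float) -> np.ndarray:
    """Density of first passage at the lower boundary for a = 1, v = 0,
    start fraction w, evaluated at scaled times tau.

    Chooses between the small-time and large-time series per element by
    the standard accuracy criterion at tolerance 1e-7.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    t = tau[pos]
    # required series lengths (Navarro & Fuss criterion)
    with np.errstate(divide="ignore"):
        ks = 2 + np.sqrt(-2 * t * np.log(2 * np.sqrt(2 * np.pi * t) * _DENSITY_TOL))
        ks = np.maximum(ks, np.sqrt(t) + 1)
        kl = np.sqrt(np.maximum(-2 * np.log(np.pi * t * _DENSITY_TOL) / (np.pi**2 * t), 0))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))
    use_small = ks < kl
    dens = np.empty_like(t)
    if use_small.any():
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1)
        terms = (w + 2 * k[None, :]) * np.exp(
            -((w + 2 * k[None, :]) ** 2) / (2 * ts[:, None])
        )
        dens[use_small] = terms.sum(axis=1) / np.sqrt(2 * np.pi * ts**3)
    if (~use_small).any():
        tl = t[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)
        terms = k[None, :] * np.exp(-(k[None, :] ** 2) * np.pi**2 * tl[:, None] / 2) * np.sin(
            k[None, :] * np.pi * w
        )
        dens[~use_small] = np.pi * terms.sum(axis=1)
    out[pos] = np.maximum(dens, 0.0)
    return out


def fpt_density_lower(t_dec: np.ndarray, a: float, v: float, w: float) -> np.ndarray:
    """First-passage density at the LOWER boundary at decision times t_dec
    (s), for boundary a, drift v, start fraction w, unit diffusion."""
    t_dec = np.asarray(t_dec, dtype=float)
    tau = t_dec / a**2
    f0 = _fpt_density_standard(tau, w)
    return (1 / a**2) * np.exp(-v * a * w - v**2 * t_dec / 2) * f0


def loglik(sample: BehaviorSample, params: DDMParams) -> float:
    """Joint log-likelihood of choices and RTs.

    The left choice is absorption at the upper boundary: its density is the
    lower-boundary density under the reflection v -> -v, z -> 1 - z.
    """
    t_dec = sample.rts - params.t
    if np.any(t_dec <= 0):
        return -np.inf
    left = sample.choices == "left"
    ll = 0.0
    if left.any():
        d = fpt_density_lower(t_dec[left], params.a, -params.v, 1 - params.z)
        if np.any(d <= 0):
            return -np.inf
        ll += float(np.log(d).sum())
    if (~left).any():
        d = fpt_density_lower(t_dec[~left], params.a, params.v, params.z)
        if np.any(d <= 0):
            return -np.inf
        ll += float(np.log(d).sum())
    return ll


# --------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------- #

def _moment_start(sample: BehaviorSample) -> DDMParams:
    """Closed-form moment-based starting point (EZ-style, z fixed at 0.5)."""
    p = np.clip(sample.p_left, 1e-3, 1 - 1e-3)
    if abs(p - 0.5) < 1e-3:
        p = 0.5 + np.sign(p - 0.5 + 1e-9) * 1e-3
    vrt = float(np.var(sample.rts))
    mrt = float(np.mean(sample.rts))
    y = np.log(p / (1 - p))
    arg = y * (y * p**2 - y * p + p - 0.5) / max(vrt, 1e-6)
    v = np.sign(p - 0.5) * abs(arg) ** 0.25
    v = float(np.clip(v, -8.0, 8.0))
    if abs(v) < 1e-3:
        v = 1e-3
    a = float(np.clip(y / v if abs(y / v) > 1e-2 else 1.0, 0.2, 5.0))
    ev = np.exp(-v * a)
    mdt = (a / (2 * v)) * (1 - ev) / (1 + ev)
    t0 = float(np.clip(mrt - mdt, 1e-3, np.min(sample.rts) * 0.95))
    return DDMParams(a=a, v=v, t=t0, z=0.5)


def _pack(p: DDMParams, rt_min: float) -> np.ndarray:
    eps = 1e-9
    frac_t = np.clip(p.t / rt_min, eps, 1 - eps)
    return np.array([
        np.log(p.a),
        p.v,
        np.log(frac_t / (1 - frac_t)),
        np.log(p.z / (1 - p.z)),
    ])


def _unpack(theta: np.ndarray, rt_min: float) -> DDMParams:
    sig = lambda x: 1 / (1 + np.exp(-x))
    return DDMParams(
        a=float(np.exp(np.clip(theta[0], -4, 4))),
        v=float(np.clip(theta[1], -20, 20)),
        t=float(sig(theta[2]) * rt_min),
        z=float(np.clip(sig(theta[3]), 1e-4, 1 - 1e-4)),
    )


def fit_ddm(sample: BehaviorSample, fit_z: bool = True) -> FitResult:
    """Maximum-likelihood DDM fit of one behavior sample.

    Returns the fitted parameters, the log-likelihood and a convergence
    flag; degenerate samples (all one choice) are fitted but flagged.
    """
    flags = []
    if sample.n < 50:
        flags.append("small_sample")
    p_left = sample.p_left
    if p_left in (0.0, 1.0):
        flags.append("one_choice_only")
        warnings.warn("all trials share one choice; v and z are weakly identified")
    rt_min = float(np.min(sample.rts))
    start = _moment_start(sample)

    def nll(theta: np.ndarray) -> float:
        p = _unpack(theta, rt_min)
        ll = loglik(sample, p)
        return -ll if np.isfinite(ll) else 1e12

    theta0 = _pack(start, rt_min)
    if not fit_z:
        theta0[3] = 0.0
    best = None
    for scale in (1.0, 0.5):
        res = minimize(
            nll, theta0, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6 * scale, "fatol": 1e-8,
                     "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
        theta0 = best.x
    params = _unpack(best.x, rt_min)
    converged = bool(best.success) and np.isfinite(best.fun)
    if not converged:
        flags.append("no_convergence")
    return FitResult(params=params, loglik=-float(best.fun),
                     converged=converged, flags=flags)


def sample_from_trials(trials: list, min_rt_s: float = 1e-3) -> BehaviorSample:
    """Build a BehaviorSample (seconds) from simulated trial records,
    excluding timeouts."""
    ch, rt = [], []
    for t in trials:
        if t.timed_out:
            continue
        ch.append(t.choice)
        rt.append(max(t.decision_time / 1000.0, min_rt_s))
    return BehaviorSample(choices=np.array(ch), rts=np.array(rt))
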