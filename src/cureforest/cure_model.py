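"""Improper (cure-fraction) survival model with a bounded cumulative hazard.

The population under study mixes susceptible ("immune-reactive") subjects, who
will eventually experience the event, with non-susceptible ("immune-tolerant")
subjects, who never do.  The model arises mechanistically: each subject carries
``N ~ Poisson(theta(w))`` latent competent clones; each clone has an i.i.d.
activation time with proper distribution ``F(t|w) = 1 - exp(-H0(t) e^{beta w})``
and the observed event time is the first activation.  Marginally this yields the
improper survival function

    S(t | w) = exp{ -theta(w) * (1 - exp(-H0(t) e^{beta w})) },
    theta(w) = theta0 * e^{alpha w},

whose cumulative hazard is bounded by ``theta(w)`` and whose tail defect
``S(inf | w) = exp(-theta(w)) > 0`` is the non-susceptible fraction.  ``alpha``
moves the tolerant fraction between the two groups of a binary covariate
``w in {0, 1}``; ``beta`` moves the event-time dynamics among the susceptible.

The resulting two-group hazard ratio,

    lambda(t, w=1) / lambda(t, w=0) = e^alpha e^beta exp(-H0(t) (e^beta - 1)),

is time-varying whenever ``beta != 0`` (crossing hazards), which is what makes
the plain logrank statistic lose power in this population and motivates the
two-component score splitting criterion in :mod:`cureforest.splitting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stepfun import StepFunction

__all__ = [
    "BaselineHazard",
    "CureModelParams",
    "SubjectOutcome",
    "population_survival",
    "hazard_ratio",
    "cure_fraction",
    "simulate_subject",
    "simulate_outcomes",
]


class BaselineHazard:
    """Baseline pseudo-cumulative hazard ``H0(t)``.

    Either a Weibull-type parametric family ``H0(t) = (t / scale)^shape`` (which
    increases from 0 to infinity and is invertible, as required for simulation)
    or a nondecreasing step function given as knot/value pairs.
    """

    def __init__(self, shape: float | None = None, scale: float | None = None,
                 step: StepFunction | None = None):
        if step is not None:
            if shape is not None or scale is not None:
                raise ValueError("give either (shape, scale) or step, not both")
            if not step.is_nondecreasing():
                raise ValueError("step-function baseline hazard must be nondecreasing")
            self.step = step
            self.shape = self.scale = None
        else:
            shape = 1.0 if shape is None else float(shape)
            scale = 1.0 if scale is None else float(scale)
            if shape <= 0 or scale <= 0:
                raise ValueError("Weibull shape and scale must be positive")
            self.shape, self.scale = shape, scale
            self.step = None

    @classmethod
    def weibull(cls, shape: float = 1.0, scale: float = 1.0) -> "BaselineHazard":
        return cls(shape=shape, scale=scale)

    @classmethod
    def from_steps(cls, times, values) -> "BaselineHazard":
        return cls(step=StepFunction(times, values))

    @property
    def is_parametric(self) -> bool:
        return self.step is None

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("H0 is defined on t >= 0 only")
        if self.step is not None:
            return self.step(t)
        vals = (t_arr / self.scale) ** self.shape
        return float(vals) if t_arr.ndim == 0 else vals

    def inverse(self, y):
        """Solve ``H0(t) = y`` for ``t`` (parametric families only)."""
        if self.step is not None:
            raise ValueError(
                "step-function baseline hazards are not invertible; use a "
                "parametric (Weibull) H0 for simulation"
            )
        y_arr = np.asarray(y, dtype=float)
        if np.any(y_arr < 0):
            raise ValueError("H0 inverse is defined on y >= 0 only")
        vals = self.scale * y_arr ** (1.0 / self.shape)
        return float(vals) if y_arr.ndim == 0 else vals


@dataclass
class CureModelParams:
    """Parameters of the two-group bounded-cumulative-hazard model.

    theta0 : baseline mean number of competent clones (baseline tail defect
        is ``exp(-theta0)``); must be positive.
    alpha : log-effect of the binary covariate on the tolerant fraction.
    beta : log-effect of the covariate on event-time dynamics.
    h0 : baseline pseudo-cumulative hazard.
    """

    theta0: float
    alpha: float = 0.0
    beta: float = 0.0
    h0: BaselineHazard = field(default_factory=BaselineHazard.weibull)

    def __post_init__(self):
        if not np.isfinite(self.theta0) or self.theta0 <= 0:
            raise ValueError("theta0 must be a positive finite real")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")

    def theta(self, w):
        return self.theta0 * np.exp(self.alpha * np.asarray(w, dtype=float))

    def to_config(self) -> dict:
        """Flat key-value form (writable as a plain-text config file)."""
        cfg = {"theta0": self.theta0, "alpha": self.alpha, "beta": self.beta}
        if self.h0.is_parametric:
            cfg["h0_shape"] = self.h0.shape
            cfg["h0_scale"] = self.h0.scale
        else:
            cfg["h0_times"] = ",".join(map(str, self.h0.step.x))
            cfg["h0_values"] = ",".join(map(str, self.h0.step.y))
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "CureModelParams":
        if "h0_times" in cfg:
            h0 = BaselineHazard.from_steps(
                [float(v) for v in str(cfg["h0_times"]).split(",")],
                [float(v) for v in str(cfg["h0_values"]).split(",")])
        else:
            h0 = BaselineHazard.weibull(float(cfg.get("h0_shape", 1.0)),
                                        float(cfg.get("h0_scale", 1.0)))
        return cls(theta0=float(cfg["theta0"]), alpha=float(cfg.get("alpha", 0.0)),
                   beta=float(cfg.get("beta", 0.0)), h0=h0)


@dataclass(frozen=True)
class SubjectOutcome:
    """Observed follow-up ``X = min(T, C)`` and event indicator ``delta``."""

    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("time must be nonnegative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def population_survival(params: CureModelParams, t, w):
    """Improper population survival ``S(t | w)``.

    Monotone nonincreasing in ``t`` from 1 down to the plateau
    ``exp(-theta(w)) > 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival is defined on t >= 0 only")
    h = np.asarray(params.h0(t_arr), dtype=float)
    ebw = np.exp(params.beta * np.asarray(w, dtype=float))
    surv = np.exp(-params.theta(w) * (1.0 - np.exp(-h * ebw)))
    return float(surv) if np.ndim(surv) == 0 else surv


def hazard_ratio(params: CureModelParams, t):
    """Instantaneous hazard ratio ``lambda(t, w=1) / lambda(t, w=0)``.

    Equals ``e^{alpha+beta}`` at ``t = 0`` and is constant (``e^alpha``) only
    when ``beta = 0``: the cure structure breaks proportional hazards.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("hazard ratio is defined on t >= 0 only")
    h = np.asarray(params.h0(t_arr), dtype=float)
    hr = np.exp(params.alpha + params.beta) * np.exp(-h * (np.exp(params.beta) - 1.0))
    return float(hr) if np.ndim(hr) == 0 else hr


def cure_fraction(params: CureModelParams, w):
    """Non-susceptible fraction ``S(inf | w) = exp(-theta0 e^{alpha w})``."""
    frac = np.exp(-params.theta(w))
    return float(frac) if np.ndim(frac) == 0 else frac


def simulate_outcomes(params: CureModelParams, w, censor_time, rng,
                      dropout_rate: float = 0.0, return_latent: bool = False):
    """Vectorised Poisson-clone simulation.

    For each subject: draw ``N ~ Poisson(theta(w))``; ``N = 0`` subjects are
    immune-tolerant and exit censored at the administrative horizon.  Otherwise
    the event time is the minimum of ``N`` i.i.d. clone activation times, drawn
    in closed form as ``H0^{-1}(E / (N e^{beta w}))`` with ``E ~ Exp(1)`` (the
    minimum of N hazards ``H0(t) e^{beta w}`` is a single hazard ``N H0(t)
    e^{beta w}``).  Optional independent uniform dropout on (0, horizon).

    Returns ``(times, events)`` arrays, plus the latent clone counts ``N`` when
    ``return_latent`` is set (test oracles only; never a model input).
    """
    if censor_time <= 0:
        raise ValueError("censor_time must be positive")
    if not params.h0.is_parametric:
        # triggers the informative step-function error
        params.h0.inverse(0.0)
    w_arr = np.atleast_1d(np.asarray(w, dtype=float))
    n = w_arr.size
    theta = params.theta(w_arr)
    n_clones = rng.poisson(theta)
    times = np.full(n, float(censor_time))
    events = np.zeros(n, dtype=np.int8)

    susceptible = n_clones > 0
    if np.any(susceptible):
        e = rng.exponential(size=int(susceptible.sum()))
        rate = n_clones[susceptible] * np.exp(params.beta * w_arr[susceptible])
        t_event = params.h0.inverse(e / rate)
        t_event = np.atleast_1d(np.asarray(t_event, dtype=float))
        obs = np.minimum(t_event, float(censor_time))
        times[susceptible] = obs
        events[susceptible] = (t_event <= censor_time).astype(np.int8)

    if dropout_rate > 0:
        drop = rng.random(n) < dropout_rate
        t_drop = rng.uniform(0.0, float(censor_time), size=n)
        early = drop & (t_drop < times)
        times[early] = t_drop[early]
        events[early] = 0

    if return_latent:
        return times, events, n_clones
    return times, events


def simulate_subject(params: CureModelParams, w: float, censor_time: float,
                     rng_seed) -> SubjectOutcome:
    """Simulate a single subject (thin wrapper over :func:`simulate_outcomes`)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    times, events = simulate_outcomes(params, [w], censor_time, rng)
    return SubjectOutcome(time=float(times[0]), event=int(events[0]))
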