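"""Synthetic cohorts reproducing the statistical structure of the study inputs.

Three generators:

- :func:`generate_noise_snps` - pure-noise genotype columns in Hardy-Weinberg
  equilibrium, each with a minor allele frequency drawn uniformly from
  (0.25, 0.4): the "pseudo three-genotype" variables that drown the signal in
  the benchmark design.
- :func:`generate_cure_cohort` - cohorts drawn from the Poisson B-cell-clone
  mechanism with planted covariate effects on the tolerant fraction (``alpha``)
  and the event dynamics (``beta``); the harness behind the null-calibration
  and power studies of the splitting statistic.
- :func:`generate_pbc_like` - a fixture emulating the dimensions of the
  benchmark cohort: n = 312 subjects, 17 quartile-coded/binary covariates with
  heterogeneous planted effects and roughly 60% censoring, ready to be
  augmented with noise genotypes.  The real liver-cirrhosis trial data are not
  bundled; :func:`load_pbc_file` accepts a user-supplied copy for exact
  replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cure_model import BaselineHazard, CureModelParams
from .data_model import Cohort

__all__ = ["CovariateEffect", "SignalSpec", "generate_noise_snps",
           "generate_cure_cohort", "generate_pbc_like", "load_pbc_file"]


def generate_noise_snps(n: int, p: int, maf_range=(0.25, 0.4), seed=0,
                        prefix: str = "snp"):
    """HWE genotype matrix: per column ``q ~ U(maf_range)``, genotypes i.i.d.
    with probabilities ``((1-q)^2, 2q(1-q), q^2)``.

    Returns ``(frame, kinds, mafs)``.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = rng.uniform(lo, hi, size=p)
    u = rng.random((n, p))
    p0 = (1.0 - q) ** 2
    p01 = p0 + 2.0 * q * (1.0 - q)
    geno = (u >= p0[None, :]).astype(np.int8) + (u >= p01[None, :]).astype(np.int8)
    width = len(str(p))
    names = [f"{prefix}{i:0{width}d}" for i in range(p)]
    frame = pd.DataFrame(geno, columns=names)
    kinds = {name: "genotype012" for name in names}
    return frame, kinds, q


@dataclass
class CovariateEffect:
    """One generated covariate and its planted effects.

    ``alpha`` acts on the log mean clone count (tolerant fraction), ``beta`` on
    the log event-time scale among susceptibles.  Covariates enter the linear
    predictors centred, so ``theta0`` keeps its meaning as the cohort-average
    baseline.  ``freq`` is the success probability (binary) or minor allele
    frequency (genotype012); ``n_levels`` the number of quartile-style levels
    for ``continuous``/``categorical``/``ordered3`` covariates.
    """

    name: str
    kind: str = "binary"
    alpha: float = 0.0
    beta: float = 0.0
    freq: float = 0.5
    n_levels: int = 4


@dataclass
class SignalSpec:
    covariates: list[CovariateEffect] = field(default_factory=list)
    theta0: float = 0.7
    baseline_shape: float = 1.0
    baseline_scale: float = 1.0
    censor_horizon: float = 3.0
    dropout_rate: float = 0.0


def _draw_covariate(cov: CovariateEffect, n: int, rng) -> np.ndarray:
    if cov.kind == "binary":
        return (rng.random(n) < cov.freq).astype(float)
    if cov.kind == "genotype012":
        q = cov.freq
        u = rng.random(n)
        p0 = (1.0 - q) ** 2
        p01 = p0 + 2.0 * q * (1.0 - q)
        return ((u >= p0).astype(float) + (u >= p01).astype(float))
    if cov.kind in ("continuous", "categorical", "ordered3"):
        k = 3 if cov.kind == "ordered3" else cov.n_levels
        return rng.integers(0, k, size=n).astype(float)
    raise ValueError(f"unknown covariate kind {cov.kind!r}")


def generate_cure_cohort(n: int, spec: SignalSpec, seed=0,
                         return_latent: bool = False):
    """Cohort from the Poisson-clone mechanism with planted effects.

    Per subject: ``theta_i = theta0 exp(sum_k alpha_k (x_ik - mean_k))``,
    clone count ``N_i ~ Poisson(theta_i)``; susceptible subjects fail at
    ``H0^{-1}(E_i / (N_i exp(sum_k beta_k (x_ik - mean_k))))`` with
    ``E_i ~ Exp(1)``; administrative censoring at the horizon, plus optional
    uniform dropout.  With ``return_latent`` the latent clone counts are
    returned alongside (test oracles only).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h0 = BaselineHazard.weibull(spec.baseline_shape, spec.baseline_scale)

    cols, kinds = {}, {}
    eta_alpha = np.zeros(n)
    eta_beta = np.zeros(n)
    for cov in spec.covariates:
        x = _draw_covariate(cov, n, rng)
        cols[cov.name] = x
        kinds[cov.name] = cov.kind
        xc = x - x.mean()
        eta_alpha += cov.alpha * xc
        eta_beta += cov.beta * xc

    theta = spec.theta0 * np.exp(eta_alpha)
    n_clones = rng.poisson(theta)
    times = np.full(n, float(spec.censor_horizon))
    events = np.zeros(n, dtype=np.int8)
    susceptible = n_clones > 0
    if np.any(susceptible):
        e = rng.exponential(size=int(susceptible.sum()))
        rate = n_clones[susceptible] * np.exp(eta_beta[susceptible])
        t_event = np.atleast_1d(h0.inverse(e / rate))
        times[susceptible] = np.minimum(t_event, spec.censor_horizon)
        events[susceptible] = (t_event <= spec.censor_horizon).astype(np.int8)
    if spec.dropout_rate > 0:
        drop = rng.random(n) < spec.dropout_rate
        t_drop = rng.uniform(0.0, spec.censor_horizon, size=n)
        early = drop & (t_drop < times)
        times[early] = t_drop[early]
        events[early] = 0

    cohort = Cohort(time=times, event=events,
                    data=pd.DataFrame(cols, index=range(n)), kinds=kinds)
    if return_latent:
        return cohort, n_clones
    return cohort


# The 17-covariate fixture: names echo the classic liver-trial variables; the
# effect pattern (a handful of strong predictors, several null ones) mirrors
# what makes that benchmark informative.  Quartile-coded covariates take values
# 0..3 and are declared "continuous" so the split search uses the quartile-cut
# thresholds 0.5/1.5/2.5.
_PBC_LIKE_COVARIATES = [
    CovariateEffect("bilirubin_q", "continuous", alpha=0.85, beta=0.45),
    CovariateEffect("albumin_q", "continuous", alpha=-0.55, beta=-0.30),
    CovariateEffect("edema", "binary", alpha=0.90, beta=0.50, freq=0.15),
    CovariateEffect("prothrombin_q", "continuous", alpha=0.50, beta=0.30),
    CovariateEffect("age_q", "continuous", alpha=0.35, beta=0.20),
    CovariateEffect("stage_q", "continuous", alpha=0.40, beta=0.20),
    CovariateEffect("copper_q", "continuous", alpha=0.35, beta=0.10),
    CovariateEffect("ascites", "binary", alpha=0.60, beta=0.30, freq=0.08),
    CovariateEffect("hepatomegaly", "binary", alpha=0.25, beta=0.0, freq=0.5),
    CovariateEffect("sex", "binary", freq=0.88),
    CovariateEffect("spiders", "binary", freq=0.29),
    CovariateEffect("treatment_arm", "binary", freq=0.49),
    CovariateEffect("alkphos_q", "continuous"),
    CovariateEffect("ast_q", "continuous"),
    CovariateEffect("cholesterol_q", "continuous"),
    CovariateEffect("triglycerides_q", "continuous"),
    CovariateEffect("platelet_q", "continuous"),
]


def generate_pbc_like(n: int = 312, seed=0, n_noise: int = 0,
                      maf_range=(0.25, 0.4)) -> Cohort:
    """Benchmark fixture: 17 covariates, ~60% censoring, optional noise SNPs.

    ``n_noise`` appends that many HWE noise genotype columns drawn with an
    independent stream derived from the same seed, emulating the
    signal-drowned-in-genotypes design.
    """
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    rng_cohort, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    spec = SignalSpec(covariates=list(_PBC_LIKE_COVARIATES), theta0=0.55,
                      baseline_shape=1.2, baseline_scale=1.5,
                      censor_horizon=3.0, dropout_rate=0.10)
    cohort = generate_cure_cohort(n, spec, seed=rng_cohort)
    if n_noise > 0:
        frame, kinds, _ = generate_noise_snps(n, n_noise, maf_range=maf_range,
                                              seed=rng_noise)
        cohort = cohort.add_variables(frame, kinds)
    return cohort


def load_pbc_file(path, time_col: str = "days", event_col: str = "status",
                  n_subjects: int | None = 312) -> Cohort:
    """Load a user-supplied liver-trial CSV for exact benchmark replication.

    Continuous columns are quartile-coded (0..3); columns with at most three
    distinct observed values load as binary/ordered.  Only the first
    ``n_subjects`` rows (the randomised-trial participants) are kept.
    """
    df = pd.read_csv(path)
    if n_subjects is not None:
        df = df.iloc[:n_subjects]
    time = df[time_col].to_numpy(dtype=float)
    event = (df[event_col].to_numpy(dtype=float) > 0).astype(int)
    data, kinds = {}, {}
    for col in df.columns:
        if col in (time_col, event_col):
            continue
        x = pd.to_numeric(df[col], errors="coerce")
        vals = x.dropna().unique()
        if len(vals) <= 2:
            lo = np.nanmin(vals) if len(vals) else 0.0
            data[col] = (x > lo).astype(float).where(~x.isna())
            kinds[col] = "binary"
        elif len(vals) <= 4:
            data[col] = x.astype(float)
            kinds[col] = "continuous"
        else:
            ranks = x.rank(pct=True)
            data[col] = np.ceil(ranks * 4).clip(1, 4) - 1
            kinds[col] = "continuous"
    return Cohort(time=time, event=event, data=pd.DataFrame(data), kinds=kinds)
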