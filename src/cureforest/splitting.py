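"""Node-splitting machinery for cure-model survival trees.

The splitting criterion is the 2-degree-of-freedom score statistic of the
bounded-cumulative-hazard model of :mod:`cureforest.cure_model`, evaluated at
the null of no group difference (``alpha = beta = 0``) with the baseline
profiled out by Nelson-Aalen plug-ins.  In counting-process form, over the
distinct event times ``t_j`` of a node (``d_j`` events among ``Y_j`` at risk,
``d_1j`` / ``Y_1j`` in group 1):

    U_alpha = sum_j (d_1j - Y_1j d_j / Y_j)                  (logrank numerator)
    U_beta  = sum_j (1 - Hhat0(t_j)) (d_1j - Y_1j d_j / Y_j)
    V_kl    = sum_j w_k(t_j) w_l(t_j) v_j,   w_alpha = 1, w_beta = 1 - Hhat0
    v_j     = d_j (Y_1j/Y_j)(1 - Y_1j/Y_j)(Y_j - d_j)/(Y_j - 1)

    statistic = U' V^- U   (generalised inverse; df = rank(V))

``Hhat0`` is the plug-in baseline, ``Hhat0(t) = -log(1 - min(NAhat(t)/theta0hat,
1 - eps))`` with ``theta0hat`` the terminal Nelson-Aalen value.  The alpha
component is exactly the logrank numerator (sensitive to a difference in cure
fractions); the beta component reweights it by ``1 - Hhat0(t)``, which changes
sign over time and targets the crossing-hazard pattern a dynamics-only effect
produces.  A classical 1-df logrank mode is provided for the comparison arms.

All candidate statistics at a node are evaluated in one vectorised pass over a
membership matrix, which is what makes forests over thousands of genotype
columns tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stepfun import StepFunction

__all__ = [
    "NullEstimates",
    "SplitCandidate",
    "ScoreResult",
    "nelson_aalen",
    "null_estimates",
    "score_split_statistic",
    "logrank_statistic",
    "enumerate_candidates",
    "best_split",
]

DEFAULT_EPSILON = 1e-6
RANK_TOL = 1e-10

# tie-break order among rule types at identical (variable, threshold)
_RULE_ORDER = {"gt": 0, "eq": 1}


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard ``sum_{t_j <= t} d_j / Y_j``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("nelson_aalen requires at least one subject")
    t_ev, d, y = _risk_table(times, events)
    return StepFunction(t_ev, np.cumsum(d / y))


@dataclass
class NullEstimates:
    """Plug-in baseline quantities of a node under the null.

    ``theta0_hat`` is the terminal Nelson-Aalen value (the estimated bound on
    the cumulative hazard, i.e. the mean clone count); ``h0_hat`` inverts the
    model identity ``Lambda(t) = theta0 (1 - e^{-H0(t)})`` with a clamp at
    ``1 - epsilon`` so that ``Hhat0`` stays finite at the last event time.
    """

    event_times: np.ndarray
    na_cumhaz: StepFunction
    theta0_hat: float
    h0_hat: StepFunction
    epsilon: float = DEFAULT_EPSILON


def null_estimates(times, events, epsilon: float = DEFAULT_EPSILON) -> NullEstimates:
    if epsilon <= 0 or epsilon >= 1:
        raise ValueError("epsilon must lie in (0, 1)")
    na = nelson_aalen(times, events)
    if na.x.size == 0:
        raise ValueError("node has no events: homogeneous, cannot be split")
    theta0_hat = na.terminal_value
    ratio = np.minimum(na.y / theta0_hat, 1.0 - epsilon)
    h0 = -np.log1p(-ratio)
    return NullEstimates(
        event_times=na.x.copy(),
        na_cumhaz=na,
        theta0_hat=theta0_hat,
        h0_hat=StepFunction(na.x, h0),
        epsilon=epsilon,
    )


@dataclass
class ScoreResult:
    u: np.ndarray            # (U_alpha, U_beta)
    v: np.ndarray            # 2x2 covariance
    statistic: float
    df_used: int


def _risk_table(times, events, membership=None):
    """Distinct event times with event/at-risk counts (and group-1 counts).

    Returns ``(t_ev, d, y)`` and additionally ``(d1, y1)`` of shape ``(J, C)``
    when a membership matrix ``(n, C)`` is given.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    n = times.size
    order = np.argsort(times, kind="stable")
    ts = times[order]
    es = events[order]
    first = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    d_all = np.add.reduceat(es, first)
    has_event = d_all > 0
    t_ev = ts[first][has_event]
    d = d_all[has_event]
    y = (n - first.astype(float))[has_event]
    if membership is None:
        return t_ev, d, y
    M = np.asarray(membership, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    Ms = M[order]
    d1 = np.add.reduceat(Ms * es[:, None], first, axis=0)[has_event]
    csum = np.cumsum(Ms, axis=0)
    tot = csum[-1]
    before = np.vstack([np.zeros((1, Ms.shape[1])), csum[first[1:] - 1]]) if first.size > 1 \
        else np.zeros((1, Ms.shape[1]))
    y1 = (tot[None, :] - before)[has_event]
    return t_ev, d, y, d1, y1


def _component_sums(times, events, M, beta_weight_fn):
    """Per-candidate score components and hypergeometric covariance entries."""
    t_ev, d, y, d1, y1 = _risk_table(times, events, M)
    if t_ev.size == 0:
        raise ValueError("no events in node")
    resid = d1 - y1 * (d / y)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        vj = d * (y - d) / np.maximum(y - 1.0, 1.0)
    vj = np.where(y > 1, vj, 0.0)
    p1 = y1 / y[:, None]
    vmat = vj[:, None] * p1 * (1.0 - p1)
    wb = beta_weight_fn(t_ev)
    u_a = resid.sum(axis=0)
    u_b = (wb[:, None] * resid).sum(axis=0)
    v11 = vmat.sum(axis=0)
    v12 = (wb[:, None] * vmat).sum(axis=0)
    v22 = ((wb ** 2)[:, None] * vmat).sum(axis=0)
    return u_a, u_b, v11, v12, v22


def _quadform_geninv(u1, u2, v11, v12, v22):
    """``U' V^- U`` and rank for batches of symmetric 2x2 matrices."""
    tr = v11 + v22
    det = v11 * v22 - v12 ** 2
    disc = np.sqrt(np.clip(tr ** 2 - 4.0 * det, 0.0, None))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    tol = RANK_TOL * np.maximum(lam1, 0.0)
    rank2 = lam2 > tol
    rank1 = (~rank2) & (lam1 > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat2 = (u1 ** 2 * v22 - 2.0 * u1 * u2 * v12 + u2 ** 2 * v11) / det
    # principal eigenvector of V; pick the better-conditioned representation
    qa1, qa2 = v12, lam1 - v11
    qb1, qb2 = lam1 - v22, v12
    use_a = qa1 ** 2 + qa2 ** 2 >= qb1 ** 2 + qb2 ** 2
    q1 = np.where(use_a, qa1, qb1)
    q2 = np.where(use_a, qa2, qb2)
    qn = q1 ** 2 + q2 ** 2
    # degenerate direction (V proportional to identity cannot be rank 1)
    qn = np.where(qn > 0, qn, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat1 = (q1 * u1 + q2 * u2) ** 2 / (lam1 * qn)
    stat = np.where(rank2, stat2, np.where(rank1, stat1, 0.0))
    stat = np.where(np.isfinite(stat) & (stat > 0), stat, 0.0)
    df = rank2.astype(int) * 2 + rank1.astype(int)
    return stat, df


def _check_two_sided(membership):
    m = np.asarray(membership, dtype=float)
    n1 = m.sum()
    if n1 == 0 or n1 == m.size:
        raise ValueError("membership must define two nonempty groups")
    return m


def score_split_statistic(times, events, membership, null_est: NullEstimates,
                          variance: str = "hypergeometric",
                          n_permutations: int = 500, rng=None) -> ScoreResult:
    """2-df score statistic for a single binary split.

    ``variance='permutation'`` replaces the hypergeometric covariance by the
    empirical covariance of ``U`` under within-node label permutation.
    """
    m = _check_two_sided(membership)
    wfun = lambda t: 1.0 - null_est.h0_hat(t)
    u_a, u_b, v11, v12, v22 = _component_sums(times, events, m, wfun)
    u = np.array([u_a[0], u_b[0]])
    if variance == "permutation":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        perms = np.empty((int(n_permutations), m.size))
        for k in range(int(n_permutations)):
            perms[k] = rng.permutation(m)
        pa, pb, *_ = _component_sums(times, events, perms.T, wfun)
        upx = np.vstack([pa, pb])
        vmat = np.cov(upx)
        v11p, v12p, v22p = vmat[0, 0], vmat[0, 1], vmat[1, 1]
        stat, df = _quadform_geninv(
            np.array([u[0]]), np.array([u[1]]),
            np.array([v11p]), np.array([v12p]), np.array([v22p]))
        v = np.array([[v11p, v12p], [v12p, v22p]])
    elif variance == "hypergeometric":
        stat, df = _quadform_geninv(u_a, u_b, v11, v12, v22)
        v = np.array([[v11[0], v12[0]], [v12[0], v22[0]]])
    else:
        raise ValueError(f"unknown variance method {variance!r}")
    return ScoreResult(u=u, v=v, statistic=float(stat[0]), df_used=int(df[0]))


def logrank_statistic(times, events, membership) -> float:
    """Classical 1-df logrank chi-square ``U_alpha^2 / V_alpha_alpha``."""
    m = _check_two_sided(membership)
    u_a, _, v11, _, _ = _component_sums(times, events, m, lambda t: np.zeros_like(t))
    if v11[0] <= 0:
        return 0.0
    return float(u_a[0] ** 2 / v11[0])


@dataclass(frozen=True)
class SplitCandidate:
    """A deterministic binary rule on one variable.

    ``rule='gt'`` sends subjects with ``x > threshold`` to group 1 (ordered and
    continuous variables); ``rule='eq'`` sends subjects with ``x == threshold``
    to group 1 (one-vs-rest on a categorical level or an ordered-variable
    dummy).
    """

    var: int
    rule: str
    threshold: float

    def membership(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.rule == "gt":
            return (x > self.threshold).astype(np.int8)
        if self.rule == "eq":
            return (x == self.threshold).astype(np.int8)
        raise ValueError(f"unknown rule {self.rule!r}")

    def sort_key(self):
        return (self.var, self.threshold, _RULE_ORDER[self.rule])


def _candidates_for_column(x, kind, var, quartile_mode=False, ordered3_dummies=False):
    cands = []
    if kind == "genotype012":
        cands.append(SplitCandidate(var, "gt", 0.5))   # dominant: {0} vs {1,2}
        cands.append(SplitCandidate(var, "gt", 1.5))   # recessive: {0,1} vs {2}
    elif kind == "binary":
        vals = np.unique(x)
        if vals.size == 2:
            cands.append(SplitCandidate(var, "gt", float(vals[:2].mean())))
    elif kind == "ordered3":
        cands.append(SplitCandidate(var, "gt", 0.5))
        cands.append(SplitCandidate(var, "gt", 1.5))
        if ordered3_dummies:
            for lvl in np.unique(x):
                cands.append(SplitCandidate(var, "eq", float(lvl)))
    elif kind == "categorical":
        for lvl in np.unique(x):
            cands.append(SplitCandidate(var, "eq", float(lvl)))
    elif kind == "continuous":
        vals = np.unique(x)
        if vals.size >= 2:
            if quartile_mode:
                qs = np.quantile(x, [0.25, 0.5, 0.75])
                thr = np.unique([
                    0.5 * (vals[vals <= q][-1] + vals[vals > q][0])
                    for q in qs if vals[0] <= q < vals[-1] and (vals > q).any()
                ])
            else:
                thr = 0.5 * (vals[:-1] + vals[1:])
            cands.extend(SplitCandidate(var, "gt", float(t)) for t in thr)
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    return cands


def enumerate_candidates(X, kinds, feature_ids=None, min_node_size: int = 1,
                         unique_mask=None, quartile_mode: bool = False,
                         ordered3_dummies: bool = False) -> list[SplitCandidate]:
    """All admissible binary split candidates at a node.

    ``X`` is the node's (possibly bootstrap-duplicated) feature matrix;
    ``unique_mask`` marks one row per distinct subject, so that admissibility
    ("both children keep at least ``min_node_size`` unique cases") is judged on
    distinct subjects as the node-size rule requires.  Genotype columns get the
    two genetic partitions (dominant ``{0} vs {1,2}``, recessive ``{0,1} vs
    {2}``); 3-level ordered variables get both thresholds plus optional
    one-vs-rest dummies; unordered categoricals one-vs-rest per level;
    continuous variables every midpoint between consecutive distinct observed
    values, or quartile cuts when ``quartile_mode`` is set.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if feature_ids is None:
        feature_ids = np.arange(m)
    if unique_mask is None:
        unique_mask = np.ones(n, dtype=bool)
    Xu = X[unique_mask]
    n_unique = Xu.shape[0]

    cands: list[SplitCandidate] = []
    for var in sorted(int(v) for v in feature_ids):
        cands.extend(_candidates_for_column(
            X[:, var], kinds[var], var,
            quartile_mode=quartile_mode, ordered3_dummies=ordered3_dummies))
    if not cands:
        return []
    cands.sort(key=SplitCandidate.sort_key)

    keep: list[SplitCandidate] = []
    for start in range(0, len(cands), 2048):
        chunk = cands[start:start + 2048]
        cols = np.array([c.var for c in chunk])
        thr = np.array([c.threshold for c in chunk])
        is_eq = np.array([c.rule == "eq" for c in chunk])
        Xg = Xu[:, cols]
        Mu = np.where(is_eq[None, :], Xg == thr[None, :], Xg > thr[None, :])
        n1 = Mu.sum(axis=0)
        ok = (n1 >= min_node_size) & (n_unique - n1 >= min_node_size)
        keep.extend(c for c, k in zip(chunk, ok) if k)
    return keep


def best_split(times, events, X, kinds, feature_ids=None, criterion: str = "score",
               min_node_size: int = 1, unique_mask=None, quartile_mode: bool = False,
               ordered3_dummies: bool = False, epsilon: float = DEFAULT_EPSILON):
    """Maximise the splitting criterion over all admissible candidates.

    Returns ``(SplitCandidate, statistic_value)`` or ``None`` when the node has
    no events or no admissible candidate.  Ties are broken deterministically:
    lowest variable id, then lowest threshold, then rule order.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not np.any(events == 1):
        return None
    cands = enumerate_candidates(
        X, kinds, feature_ids=feature_ids, min_node_size=min_node_size,
        unique_mask=unique_mask, quartile_mode=quartile_mode,
        ordered3_dummies=ordered3_dummies)
    if not cands:
        return None

    if criterion == "score":
        ne = null_estimates(times, events, epsilon=epsilon)
        wfun = lambda t: 1.0 - ne.h0_hat(t)
    elif criterion == "logrank":
        wfun = lambda t: np.zeros_like(t)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    X = np.asarray(X, dtype=float)
    best_stat = -np.inf
    best_cand = None
    for start in range(0, len(cands), 2048):
        chunk = cands[start:start + 2048]
        cols = np.array([c.var for c in chunk])
        thr = np.array([c.threshold for c in chunk])
        is_eq = np.array([c.rule == "eq" for c in chunk])
        Xg = X[:, cols]
        M = np.where(is_eq[None, :], Xg == thr[None, :], Xg > thr[None, :]).astype(float)
        u_a, u_b, v11, v12, v22 = _component_sums(times, events, M, wfun)
        if criterion == "score":
            stat, _ = _quadform_geninv(u_a, u_b, v11, v12, v22)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = np.where(v11 > 0, u_a ** 2 / v11, 0.0)
        k = int(np.argmax(stat))
        if stat[k] > best_stat:
            best_stat = float(stat[k])
            best_cand = chunk[k]
    if best_cand is None:
        return None
    return best_cand, best_stat
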