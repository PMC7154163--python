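"""Predictive-accuracy evaluation: Harrell's concordance index.

The C-index is the probability that, in a randomly chosen permissible pair,
the subject who fails first carries the higher predicted risk; the reported
error rate is ``1 - C``.  Permissible pairs follow the standard Harrell
convention for censored data: ``(i, j)`` with ``X_i < X_j`` and ``delta_i = 1``
(the earlier time is a genuine failure), or ``X_i = X_j`` with exactly one
event (the event-bearer fails first).  Pairs tied on time with both events are
not permissible; risk ties are credited 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Cohort
from .forest import SurvivalForest, oob_predict

__all__ = ["ConcordanceResult", "concordance_index", "oob_error"]


@dataclass
class ConcordanceResult:
    c_index: float
    n_permissible: int
    n_concordant: int
    n_discordant: int
    n_tied_risk: int
    n_excluded: int = 0

    @property
    def error_rate(self) -> float:
        return 1.0 - self.c_index

    def as_dict(self) -> dict:
        return {"c_index": self.c_index, "error_rate": self.error_rate,
                "n_permissible": self.n_permissible,
                "n_concordant": self.n_concordant,
                "n_discordant": self.n_discordant,
                "n_tied_risk": self.n_tied_risk,
                "n_excluded": self.n_excluded}


def concordance_index(times, events, risk_scores) -> ConcordanceResult:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    risks = np.asarray(risk_scores, dtype=float)
    if not (times.size == events.size == risks.size):
        raise ValueError("times, events and risk_scores must have equal length")

    ti, tj = times[:, None], times[None, :]
    di, dj = events[:, None], events[None, :]
    ri, rj = risks[:, None], risks[None, :]
    # ordered pairs (i, j) in which i demonstrably fails first
    permissible = ((ti < tj) & (di == 1)) | ((ti == tj) & (di == 1) & (dj == 0))
    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs (e.g. all subjects censored)")
    conc = int((permissible & (ri > rj)).sum())
    tied = int((permissible & (ri == rj)).sum())
    disc = n_perm - conc - tied
    c = (conc + 0.5 * tied) / n_perm
    return ConcordanceResult(c_index=float(c), n_permissible=n_perm,
                             n_concordant=conc, n_discordant=disc,
                             n_tied_risk=tied)


def oob_error(forest: SurvivalForest, cohort: Cohort) -> ConcordanceResult:
    """Out-of-bag error rate ``1 - C`` using ensemble-mortality risk scores.

    Subjects with no out-of-bag tree are excluded (their count is reported in
    ``n_excluded``).
    """
    pred = oob_predict(forest, cohort)
    mask = pred.available
    if not np.any(mask):
        raise ValueError("no subject has an out-of-bag prediction")
    risks = pred.chf[mask].sum(axis=1)
    res = concordance_index(cohort.time[mask], cohort.event[mask], risks)
    res.n_excluded = int((~mask).sum())
    return res
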