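"""Analytic expected confidence-interval width for an AUC.

Implements the Hanley & McNeil (1982) approximation to the variance of a
nonparametric AUC estimate given the number of events (n1) and non-events
(n2).  The expected two-sided CI width answers the power question "how
precise could an AUC estimate possibly be at this sample size?", which is
the benchmark a bootstrap CI from real data is compared against.

The Hanley-McNeil variance treats the marker distributions as
binormal/exponential-like::

    Q1 = A / (2 - A)
    Q2 = 2 A^2 / (1 + A)
    var(A) = [ A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2) ] / (n1 n2)

with A the AUC.  Bounds are symmetric (A -/+ z*SE) and deliberately not
clipped to [0, 1]: at very small event counts the analytic interval can
extend past 1, which is itself informative about power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["AucPowerResult", "hanley_mcneil_se", "expected_ci"]


@dataclass(frozen=True)
class AucPowerResult:
    """Expected CI geometry for an AUC at a given event/non-event split."""

    auc: float
    n_events: int
    n_nonevents: int
    se: float
    width: float
    lower: float
    upper: float
    level: float = 0.95


def hanley_mcneil_se(auc: float, n_events: int, n_nonevents: int) -> float:
    """Standard error of an AUC by the Hanley-McNeil (1982) approximation.

    Parameters
    ----------
    auc : float
        The (true or observed) area under the ROC curve, in (0, 1).
    n_events, n_nonevents : int
        Number of positive and negative subjects, each >= 1.
    """
    if not 0.0 < auc < 1.0:
        raise ValueError(f"auc must be in (0, 1), got {auc}")
    if n_events < 1 or n_nonevents < 1:
        raise ValueError("n_events and n_nonevents must each be >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_events - 1) * (q1 - a * a)
        + (n_nonevents - 1) * (q2 - a * a)
    ) / (n_events * n_nonevents)
    return math.sqrt(var)


def expected_ci(
    auc: float,
    n_events: int,
    n_nonevents: int,
    level: float = 0.95,
) -> AucPowerResult:
    """Expected two-sided CI for an AUC estimated from n1 events / n2 non-events.

    ``width = 2 * z_{(1+level)/2} * SE``; bounds are ``auc -/+ width/2``.
    The z quantile is used at full double precision (1.959964... for 95%).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    se = hanley_mcneil_se(auc, n_events, n_nonevents)
    z = stats.norm.ppf(0.5 + level / 2.0)
    width = 2.0 * z * se
    return AucPowerResult(
        auc=float(auc),
        n_events=int(n_events),
        n_nonevents=int(n_nonevents),
        se=se,
        width=width,
        lower=float(auc) - width / 2.0,
        upper=float(auc) + width / 2.0,
        level=level,
    )
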