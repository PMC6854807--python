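"""Incremental-value analysis: IDI and NRI for one added ECG marker.

Given a landmark outcome window, a clinical logistic risk model (age,
sex, race, diabetes, hypertension, CHD, stroke) is fit with and without
one ECG marker, and the improvement is quantified by:

* absolute IDI — the gain in the discrimination slope
  (mean predicted risk among events minus among non-events);
* category-free NRI — the net proportion of events moved up plus
  non-events moved down, over any change in predicted probability;
* two-category NRI at a risk threshold (25% for windows up to 1 year
  after ECG recording, 10% beyond), with the count of events
  reclassified from below to at/above the threshold reported as
  ``k/n (percent)``.

P-values are the asymptotic z-tests of Pencina et al. (2008).
Probabilities are in-sample (no cross-validation), matching the typical
reporting of reclassification tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_COVARIATES",
    "DEFAULT_WINDOWS",
    "WindowOutcome",
    "ReclassResult",
    "fit_logistic",
    "idi",
    "nri_category_free",
    "nri_two_category",
    "window_risk_sets",
    "reclassify",
]

CLINICAL_COVARIATES = ("age", "sex", "race", "diabetes", "hypertension", "chd", "stroke")

_DAY = 1.0 / 365.25

#: (label, start_years, end_years, high-risk threshold)
DEFAULT_WINDOWS = (
    ("1-90d", 0.0, 90 * _DAY, 0.25),
    ("91-180d", 90 * _DAY, 180 * _DAY, 0.25),
    ("181-365d", 180 * _DAY, 365 * _DAY, 0.25),
    ("365-730d", 365 * _DAY, 730 * _DAY, 0.10),
    ("731-1825d", 730 * _DAY, 1825 * _DAY, 0.10),
    (">5y", 1825 * _DAY, np.inf, 0.10),
)


@dataclass
class WindowOutcome:
    """Binary outcome and predictors for one landmark window."""

    window: str
    threshold: float
    y: np.ndarray
    X: pd.DataFrame  # clinical covariates
    marker: np.ndarray
    n_at_risk: int = 0


@dataclass
class ReclassResult:
    """IDI / NRI summary for one marker in one window."""

    window: str
    threshold: float
    idi: float
    idi_p: float
    nri_cf: float
    nri_cf_p: float
    nri_2cat: float
    events_up: int
    n_events: int
    separation_flag: bool = False

    @property
    def events_up_label(self) -> str:
        if self.n_events == 0:
            return "0"
        pct = 100.0 * self.events_up / self.n_events
        return f"{self.events_up}/{self.n_events} ({pct:.0f}%)"


def fit_logistic(y: np.ndarray, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Maximum-likelihood logistic fit; returns in-sample probabilities.

    Newton–Raphson via statsmodels (tolerance 1e-8, max 50 iterations).
    An intercept column is added.  Quasi-separation (any |coefficient|
    exceeding 15) raises a warning and flags the fit; non-convergence is
    an error.
    """
    y = np.asarray(y, dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one event and one non-event")
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if Xa.shape[1]:
        keep = Xa.std(axis=0) > 0  # constant columns are absorbed by the intercept
        Xa = Xa[:, keep]
    Xd = sm.add_constant(Xa, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own convergence chatter
        try:
            res = sm.Logit(y, Xd).fit(method="newton", maxiter=50, tol=1e-8, disp=0)
        except Exception as exc:  # singular Hessian etc.
            raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge")
    if np.any(np.abs(res.params) > 15):
        warnings.warn(
            "possible separation: |coefficient| > 15 in logistic fit",
            UserWarning,
            stacklevel=2,
        )
    return np.asarray(res.predict(Xd))


def idi(p_old: np.ndarray, p_new: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Absolute integrated discrimination improvement with Pencina's z-test.

    IDI = [mean Δp | events] − [mean Δp | non-events], Δp = p_new − p_old.
    """
    p_old, p_new, y = map(np.asarray, (p_old, p_new, y))
    ev, ne = y == 1, y == 0
    if not ev.any() or not ne.any():
        raise ValueError("need both events and non-events")
    d = p_new - p_old
    d1, d0 = d[ev], d[ne]
    value = float(d1.mean() - d0.mean())
    se = np.sqrt(
        (d1.var(ddof=1) / len(d1) if len(d1) > 1 else 0.0)
        + (d0.var(ddof=1) / len(d0) if len(d0) > 1 else 0.0)
    )
    if se == 0:
        p = 1.0 if value == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(value) / se))
    return value, p


def nri_category_free(
    p_old: np.ndarray, p_new: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Category-free (continuous) NRI with the two-proportion z-test.

    NRI = [P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)],
    with up/down any increase/decrease of predicted probability.
    """
    p_old, p_new, y = map(np.asarray, (p_old, p_new, y))
    ev, ne = y == 1, y == 0
    if not ev.any() or not ne.any():
        raise ValueError("need both events and non-events")
    d = p_new - p_old
    up1, dn1 = float((d[ev] > 0).mean()), float((d[ev] < 0).mean())
    up0, dn0 = float((d[ne] > 0).mean()), float((d[ne] < 0).mean())
    nri_e = up1 - dn1
    nri_ne = dn0 - up0
    value = nri_e + nri_ne
    n1, n0 = int(ev.sum()), int(ne.sum())
    var = (up1 + dn1 - nri_e**2) / n1 + (up0 + dn0 - nri_ne**2) / n0
    if var <= 0:
        p = 1.0 if value == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(value) / np.sqrt(var)))
    return value, p


def nri_two_category(
    p_old: np.ndarray, p_new: np.ndarray, y: np.ndarray, threshold: float
) -> tuple[float, int, int]:
    """Two-category NRI at a high-risk threshold.

    Returns (nri, events reclassified upward, number of events).  A
    subject moves "up" when the old model places them below the
    threshold and the new model at/above it.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p_old, p_new, y = map(np.asarray, (p_old, p_new, y))
    ev, ne = y == 1, y == 0
    if not ev.any() or not ne.any():
        raise ValueError("need both events and non-events")
    hi_old = p_old >= threshold
    hi_new = p_new >= threshold
    up = ~hi_old & hi_new
    down = hi_old & ~hi_new
    n1, n0 = int(ev.sum()), int(ne.sum())
    nri_e = (int(up[ev].sum()) - int(down[ev].sum())) / n1
    nri_ne = (int(down[ne].sum()) - int(up[ne].sum())) / n0
    return nri_e + nri_ne, int(up[ev].sum()), n1


def window_risk_sets(
    cohort: pd.DataFrame,
    outcome: str = "SCD",
    windows: tuple = DEFAULT_WINDOWS,
    marker_name: str = "marker",
    covariates: tuple[str, ...] = CLINICAL_COVARIATES,
) -> list[WindowOutcome]:
    """Landmark risk sets for each outcome window.

    For a window (t0, t1]: the risk set is subjects with follow-up time
    ≥ t0 (alive and uncensored at the window start); y = 1 if the target
    event occurred inside the window; subjects whose follow-up ends
    inside the window without a target event (loss to follow-up or
    competing death) are dropped.  Empty or event-free windows are
    skipped with a log entry.
    """
    code = {"SCD": 1, "nonSCD": 2}[outcome]
    t = cohort["time_to_event_years"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy()
    out = []
    for label, t0, t1, thr in windows:
        at_risk = t >= t0
        event_in = at_risk & (e == code) & (t > t0) & (t <= t1)
        ends_in = at_risk & (t <= t1) & ~event_in  # censor or competing inside
        keep = at_risk & ~ends_in
        if not keep.any() or not event_in[keep].any():
            logger.info("window %s skipped: no usable events", label)
            continue
        sub = cohort.loc[keep]
        out.append(
            WindowOutcome(
                window=label,
                threshold=thr,
                y=event_in[keep].astype(int),
                X=sub[list(covariates)].reset_index(drop=True),
                marker=sub[marker_name].to_numpy(dtype=float),
                n_at_risk=int(keep.sum()),
            )
        )
    return out


def reclassify(wo: WindowOutcome) -> ReclassResult:
    """Fit clinical vs clinical+marker models and compute IDI/NRI."""
    sep = False
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        p_old = fit_logistic(wo.y, wo.X)
        p_new = fit_logistic(wo.y, np.column_stack([wo.X.to_numpy(dtype=float), wo.marker]))
        sep = any("separation" in str(w.message) for w in wlist)
    idi_v, idi_p = idi(p_old, p_new, wo.y)
    nri_v, nri_p = nri_category_free(p_old, p_new, wo.y)
    nri2, ev_up, n_ev = nri_two_category(p_old, p_new, wo.y, wo.threshold)
    return ReclassResult(
        window=wo.window,
        threshold=wo.threshold,
        idi=idi_v,
        idi_p=idi_p,
        nri_cf=nri_v,
        nri_cf_p=nri_p,
        nri_2cat=nri2,
        events_up=ev_up,
        n_events=n_ev,
        separation_flag=sep,
    )
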