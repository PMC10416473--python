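"""Time-to-onset (TTO) analysis with the Weibull shape-parameter test.

TTO is the event date minus the earliest day-precision therapy start date,
in whole days; 0 means the event occurred on the first day of therapy.
Cases with partial dates (YYYY or YYYYMM), missing dates, or reversed
dates (event before start) are excluded and counted per reason.

The onset distribution of each group is summarised by median/IQR, monthly
bins and a cumulative curve, and fitted with a two-parameter Weibull by
maximum likelihood.  The shape parameter β drives the hazard over time:
β < 1 means a decreasing hazard (*early failure* — most events shortly
after starting therapy), β ≈ 1 a constant hazard (*random failure*), and
β > 1 an increasing hazard (*wear-out failure*).  Classification uses the
95% CI of β: entirely below 1 → early, entirely above → wear-out,
spanning 1 → random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import faers_io
from ._util import round_half_up

_BIN_EDGES = [(0, 30), (31, 60), (61, 90), (91, 120), (121, 150), (151, 180),
              (181, 210), (211, 240), (241, 270), (271, 300), (301, 330), (331, 360)]


class WeibullFitError(RuntimeError):
    """The Weibull MLE is degenerate or did not converge."""


@dataclass
class TTOSample:
    """Validated onset intervals for one group of cases."""

    group: str
    values: np.ndarray  # onset days, integers >= 0
    n_excluded_partial: int = 0
    n_excluded_reversed: int = 0
    n_excluded_missing: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and self.values.min() < 0:
            raise ValueError("onset values must be >= 0")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def n_candidates(self) -> int:
        return (self.n + self.n_excluded_partial + self.n_excluded_reversed
                + self.n_excluded_missing)


@dataclass
class TTOSummary:
    """Descriptive onset distribution for one sample."""

    group: str
    n: int
    empty: bool
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    min: float | None = None
    max: float | None = None
    bins: list[tuple[str, int, float]] = field(default_factory=list)
    cumulative: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class WeibullFit:
    """ML estimates of the two-parameter Weibull with Wald CIs on log scale."""

    alpha: float
    alpha_lo95: float
    alpha_hi95: float
    beta: float
    beta_lo95: float
    beta_hi95: float
    n: int
    failure_type: str = ""


def compute_tto(
    cases: pd.DataFrame,
    therapies: pd.DataFrame,
    groups: pd.DataFrame | None = None,
    group_col: str = "soc",
) -> dict[str, TTOSample]:
    """Validated TTO samples for ``"all"`` cases and each group.

    Parameters
    ----------
    cases : deduplicated case table with ``caseid`` and raw ``event_dt`` text
        (or a parsed ``event_date``/``event_precision`` pair from
        :func:`pvsignal.faers_io.build_cases`).
    therapies : THER table with ``caseid`` and raw ``start_dt`` text; a case
        may have several therapy rows — the earliest day-precision start is
        used.
    groups : optional event-mention table (``caseid``, *group_col*); each
        case contributes its TTO to every group it reports.

    Exclusion precedence per case: missing (either date absent or invalid),
    then partial (either date at month/year precision), then reversed
    (event before start).  Candidates = included + the three exclusions.
    """
    if "event_date" in cases.columns and "event_precision" in cases.columns:
        ev = cases[["caseid"]].copy()
        ev["date"] = cases["event_date"]
        ev["precision"] = cases["event_precision"]
    else:
        parsed = faers_io.parse_date_column(cases["event_dt"])
        ev = pd.DataFrame({"caseid": cases["caseid"],
                           "date": parsed["date"], "precision": parsed["precision"]})
    ev = ev.drop_duplicates("caseid").set_index("caseid")

    sp = faers_io.parse_date_column(therapies["start_dt"])
    th = pd.DataFrame({"caseid": therapies["caseid"],
                       "date": sp["date"], "precision": sp["precision"]})

    # per case: earliest day-precision start, plus whether any partial start exists
    day_starts = th[th["precision"] == "day"].groupby("caseid")["date"].min()
    has_partial_start = (
        th[th["precision"].isin(["month", "year"])].groupby("caseid").size() > 0
    )

    status: dict[str, str] = {}
    tto: dict[str, int] = {}
    for caseid, row in ev.iterrows():
        start = day_starts.get(caseid)
        if row["precision"] in ("missing", "invalid"):
            status[caseid] = "missing"
        elif start is None and not has_partial_start.get(caseid, False):
            status[caseid] = "missing"  # no usable therapy start at all
        elif row["precision"] in ("month", "year") or start is None:
            status[caseid] = "partial"
        else:
            delta = (row["date"] - start).days
            if delta < 0:
                status[caseid] = "reversed"
            else:
                status[caseid] = "included"
                tto[caseid] = delta

    def make_sample(name: str, caseids) -> TTOSample:
        caseids = [c for c in caseids if c in status]
        counts = {"included": 0, "partial": 0, "reversed": 0, "missing": 0}
        values = []
        for c in caseids:
            counts[status[c]] += 1
            if status[c] == "included":
                values.append(tto[c])
        return TTOSample(
            group=name, values=np.array(values, dtype=float),
            n_excluded_partial=counts["partial"],
            n_excluded_reversed=counts["reversed"],
            n_excluded_missing=counts["missing"],
        )

    samples = {"all": make_sample("all", ev.index)}
    if groups is not None:
        for g, sub in groups[["caseid", group_col]].drop_duplicates().groupby(group_col):
            samples[str(g)] = make_sample(str(g), sub["caseid"])
    return samples


def summarize_tto(sample: TTOSample) -> TTOSummary:
    """Median/IQR (linear interpolation), monthly bins and cumulative curve."""
    if sample.n == 0:
        return TTOSummary(group=sample.group, n=0, empty=True)
    v = np.sort(sample.values)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    bins: list[tuple[str, int, float]] = []
    for lo, hi in _BIN_EDGES:
        count = int(((v >= lo) & (v <= hi)).sum())
        bins.append((f"{lo}-{hi}", count, round_half_up(100 * count / sample.n, 2)))
    over = int((v > 360).sum())
    bins.append((">360", over, round_half_up(100 * over / sample.n, 2)))
    distinct, counts = np.unique(v, return_counts=True)
    cumulative = list(zip(distinct.tolist(), (np.cumsum(counts) / sample.n).tolist()))
    return TTOSummary(
        group=sample.group, n=sample.n, empty=False,
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(v[0]), max=float(v[-1]),
        bins=bins, cumulative=cumulative,
    )


def _weibull_loglik(la: float, lb: float, logt: np.ndarray) -> float:
    b = math.exp(lb)
    z = b * (logt - la)
    return float(np.sum(lb + z - logt - np.exp(z)))


def fit_weibull(
    sample: TTOSample | np.ndarray,
    zero_value: float = 0.5,
    min_n: int = 10,
) -> WeibullFit:
    """Two-parameter Weibull MLE with 95% Wald CIs on (ln α, ln β).

    Zero-day onsets are mapped to *zero_value* days for the fit only (the
    Weibull density needs t > 0); raw samples are left untouched elsewhere.
    The shape MLE solves the standard profile score equation by bracketed
    root finding; the scale follows in closed form.  CIs come from the
    observed information of the log-parameterised likelihood.

    Raises :class:`WeibullFitError` for n below *min_n*, all-equal samples,
    or a non-invertible information matrix.
    """
    values = sample.values if isinstance(sample, TTOSample) else np.asarray(sample, float)
    group = sample.group if isinstance(sample, TTOSample) else ""
    t = values.astype(float).copy()
    t[t == 0] = zero_value
    n = len(t)
    if n < min_n:
        raise WeibullFitError(f"need at least {min_n} onsets to fit (group={group!r}, n={n})")
    if np.ptp(t) == 0:
        raise WeibullFitError(f"all onset values equal ({t[0]}); shape is unidentifiable")
    logt = np.log(t)
    lbar = logt.mean()
    tmax = t.max()
    s = t / tmax  # normalised to avoid overflow in s**b at large shapes

    def score(b: float) -> float:
        w = s**b
        return float((w * logt).sum() / w.sum() - 1.0 / b - lbar)

    lo, hi = 1e-3, 1.0
    while score(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise WeibullFitError("shape profile equation has no root below 1e4")
    beta = float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14))
    alpha = float(tmax * ((s**beta).mean()) ** (1.0 / beta))

    # observed information via central differences of the log-likelihood
    la, lb = math.log(alpha), math.log(beta)
    h = 1e-5
    def ll(x: float, y: float) -> float:
        return _weibull_loglik(x, y, logt)
    f0 = ll(la, lb)
    h11 = (ll(la + h, lb) - 2 * f0 + ll(la - h, lb)) / h**2
    h22 = (ll(la, lb + h) - 2 * f0 + ll(la, lb - h)) / h**2
    h12 = (ll(la + h, lb + h) - ll(la + h, lb - h)
           - ll(la - h, lb + h) + ll(la - h, lb - h)) / (4 * h**2)
    det = h11 * h22 - h12**2
    if not (h11 < 0 and det > 0):
        raise WeibullFitError("observed information is not positive definite at the MLE")
    var_la = -h22 / det
    var_lb = -h11 / det
    z = 1.959963984540054
    fit = WeibullFit(
        alpha=alpha,
        alpha_lo95=alpha * math.exp(-z * math.sqrt(var_la)),
        alpha_hi95=alpha * math.exp(z * math.sqrt(var_la)),
        beta=beta,
        beta_lo95=beta * math.exp(-z * math.sqrt(var_lb)),
        beta_hi95=beta * math.exp(z * math.sqrt(var_lb)),
        n=n,
    )
    fit.failure_type = classify_failure_type(fit)
    return fit


def classify_failure_type(fit: WeibullFit) -> str:
    """Hazard-over-time label from the shape CI: early / random / wear-out."""
    if fit.beta_hi95 < 1.0:
        return "early"
    if fit.beta_lo95 > 1.0:
        return "wear-out"
    return "random"
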