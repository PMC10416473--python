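"""Disproportionality statistics for drug–event signal screening.

Each drug–event pair is summarised by a 2×2 contingency table over report
pairs (rows = target drug vs all other drugs, columns = the event term vs
all other terms):

    ============  ========  ============
                  term      other terms
    ============  ========  ============
    target drug   a         b
    other drugs   c         d
    ============  ========  ============

Four classical algorithms are computed on it:

* **ROR** — reporting odds ratio ``(a·d)/(b·c)`` with a log-normal 95% CI;
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson χ² of the table (no continuity correction by default);
* **IC** — the Bayesian-shrinkage information component
  ``log2((a+0.5)/(E+0.5))`` with ``E=(a+b)(a+c)/N``, and its lower 95%
  credibility bound via the two-term expansion
  ``IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)``;
* **EBGM** — by default the closed-form relative reporting ratio
  ``a·N/((a+b)(a+c))`` with a log-normal 90% lower bound (EBGM05); the full
  empirical-Bayes gamma-Poisson shrinker lives in :mod:`pvsignal.mgps` and
  can be requested in :func:`screen` with ``ebgm="mgps"``.

A term is a *signal* only when all four criteria hold simultaneously:
ROR lower 95% bound > 1 with a ≥ min_count; PRR ≥ 2 with χ² ≥ 4 and
a ≥ min_count; IC025 > 0; EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from ._util import round_half_up

# conventional rounded normal quantiles, as written in the field's formulas
Z95 = 1.96
Z90 = 1.645


class ZeroCellError(ValueError):
    """A zero cell makes the statistic undefined; retry with correct_zero_cells=True."""


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report-pair counts for one drug–term pair."""

    a: int
    b: int
    c: int
    d: int
    term: str = ""
    level: str = "pt"
    soc: str | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.N <= 0:
            raise ValueError("contingency table is empty (N=0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell *a* under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N


@dataclass
class DisproportionalityResult:
    """All four statistics with bounds, per-criterion flags and the joint call."""

    term: str
    level: str
    soc: str | None
    a: int
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    corrected: bool = False
    flags: dict[str, bool] = field(default_factory=dict)
    signal: bool = False


def _cells(t: ContingencyTable, correct_zero_cells: bool) -> tuple[float, float, float, float, bool]:
    """Return (a,b,c,d) with the Haldane–Anscombe +0.5 applied only if needed."""
    if min(t.a, t.b, t.c, t.d) > 0:
        return float(t.a), float(t.b), float(t.c), float(t.d), False
    if not correct_zero_cells:
        raise ZeroCellError(
            f"zero cell in table {t.term or '(unnamed)'} (a={t.a}, b={t.b}, c={t.c}, d={t.d}); "
            "pass correct_zero_cells=True for the Haldane-Anscombe +0.5 correction"
        )
    return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True


def ror(t: ContingencyTable, correct_zero_cells: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with its log-normal 95% CI."""
    a, b, c, d, _ = _cells(t, correct_zero_cells)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr(t: ContingencyTable, correct_zero_cells: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and the table's Pearson χ² (no Yates)."""
    a, b, c, d, corrected = _cells(t, correct_zero_cells)
    est = (a / (a + b)) / (c / (c + d))
    if corrected:
        chi2 = chi_square(ContingencyTable(t.a, t.b, t.c, t.d))
    else:
        chi2 = chi_square(t)
    return est, chi2


def chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson χ² of the 2×2 table; optional Yates continuity correction."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = t.N
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff**2 / denom


def ic(t: ContingencyTable) -> tuple[float, float]:
    """Shrunken information component and its lower 95% credibility bound.

    The +0.5 shrinkage keeps the statistic finite for all a ≥ 0, so no
    zero-cell correction is ever needed.
    """
    est = math.log2((t.a + 0.5) / (t.expected + 0.5))
    return est, ic_credibility_lower(est, t.a)


def ic_credibility_lower(ic_value: float, a: int | float) -> float:
    """Lower 95% credibility bound of the IC from its point value and count a.

    Uses the two-term credibility-interval expansion
    ``IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)``, which depends on the data
    only through the observed count, so a printed (a, IC) pair suffices to
    recompute the bound.
    """
    s = a + 0.5
    return ic_value - 3.3 * s ** (-0.5) - 2.0 * s ** (-1.5)


def ebgm_simple(t: ContingencyTable, correct_zero_cells: bool = False) -> tuple[float, float]:
    """Closed-form EBGM (relative reporting ratio) and its 90% lower bound."""
    a, b, c, d, _ = _cells(t, correct_zero_cells)
    n = a + b + c + d
    est = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z90 * se)


def evaluate_flags(
    *,
    a: int,
    ror_lo95: float,
    prr_value: float,
    chi2: float,
    ic025: float,
    ebgm05: float,
    min_count: int = 3,
) -> tuple[dict[str, bool], bool]:
    """Apply the four per-algorithm criteria and the joint signal rule.

    Works equally on freshly computed statistics or on published table rows,
    since only the bounds and the case count enter the rule.
    """
    flags = {
        "ror": ror_lo95 > 1.0 and a >= min_count,
        "prr": prr_value >= 2.0 and chi2 >= 4.0 and a >= min_count,
        "ic": ic025 > 0.0,
        "ebgm": ebgm05 > 2.0,
    }
    return flags, all(flags.values())


def compute_result(
    t: ContingencyTable,
    min_count: int = 3,
    correct_zero_cells: bool = True,
    mgps_prior=None,
) -> DisproportionalityResult:
    """All four statistics plus flags for one table.

    Zero cells are corrected automatically (flagged in ``corrected``) because
    screening must not abort on rare terms.  If *mgps_prior* is given the
    EBGM column comes from the full gamma-Poisson shrinker instead of the
    closed form.
    """
    ror_est, ror_lo, ror_hi = ror(t, correct_zero_cells)
    prr_est, chi2 = prr(t, correct_zero_cells)
    ic_est, ic025 = ic(t)
    if mgps_prior is not None:
        from .mgps import ebgm_full

        ebgm_est, ebgm05 = ebgm_full(t, mgps_prior)
    else:
        ebgm_est, ebgm05 = ebgm_simple(t, correct_zero_cells)
    corrected = min(t.a, t.b, t.c, t.d) == 0
    flags, signal = evaluate_flags(
        a=t.a, ror_lo95=ror_lo, prr_value=prr_est, chi2=chi2,
        ic025=ic025, ebgm05=ebgm05, min_count=min_count,
    )
    return DisproportionalityResult(
        term=t.term, level=t.level, soc=t.soc, a=t.a,
        ror=ror_est, ror_lo95=ror_lo, ror_hi95=ror_hi,
        prr=prr_est, chi2=chi2, ic=ic_est, ic025=ic025,
        ebgm=ebgm_est, ebgm05=ebgm05,
        corrected=corrected, flags=flags, signal=signal,
    )


def build_contingency(
    events: pd.DataFrame,
    target_cases: Iterable[str],
    term: str,
    level: str = "pt",
    soc_of_term: str | None = None,
) -> ContingencyTable:
    """2×2 table for one term from an event-mention table.

    The counting unit is the unique (caseid, term) pair at the requested
    level, so duplicate REAC rows never inflate counts.  A term absent from
    *events* yields a=c=0 (allowed; screening flags it).
    """
    col = "pt" if level == "pt" else "soc"
    pairs = events[["caseid", col]].drop_duplicates()
    target = set(target_cases)
    in_target = pairs["caseid"].isin(target)
    is_term = pairs[col] == term
    a = int((in_target & is_term).sum())
    b = int((in_target & ~is_term).sum())
    c = int((~in_target & is_term).sum())
    d = int(len(pairs) - a - b - c)
    return ContingencyTable(a, b, c, d, term=term, level=level, soc=soc_of_term)


def all_contingency_tables(
    events: pd.DataFrame, target_cases: Iterable[str], level: str = "pt"
) -> list[ContingencyTable]:
    """One table per distinct term at *level*, built in a single pass."""
    col = "pt" if level == "pt" else "soc"
    pairs = events[["caseid", col] + (["soc"] if level == "pt" else [])].drop_duplicates(
        ["caseid", col]
    )
    target = set(target_cases)
    in_target = pairs["caseid"].isin(target)
    n_pairs = len(pairs)
    n_target_pairs = int(in_target.sum())
    a_counts = pairs.loc[in_target, col].value_counts()
    tot_counts = pairs[col].value_counts()
    if level == "pt":
        soc_of = pairs.groupby(col)["soc"].first()
    tables = []
    for term in sorted(tot_counts.index):
        a = int(a_counts.get(term, 0))
        c = int(tot_counts[term] - a)
        b = n_target_pairs - a
        d = n_pairs - n_target_pairs - c
        soc = str(soc_of[term]) if level == "pt" else str(term)
        tables.append(ContingencyTable(a, b, c, d, term=str(term), level=level, soc=soc))
    return tables


def screen(
    events: pd.DataFrame,
    target_cases: Iterable[str],
    level: str = "pt",
    min_count: int = 3,
    ebgm: str = "simple",
) -> pd.DataFrame:
    """Run the four-algorithm screen over every term at *level*.

    Parameters
    ----------
    events : event-mention table with columns caseid, pt, soc (from
        :func:`pvsignal.faers_io.map_pt_to_soc`).
    target_cases : CASEIDs of the target-drug cohort.
    level : "pt" or "soc".
    min_count : minimum observed count a for a term to be scored.
    ebgm : "simple" for the closed form, "mgps" for the full shrinker
        (prior fitted across all scored tables).

    Returns a DataFrame sorted by SOC then descending a, one row per term
    with a ≥ min_count, with ``attrs["n_signals"]`` and
    ``attrs["n_signal_socs"]`` summarising the joint rule.
    """
    tables = [t for t in all_contingency_tables(events, target_cases, level) if t.a >= min_count]
    prior = None
    if ebgm == "mgps" and tables:
        from .mgps import mgps_fit

        prior = mgps_fit(tables)
    elif ebgm != "simple" and ebgm != "mgps":
        raise ValueError(f"ebgm must be 'simple' or 'mgps', got {ebgm!r}")
    rows = []
    for t in tables:
        r = compute_result(t, min_count=min_count, mgps_prior=prior)
        rows.append(
            {
                "level": r.level, "soc": r.soc, "term": r.term, "a": r.a,
                "ror": r.ror, "ror_lo95": r.ror_lo95, "ror_hi95": r.ror_hi95,
                "prr": r.prr, "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "flag_ror": r.flags["ror"], "flag_prr": r.flags["prr"],
                "flag_ic": r.flags["ic"], "flag_ebgm": r.flags["ebgm"],
                "signal": r.signal, "corrected": r.corrected,
            }
        )
    out = pd.DataFrame(rows, columns=[
        "level", "soc", "term", "a", "ror", "ror_lo95", "ror_hi95", "prr", "chi2",
        "ic", "ic025", "ebgm", "ebgm05", "flag_ror", "flag_prr", "flag_ic",
        "flag_ebgm", "signal", "corrected",
    ])
    if len(out):
        out = out.sort_values(["soc", "a"], ascending=[True, False]).reset_index(drop=True)
        n_signals = int(out["signal"].sum())
        n_socs = int(out.loc[out["signal"], "soc"].nunique())
    else:
        n_signals = n_socs = 0
    out.attrs["n_signals"] = n_signals
    out.attrs["n_signal_socs"] = n_socs
    return out


def format_report(results: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Round the statistic columns half-up for report output."""
    out = results.copy()
    for col in ("ror", "ror_lo95", "ror_hi95", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"):
        if col in out.columns:
            out[col] = out[col].map(lambda x: round_half_up(float(x), ndigits))
    return out
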