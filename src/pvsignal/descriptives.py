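"""Cohort characteristics tables for a spontaneous-report drug cohort.

Mirrors the conventional "Table 1" of a pharmacovigilance study: sex, age
and weight bands, reporting country, indications, combination drugs,
comorbidities, outcome seriousness, reporter type and reporting year.
Percentages within each block use the block's *available-n* — the number
of cases with the item recorded — not the full cohort size, and serious
outcome subtypes allow multiplicity (one case may be hospitalised and
later die, contributing to both counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up

OUTCOME_ORDER = ["death", "life-threatening", "hospitalization", "disability", "other"]


def percent(numerator: int, denominator: int) -> float | None:
    """Case proportion in percent, half-up at 2 dp.

    A zero denominator returns ``None`` — an explicit undefined marker,
    never a silent 0.  Negative inputs are rejected.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, 2)


@dataclass
class CategoryBlock:
    """One Table-1 block: available-n and (label, count, percent) rows."""

    available_n: int
    rows: list[tuple[str, int, float | None]] = field(default_factory=list)


@dataclass
class CohortSummary:
    """All descriptive blocks plus medians with IQR."""

    n_cases: int
    blocks: dict[str, CategoryBlock] = field(default_factory=dict)
    medians: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, cb in self.blocks.items():
            for label, count, pct in cb.rows:
                rows.append((block, cb.available_n, label, count, pct))
        for name, (med, q1, q3) in self.medians.items():
            rows.append((f"median_{name}", None, f"{med} ({q1}-{q3})", None, None))
        return pd.DataFrame(
            rows, columns=["block", "available_n", "label", "count", "percent"]
        )


def _band_block(values: pd.Series, bands: list[tuple[str, float, float]]) -> CategoryBlock:
    """Counts per [lo, hi) band over non-missing values."""
    v = values.dropna()
    n = len(v)
    rows = []
    for label, lo, hi in bands:
        count = int(((v >= lo) & (v < hi)).sum())
        rows.append((label, count, percent(count, n)))
    return CategoryBlock(available_n=n, rows=rows)


def _top_k_block(per_case_items: pd.DataFrame, k: int) -> CategoryBlock:
    """Top-k item counts; one count per case per item; denominator = cases with any item."""
    if len(per_case_items) == 0:
        return CategoryBlock(available_n=0, rows=[])
    pairs = per_case_items.drop_duplicates()
    n_avail = pairs["caseid"].nunique()
    counts = pairs["item"].value_counts().head(k)
    rows = [(str(item), int(c), percent(int(c), n_avail)) for item, c in counts.items()]
    return CategoryBlock(available_n=n_avail, rows=rows)


def summarize_cohort(
    cases: pd.DataFrame,
    drugs: pd.DataFrame | None = None,
    indications: pd.DataFrame | None = None,
    target_role: str = "PS",
    top_k: int = 5,
) -> CohortSummary:
    """Build the Table-1-style summary for a deduplicated cohort.

    Parameters
    ----------
    cases : harmonised case table from :func:`pvsignal.faers_io.build_cases`,
        already restricted to the target cohort.
    drugs : DRUG rows of the cohort; non-PS rows yield the combination-drug
        block.
    indications : INDI rows of the cohort; rows linked to the PS drug
        (``indi_drug_seq`` matching a PS ``drug_seq``) are indications, rows
        linked to other drugs are counted as comorbidities.
    """
    n = len(cases)
    summary = CohortSummary(n_cases=n)

    sex = cases["sex"]
    known_sex = sex[sex.isin(["female", "male"])]
    summary.blocks["sex"] = CategoryBlock(
        available_n=len(known_sex),
        rows=[(lab, int((known_sex == lab).sum()), percent(int((known_sex == lab).sum()), len(known_sex)))
              for lab in ("female", "male")],
    )

    summary.blocks["age_years"] = _band_block(
        cases["age_years"], [("<18", 0, 18), ("18-65", 18, 65.0000001), (">65", 65.0000001, np.inf)]
    )
    summary.blocks["weight_kg"] = _band_block(
        cases["weight_kg"], [("<80", 0, 80), ("80-100", 80, 100.0000001), (">100", 100.0000001, np.inf)]
    )

    known_country = cases[cases["country"] != "unknown"]
    n_us = int(known_country["is_us"].sum())
    summary.blocks["country"] = CategoryBlock(
        available_n=len(known_country),
        rows=[("US", n_us, percent(n_us, len(known_country))),
              ("non-US", len(known_country) - n_us,
               percent(len(known_country) - n_us, len(known_country)))],
    )

    if drugs is not None and indications is not None:
        cohort_ids = set(cases["caseid"])
        d = drugs[drugs["caseid"].isin(cohort_ids)].copy()
        d["role_cod"] = d["role_cod"].str.strip().str.upper()
        ind = indications[indications["caseid"].isin(cohort_ids)].copy()
        ps_keys = d.loc[d["role_cod"] == target_role, ["caseid", "drug_seq"]].astype(str)
        ind_keys = ind[["caseid", "indi_drug_seq"]].astype(str)
        is_ps_linked = ind_keys.apply(tuple, axis=1).isin(
            set(ps_keys.apply(tuple, axis=1))
        ) if len(ind) else pd.Series(dtype=bool)

        drug_indis = ind.loc[is_ps_linked, ["caseid", "indi_pt"]].rename(columns={"indi_pt": "item"})
        summary.blocks["indications"] = _top_k_block(drug_indis, top_k)
        comorb = ind.loc[~is_ps_linked, ["caseid", "indi_pt"]].rename(columns={"indi_pt": "item"})
        summary.blocks["comorbidities"] = _top_k_block(comorb, top_k)

        combo = d.loc[d["role_cod"] != target_role, ["caseid"]].copy()
        name_col = "prod_ai" if "prod_ai" in d.columns else "drugname"
        combo["item"] = d.loc[d["role_cod"] != target_role, name_col].str.strip().str.upper()
        summary.blocks["combination_drugs"] = _top_k_block(combo, top_k)

    n_serious = int(cases["serious"].sum())
    outcome_rows = [("non-serious", n - n_serious, percent(n - n_serious, n)),
                    ("serious", n_serious, percent(n_serious, n))]
    all_outcomes = [o for outs in cases["outcomes"] for o in outs]
    for lab in OUTCOME_ORDER:
        count = sum(1 for o in all_outcomes if o == lab)
        outcome_rows.append((lab, count, percent(count, n_serious)))
    summary.blocks["outcomes"] = CategoryBlock(available_n=n, rows=outcome_rows)

    rep = cases["reporter"]
    known_rep = rep[rep != "unknown"]
    summary.blocks["reporter"] = CategoryBlock(
        available_n=len(known_rep),
        rows=[(lab, int((known_rep == lab).sum()), percent(int((known_rep == lab).sum()), len(known_rep)))
              for lab in ("health professional", "consumer")],
    )

    years = cases["event_year"].dropna().astype(int)
    summary.blocks["reporting_year"] = CategoryBlock(
        available_n=len(years),
        rows=[(str(y), int((years == y).sum()), percent(int((years == y).sum()), len(years)))
              for y in sorted(years.unique())],
    )

    for name, col in (("age_years", "age_years"), ("weight_kg", "weight_kg")):
        v = cases[col].dropna()
        if len(v):
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            summary.medians[name] = (float(med), float(q1), float(q3))
    return summary
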