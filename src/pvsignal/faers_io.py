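"""Reading and cleaning FAERS-style spontaneous-report tables.

FAERS quarterly extracts are ``$``-delimited ASCII files (DEMO, DRUG, REAC,
THER, OUTC, INDI).  A *case* (CASEID) may appear under several report
versions (PRIMARYID); analysis keeps one row per case — the highest
PRIMARYID — and drops cases named in the FDA deleted-case list.  Adverse
events are MedDRA preferred terms (PT) which roll up to system organ
classes (SOC); a PT may be linked to more than one SOC, with one link
flagged primary.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical table keys → file-name prefixes of the quarterly extracts
TABLE_PREFIXES: Mapping[str, str] = {
    "demo": "DEMO",
    "drug": "DRUG",
    "reac": "REAC",
    "ther": "THER",
    "outc": "OUTC",
    "indi": "INDI",
}

_SEX_MAP = {"F": "female", "M": "male"}
_REPORTER_MAP = {
    "MD": "health professional",
    "PH": "health professional",
    "OT": "health professional",
    "HP": "health professional",
    "CN": "consumer",
}
_OUTCOME_MAP = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "other",
    "RI": "other",
    "OT": "other",
}
#: age_cod unit → multiplier into years
_AGE_UNITS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 1 / 52.143, "DY": 1 / 365.25}


def read_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Load the six raw tables from *directory*.

    Files are matched by prefix (``DEMO*.txt`` etc.) so several quarters can
    coexist; all matches are concatenated.  Every column is read as text —
    identifiers like PRIMARYID must never be coerced to numbers silently.

    Raises
    ------
    FileNotFoundError
        If a mandatory table has no matching file; the message names it.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for key, prefix in TABLE_PREFIXES.items():
        paths = sorted(directory.glob(f"{prefix}*.txt"))
        if not paths:
            raise FileNotFoundError(
                f"mandatory table {prefix} not found: no {prefix}*.txt in {directory}"
            )
        frames = [
            pd.read_csv(p, sep="$", dtype=str, keep_default_na=False, engine="python")
            for p in paths
        ]
        df = pd.concat(frames, ignore_index=True)
        df.columns = [c.strip().lower() for c in df.columns]
        tables[key] = df
        logger.info("read %s: %d rows from %d file(s)", prefix, len(df), len(paths))
    return tables


def read_deleted_cases(path: str | Path) -> list[str]:
    """Read a newline-delimited CASEID list; blank lines ignored."""
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_dictionary(path: str | Path) -> pd.DataFrame:
    """Load a 3-column PT→SOC mapping TSV (pt, soc, is_primary)."""
    df = pd.read_csv(path, sep="\t", dtype={"pt": str, "soc": str})
    df["is_primary"] = df["is_primary"].astype(int).astype(bool)
    return df


def deduplicate(
    demo: pd.DataFrame, deleted_caseids: Iterable[str] = ()
) -> tuple[pd.DataFrame, int]:
    """Collapse report versions to one row per case and drop deleted cases.

    For each CASEID the row with the numerically highest PRIMARYID is kept
    (exact ties keep the first row in file order); rows whose CASEID appears
    in *deleted_caseids* are then removed.  Returns the cleaned table and the
    number of rows removed.  Idempotent.
    """
    if "primaryid" not in demo.columns or "caseid" not in demo.columns:
        raise ValueError("demo table must have primaryid and caseid columns")
    pid = pd.to_numeric(demo["primaryid"], errors="coerce")
    if pid.isna().any():
        bad = demo.loc[pid.isna(), "primaryid"].iloc[0]
        raise ValueError(f"non-numeric PRIMARYID: {bad!r}")
    keep_idx = pid.groupby(demo["caseid"]).idxmax()  # idxmax → first max in file order
    out = demo.loc[sorted(keep_idx)]
    deleted = set(str(c) for c in deleted_caseids)
    if deleted:
        out = out[~out["caseid"].isin(deleted)]
    out = out.reset_index(drop=True)
    removed = len(demo) - len(out)
    logger.info("deduplicate: %d rows in, %d removed, %d cases out", len(demo), removed, len(out))
    return out, removed


def extract_target_cases(
    drug: pd.DataFrame,
    synonyms: Iterable[str],
    role: str = "PS",
    exact: bool = False,
) -> set[str]:
    """CASEIDs with at least one drug row matching *synonyms* in *role*.

    Both ``drugname`` and ``prod_ai`` are searched, case-insensitively after
    trimming; by default a substring hit counts (FAERS verbatim drug names
    carry salts, brands and free text), ``exact=True`` requires full equality.
    """
    synonyms = [s.strip().lower() for s in synonyms]
    if not synonyms:
        raise ValueError("synonyms must be nonempty")
    mask = drug["role_cod"].str.strip().str.upper() == role.upper()
    name_cols = [c for c in ("drugname", "prod_ai") if c in drug.columns]
    hit = pd.Series(False, index=drug.index)
    for col in name_cols:
        values = drug[col].fillna("").str.strip().str.lower()
        for syn in synonyms:
            hit |= (values == syn) if exact else values.str.contains(syn, regex=False)
    return set(drug.loc[mask & hit, "caseid"])


def parse_faers_date(text: str | None) -> tuple[datetime.date | None, str]:
    """Parse a FAERS date field into ``(date-or-None, precision)``.

    Precision is ``day`` (YYYYMMDD, valid calendar date), ``month`` (YYYYMM),
    ``year`` (YYYY), ``missing`` (empty), or ``invalid`` (anything else,
    including out-of-range calendar values).  Only day precision yields a
    date object; partial dates are unusable for onset arithmetic.
    """
    if text is None:
        return None, "missing"
    s = str(text).strip()
    if s == "" or s.lower() == "nan":
        return None, "missing"
    if not s.isdigit():
        return None, "invalid"
    if len(s) == 8:
        try:
            return datetime.date(int(s[:4]), int(s[4:6]), int(s[6:])), "day"
        except ValueError:
            return None, "invalid"
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:])
        if 1 <= month <= 12:
            return None, "month"
        return None, "invalid"
    if len(s) == 4:
        return None, "year"
    return None, "invalid"


def parse_date_column(series: pd.Series) -> pd.DataFrame:
    """Vectorised :func:`parse_faers_date` → columns ``date``, ``precision``."""
    parsed = series.map(parse_faers_date)
    return pd.DataFrame(
        {"date": parsed.map(lambda t: t[0]), "precision": parsed.map(lambda t: t[1])},
        index=series.index,
    )


def map_pt_to_soc(
    events: pd.DataFrame, dictionary: pd.DataFrame, policy: str = "primary"
) -> pd.DataFrame:
    """Attach SOCs to event rows (caseid, pt) via the PT→SOC dictionary.

    ``policy="primary"`` gives exactly one SOC per PT (its primary link);
    ``policy="all"`` emits one row per (PT, SOC) link.  PTs absent from the
    dictionary are kept with ``soc="UNMAPPED"`` and counted in the result's
    ``attrs["n_unmapped_pts"]`` — never dropped silently.
    """
    if policy not in ("primary", "all"):
        raise ValueError(f"policy must be 'primary' or 'all', got {policy!r}")
    dictionary = dictionary.assign(is_primary=dictionary["is_primary"].astype(bool))
    n_primary = dictionary.groupby("pt")["is_primary"].sum()
    if (n_primary > 1).any():
        bad = n_primary[n_primary > 1].index[0]
        raise ValueError(f"dictionary has conflicting primary flags for PT {bad!r}")
    if policy == "primary":
        if (n_primary < 1).any():
            bad = n_primary[n_primary < 1].index[0]
            raise ValueError(f"dictionary has no primary SOC for PT {bad!r}")
        mapping = dictionary[dictionary["is_primary"]][["pt", "soc"]]
    else:
        mapping = dictionary[["pt", "soc"]].drop_duplicates()

    pairs = events[["caseid", "pt"]].drop_duplicates()
    out = pairs.merge(mapping, on="pt", how="left")
    unmapped = out["soc"].isna()
    n_unmapped = out.loc[unmapped, "pt"].nunique()
    if n_unmapped:
        logger.warning("map_pt_to_soc: %d PT(s) not in dictionary, flagged UNMAPPED", n_unmapped)
    out["soc"] = out["soc"].fillna("UNMAPPED")
    out = out.drop_duplicates(["caseid", "pt", "soc"]).reset_index(drop=True)
    out.attrs["n_unmapped_pts"] = int(n_unmapped)
    return out


def _age_to_years(age: str, unit: str) -> float:
    try:
        value = float(age)
    except (TypeError, ValueError):
        return np.nan
    mult = _AGE_UNITS.get(unit.strip().upper())
    return value * mult if mult is not None else np.nan


def build_cases(tables: dict[str, pd.DataFrame], deleted_caseids: Iterable[str] = ()) -> pd.DataFrame:
    """Harmonise DEMO+OUTC into one deduplicated case-level table.

    Columns: caseid, primaryid, sex, age_years, weight_kg, country, is_us,
    reporter, event_date, event_precision, event_year, outcomes (tuple of
    labels, multiplicity collapsed per label set), serious.  Unknown codes map
    to ``unknown``/NaN, never dropped.
    """
    demo, _ = deduplicate(tables["demo"], deleted_caseids)
    out = pd.DataFrame({"caseid": demo["caseid"], "primaryid": demo["primaryid"]})
    out["sex"] = demo.get("sex", pd.Series("", index=demo.index)).str.strip().str.upper().map(
        _SEX_MAP
    ).fillna("unknown")
    if "age" in demo.columns:
        unit = demo.get("age_cod", pd.Series("", index=demo.index))
        out["age_years"] = [_age_to_years(a, u) for a, u in zip(demo["age"], unit)]
    else:
        out["age_years"] = np.nan
    if "wt" in demo.columns:
        out["weight_kg"] = pd.to_numeric(demo["wt"], errors="coerce")
    else:
        out["weight_kg"] = np.nan
    country_col = "occr_country" if "occr_country" in demo.columns else "reporter_country"
    country = demo.get(country_col, pd.Series("", index=demo.index)).str.strip().str.upper()
    out["country"] = country.replace("", "unknown")
    out["is_us"] = country == "US"
    out["reporter"] = demo.get("occp_cod", pd.Series("", index=demo.index)).str.strip().str.upper().map(
        _REPORTER_MAP
    ).fillna("unknown")
    dates = parse_date_column(demo.get("event_dt", pd.Series("", index=demo.index)))
    out["event_date"] = dates["date"]
    out["event_precision"] = dates["precision"]
    out["event_year"] = [d.year if d is not None else np.nan for d in dates["date"]]

    outc = tables["outc"]
    oc = outc.copy()
    oc["label"] = oc["outc_cod"].str.strip().str.upper().map(_OUTCOME_MAP)
    oc = oc.dropna(subset=["label"])
    per_case = oc.groupby("caseid")["label"].apply(lambda s: tuple(sorted(set(s))))
    out["outcomes"] = out["caseid"].map(per_case).apply(
        lambda v: v if isinstance(v, tuple) else ()
    )
    out["serious"] = out["outcomes"].map(bool)
    return out
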