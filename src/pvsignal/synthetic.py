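"""Synthetic FAERS-shaped spontaneous-report cohorts with known ground truth.

Every downstream stage (deduplication, primary-suspect extraction, PT→SOC
rollup, disproportionality screening, time-to-onset analysis) is testable
without downloading the real corpus: the generator emits the six raw
quarterly tables (DEMO, DRUG, REAC, THER, OUTC, INDI), a deleted-case list
and a PT→SOC dictionary, together with a self-auditing
:class:`GroundTruth` recording exactly what was injected — true per-PT
reporting-rate ratios for the target drug, true onset Weibull parameters,
and the counts of duplicates, deleted cases, partial dates and reversed
dates.

The statistical model per case: the primary-suspect drug is the target
with probability ``target_drug_share``; each catalog PT is reported as an
independent Bernoulli with probability ``baseline`` (background cases) or
``min(baseline·RR_true, 1)`` (target cases); the case's onset time is a
Weibull draw for its first reported term, added to the therapy start date,
so same-day (TTO = 0) events occur naturally.  A case that draws no PT is
given one fallback PT sampled proportionally to the baselines, so every
case carries at least one reaction.

All randomness flows through one seeded generator with a fixed draw order,
so outputs are byte-identical for equal configurations.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TARGET_DRUGNAME = "RUBRACA"
TARGET_PROD_AI = "RUCAPARIB"

_BACKGROUND_DRUGS = [
    "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE", "LEVOTHYROXINE",
    "AMLODIPINE", "SERTRALINE", "ALBUTEROL", "IBUPROFEN", "WARFARIN",
    "PREDNISONE", "DULOXETINE", "PEMBROLIZUMAB", "CARBOPLATIN", "PACLITAXEL",
]
_CONCOMITANT_DRUGS = [
    "ONDANSETRON", "CHOLECALCIFEROL", "GABAPENTIN", "VITAMINS", "LORAZEPAM",
    "DEXAMETHASONE", "PANTOPRAZOLE",
]
_COMORBIDITY_PTS = ["Nausea", "Pain", "Hypertension", "Anxiety", "Vomiting", "Insomnia"]
_TARGET_INDICATIONS = [
    ("Ovarian cancer", 0.83),
    ("Fallopian tube cancer", 0.04),
    ("Malignant peritoneal neoplasm", 0.04),
    ("Breast cancer", 0.09),
]
_BACKGROUND_INDICATIONS = ["Hypertension", "Diabetes mellitus", "Depression", "Asthma", "Pain"]

_EPOCH = datetime.date(2017, 1, 1)
_START_SPAN_DAYS = 1900  # therapy starts spread over 2017-01 .. 2022-03


def default_pt_catalog() -> list[tuple[str, str, float]]:
    """A realistic 30-term catalog: (PT, primary SOC, baseline probability).

    Baselines approximate how often common terms appear in spontaneous
    reports of any drug; the SOC spread mirrors a PARP-inhibitor safety
    profile (gastrointestinal, blood, investigations, general, nervous).
    """
    return [
        ("Nausea", "Gastrointestinal disorders", 0.060),
        ("Vomiting", "Gastrointestinal disorders", 0.035),
        ("Diarrhoea", "Gastrointestinal disorders", 0.040),
        ("Constipation", "Gastrointestinal disorders", 0.018),
        ("Abdominal pain", "Gastrointestinal disorders", 0.020),
        ("Fatigue", "General disorders and administration site conditions", 0.070),
        ("Asthenia", "General disorders and administration site conditions", 0.030),
        ("Malaise", "General disorders and administration site conditions", 0.025),
        ("Pyrexia", "General disorders and administration site conditions", 0.020),
        ("Anaemia", "Blood and lymphatic system disorders", 0.015),
        ("Thrombocytopenia", "Blood and lymphatic system disorders", 0.008),
        ("Neutropenia", "Blood and lymphatic system disorders", 0.007),
        ("Platelet count decreased", "Investigations", 0.008),
        ("Blood creatinine increased", "Investigations", 0.006),
        ("Alanine aminotransferase increased", "Investigations", 0.007),
        ("Aspartate aminotransferase increased", "Investigations", 0.006),
        ("Weight decreased", "Investigations", 0.012),
        ("Headache", "Nervous system disorders", 0.045),
        ("Dizziness", "Nervous system disorders", 0.035),
        ("Dysgeusia", "Nervous system disorders", 0.005),
        ("Neuropathy peripheral", "Nervous system disorders", 0.008),
        ("Decreased appetite", "Metabolism and nutrition disorders", 0.015),
        ("Dehydration", "Metabolism and nutrition disorders", 0.008),
        ("Rash", "Skin and subcutaneous tissue disorders", 0.030),
        ("Photosensitivity reaction", "Skin and subcutaneous tissue disorders", 0.003),
        ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.030),
        ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.020),
        ("Insomnia", "Psychiatric disorders", 0.020),
        ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.025),
        ("Renal disorder", "Renal and urinary disorders", 0.006),
    ]


def default_effect_map() -> dict[str, float]:
    """True reporting-rate ratios for the target drug (RR=1 elsewhere).

    Chosen so the total excess reporting mass stays moderate: when many
    terms are elevated at once, target cases carry more terms overall and
    every profile-based ratio is diluted below its RR_true, so rare terms
    get the large ratios and common terms the small ones, as in real
    spontaneous-report profiles.
    """
    return {
        "Nausea": 2.0,
        "Constipation": 3.0,
        "Anaemia": 4.0,
        "Thrombocytopenia": 3.0,
        "Platelet count decreased": 5.0,
        "Blood creatinine increased": 5.0,
        "Dysgeusia": 12.0,
        "Decreased appetite": 2.0,
        "Photosensitivity reaction": 15.0,
    }


def default_onset_map() -> dict[str, tuple[float, float]]:
    """True onset Weibull (scale days, shape) per SOC; shapes < 1 = early failure."""
    return {
        "Gastrointestinal disorders": (8.72, 0.29),
        "General disorders and administration site conditions": (12.37, 0.30),
        "Blood and lymphatic system disorders": (31.85, 0.31),
        "Investigations": (16.57, 0.28),
        "Nervous system disorders": (11.89, 0.31),
        "Metabolism and nutrition disorders": (10.17, 0.32),
        "Skin and subcutaneous tissue disorders": (15.25, 0.31),
        "default": (16.57, 0.28),
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 5000
    target_drug_share: float = 0.10
    pt_catalog: list[tuple[str, str, float]] = field(default_factory=default_pt_catalog)
    effect_map: dict[str, float] = field(default_factory=default_effect_map)
    onset_map: dict[str, tuple[float, float]] = field(default_factory=default_onset_map)
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.01
    partial_date_rate: float = 0.10
    reversed_date_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.target_drug_share <= 1:
            raise ValueError("target_drug_share must lie in [0, 1]")
        for name, rate in (
            ("duplicate_rate", self.duplicate_rate),
            ("deleted_rate", self.deleted_rate),
            ("partial_date_rate", self.partial_date_rate),
            ("reversed_date_rate", self.reversed_date_rate),
        ):
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not self.pt_catalog:
            raise ValueError("pt_catalog must be nonempty")
        pts = {pt for pt, _, _ in self.pt_catalog}
        if len(pts) != len(self.pt_catalog):
            raise ValueError("pt_catalog contains duplicate PTs")
        for pt, _, p in self.pt_catalog:
            if not 0 < p <= 1:
                raise ValueError(f"baseline probability for {pt!r} must lie in (0, 1]")
        for pt, rr in self.effect_map.items():
            if pt not in pts:
                raise ValueError(f"effect_map PT {pt!r} missing from pt_catalog")
            if rr < 0:
                raise ValueError(f"RR_true for {pt!r} must be >= 0")
        socs = {soc for _, soc, _ in self.pt_catalog}
        for key, (scale, shape) in self.onset_map.items():
            if key != "default" and key not in pts and key not in socs:
                raise ValueError(f"onset_map key {key!r} is neither a catalog PT nor SOC")
            if scale <= 0 or shape <= 0:
                raise ValueError(f"onset parameters for {key!r} must be positive")


@dataclass
class GroundTruth:
    """Self-audit of one generated cohort."""

    rr_true: dict[str, float]
    onset_true: dict[str, tuple[float, float]]
    n_cases: int
    n_target_cases: int
    n_duplicates: int
    n_deleted: int
    n_partial_dates: int
    n_reversed_dates: int
    table_rows: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_cases", "", self.n_cases),
                ("n_target_cases", "", self.n_target_cases),
                ("n_duplicates", "", self.n_duplicates),
                ("n_deleted", "", self.n_deleted),
                ("n_partial_dates", "", self.n_partial_dates),
                ("n_reversed_dates", "", self.n_reversed_dates)]
        rows += [(f"rows_{k}", "", v) for k, v in self.table_rows.items()]
        rows += [("rr_true", pt, rr) for pt, rr in self.rr_true.items()]
        rows += [("onset_scale", k, v[0]) for k, v in self.onset_true.items()]
        rows += [("onset_shape", k, v[1]) for k, v in self.onset_true.items()]
        return pd.DataFrame(rows, columns=["quantity", "key", "value"])


@dataclass
class SyntheticCohort:
    """Generated raw tables plus dictionary, deleted list and audit."""

    tables: dict[str, pd.DataFrame]
    deleted_caseids: list[str]
    dictionary: pd.DataFrame
    truth: GroundTruth


def generate_dictionary(
    n_pts: int,
    n_socs: int,
    multi_soc_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random PT→SOC mapping table with columns (pt, soc, is_primary).

    Every PT gets exactly one primary SOC; ``round(multi_soc_fraction·n_pts)``
    PTs carry one additional secondary SOC link, mirroring MedDRA's
    multi-axiality.  Each SOC is primary for at least one PT.
    """
    if n_socs < 1:
        raise ValueError("n_socs must be >= 1")
    if n_pts < n_socs:
        raise ValueError(f"n_pts ({n_pts}) must be >= n_socs ({n_socs})")
    if not 0 <= multi_soc_fraction <= 1:
        raise ValueError("multi_soc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pts = [f"PT_{i:04d}" for i in range(n_pts)]
    socs = [f"SOC_{i:02d}" for i in range(n_socs)]
    # first n_socs PTs cover every SOC once, the rest draw uniformly
    primary = list(range(n_socs)) + list(rng.integers(0, n_socs, size=n_pts - n_socs))
    rows = [(pt, socs[s], 1) for pt, s in zip(pts, primary)]
    n_multi = round(multi_soc_fraction * n_pts)
    if n_multi and n_socs < 2:
        raise ValueError("multi_soc_fraction > 0 requires n_socs >= 2")
    multi_idx = rng.choice(n_pts, size=n_multi, replace=False)
    for i in sorted(multi_idx):
        secondary = (primary[i] + 1 + int(rng.integers(0, n_socs - 1))) % n_socs
        rows.append((pts[i], socs[secondary], 0))
    df = pd.DataFrame(rows, columns=["pt", "soc", "is_primary"])
    return df.sort_values(["pt", "is_primary"], ascending=[True, False]).reset_index(drop=True)


def _fmt_date(days_since_epoch: int) -> str:
    return (_EPOCH + datetime.timedelta(days=int(days_since_epoch))).strftime("%Y%m%d")


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort under *config*; deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    pts = [pt for pt, _, _ in config.pt_catalog]
    socs = [soc for _, soc, _ in config.pt_catalog]
    baselines = np.array([p for _, _, p in config.pt_catalog])
    rr = np.array([config.effect_map.get(pt, 1.0) for pt in pts])

    caseids = np.array([str(10_000_000 + i) for i in range(n)])
    primaryids = np.array([cid + "1" for cid in caseids])

    # --- draw order is fixed; every block below consumes rng unconditionally ---
    n_target = round(n * config.target_drug_share)
    target_mask = np.zeros(n, dtype=bool)
    target_mask[rng.permutation(n)[:n_target]] = True

    # reaction draws: independent Bernoulli per (case, PT)
    probs = np.where(target_mask[:, None], np.minimum(baselines * rr, 1.0), baselines)
    hits = rng.random((n, len(pts))) < probs
    fallback_pt = rng.choice(len(pts), size=n, p=baselines / baselines.sum())
    none_drawn = ~hits.any(axis=1)
    hits[none_drawn, fallback_pt[none_drawn]] = True

    # therapy start and onset: one event date per case, Weibull of its first term
    start_days = rng.integers(0, _START_SPAN_DAYS, size=n)
    first_pt = hits.argmax(axis=1)
    default_onset = config.onset_map.get("default", (16.57, 0.28))
    per_pt_onset = [
        config.onset_map.get(pt, config.onset_map.get(soc, default_onset))
        for pt, soc in zip(pts, socs)
    ]
    scale_by_pt = np.array([p[0] for p in per_pt_onset])
    shape_by_pt = np.array([p[1] for p in per_pt_onset])
    onset_scale = scale_by_pt[first_pt]
    onset_shape = shape_by_pt[first_pt]
    onset_days = np.round(onset_scale * rng.weibull(onset_shape, size=n)).astype(int)
    event_days = start_days + onset_days

    # date corruption: disjoint partial / reversed sets, deterministic sizes
    n_partial = round(n * config.partial_date_rate)
    n_reversed = round(n * config.reversed_date_rate)
    corrupt = rng.permutation(n)[: n_partial + n_reversed]
    partial_idx, reversed_idx = corrupt[:n_partial], corrupt[n_partial:]
    partial_to_month = rng.random(n_partial) < 0.5
    reversed_shift = rng.integers(1, 31, size=n_reversed)
    event_days[reversed_idx] = start_days[reversed_idx] - reversed_shift

    start_txt = np.array([_fmt_date(d) for d in start_days], dtype=object)
    for j, i in enumerate(partial_idx):
        start_txt[i] = start_txt[i][:6] if partial_to_month[j] else start_txt[i][:4]
    event_txt = np.array([_fmt_date(d) for d in event_days], dtype=object)

    # demographics (target cohort skews female: ovarian-cancer indication)
    u_sex = rng.random(n)
    sex = np.where(
        target_mask,
        np.select([u_sex < 0.95, u_sex < 0.99], ["F", "M"], default=""),
        np.select([u_sex < 0.60, u_sex < 0.98], ["F", "M"], default=""),
    )
    age = np.clip(rng.normal(63, 11, size=n), 18, 95).round(0)
    age_missing = rng.random(n) < 0.40
    weight = np.clip(rng.normal(72, 15, size=n), 35, 160).round(1)
    weight_missing = rng.random(n) < 0.70
    country = np.where(rng.random(n) < 0.95, "US", "CA")
    occp = np.select([rng.random(n) < 0.65], ["MD"], default="CN")

    demo = pd.DataFrame({
        "primaryid": primaryids,
        "caseid": caseids,
        "event_dt": event_txt,
        "age": np.where(age_missing, "", age.astype(int).astype(str)),
        "age_cod": np.where(age_missing, "", "YR"),
        "sex": sex,
        "wt": np.where(weight_missing, "", weight.astype(str)),
        "wt_cod": np.where(weight_missing, "", "KG"),
        "occr_country": country,
        "occp_cod": occp,
    })

    # duplicates: extra DEMO row, higher PRIMARYID, same CASEID
    n_dup = round(n * config.duplicate_rate)
    dup_idx = rng.permutation(n)[:n_dup]
    dup_rows = demo.iloc[sorted(dup_idx)].copy()
    dup_rows["primaryid"] = dup_rows["caseid"] + "2"
    demo = pd.concat([demo, dup_rows], ignore_index=True)

    # deleted-case list (cases remain in the tables; the reader must drop them)
    n_del = round(n * config.deleted_rate)
    deleted = sorted(caseids[rng.permutation(n)[:n_del]])

    # DRUG: PS row per case plus concomitants
    target_name_variant = rng.random(n) < 0.3  # exercise case/substring matching
    n_conc = rng.poisson(np.where(target_mask, 0.8, 0.5))
    bg_drug = rng.integers(0, len(_BACKGROUND_DRUGS), size=n)
    total_conc = int(n_conc.sum())
    conc_choices = rng.integers(0, len(_CONCOMITANT_DRUGS), size=total_conc)

    bg_names = np.array(_BACKGROUND_DRUGS, dtype=object)[bg_drug]
    ps_name = np.where(
        target_mask, np.where(target_name_variant, "rucaparib", TARGET_DRUGNAME), bg_names
    )
    ps_ai = np.where(target_mask, TARGET_PROD_AI, bg_names)
    ps_rows = pd.DataFrame({
        "primaryid": primaryids, "caseid": caseids, "drug_seq": 1,
        "role_cod": "PS", "drugname": ps_name, "prod_ai": ps_ai,
        "_case": np.arange(n),
    })
    conc_case = np.repeat(np.arange(n), n_conc)
    seq_within = np.arange(total_conc) - np.repeat(np.cumsum(n_conc) - n_conc, n_conc)
    conc_names = np.array(_CONCOMITANT_DRUGS, dtype=object)[conc_choices]
    conc_rows = pd.DataFrame({
        "primaryid": primaryids[conc_case], "caseid": caseids[conc_case],
        "drug_seq": 2 + seq_within, "role_cod": "C",
        "drugname": conc_names, "prod_ai": conc_names,
        "_case": conc_case,
    })
    drug = (
        pd.concat([ps_rows, conc_rows], ignore_index=True)
        .sort_values(["_case", "drug_seq"], kind="stable")
        .drop(columns="_case")
        .reset_index(drop=True)
    )

    # REAC from the Bernoulli matrix
    case_idx, pt_idx = np.nonzero(hits)
    reac = pd.DataFrame({
        "primaryid": primaryids[case_idx],
        "caseid": caseids[case_idx],
        "pt": [pts[j] for j in pt_idx],
    })

    ther = pd.DataFrame({
        "primaryid": primaryids,
        "caseid": caseids,
        "dsg_drug_seq": 1,
        "start_dt": start_txt,
    })

    # OUTC: ~39% serious; serious cases may list several outcome codes
    serious = rng.random(n) < 0.39
    outc_draw = rng.random((n, 5))
    codes = np.array(["HO", "DE", "LT", "DS", "OT"], dtype=object)
    thresholds = np.array([0.38, 0.13, 0.01, 0.002, 0.70])
    drawn = (outc_draw < thresholds) & serious[:, None]
    drawn[:, 4] |= serious & ~drawn.any(axis=1)  # every serious case gets >=1 code
    oc_case, oc_code = np.nonzero(drawn)
    outc = pd.DataFrame({
        "primaryid": primaryids[oc_case],
        "caseid": caseids[oc_case],
        "outc_cod": codes[oc_code],
    })

    # INDI: PS-drug indication; concomitants may carry comorbidity indications
    ind_u = rng.random(n)
    ind_bg = rng.integers(0, len(_BACKGROUND_INDICATIONS), size=n)
    comor_u = rng.random(total_conc)
    comor_pick = rng.integers(0, len(_COMORBIDITY_PTS), size=total_conc)
    cum = np.cumsum([w for _, w in _TARGET_INDICATIONS])
    target_ind = np.array([name for name, _ in _TARGET_INDICATIONS], dtype=object)[
        np.searchsorted(cum, ind_u * cum[-1])
    ]
    ps_ind = np.where(
        target_mask, target_ind, np.array(_BACKGROUND_INDICATIONS, dtype=object)[ind_bg]
    )
    ps_indi = pd.DataFrame({
        "primaryid": primaryids, "caseid": caseids, "indi_drug_seq": 1,
        "indi_pt": ps_ind, "_case": np.arange(n),
    })
    has_comor = comor_u < 0.5
    comor_rows = pd.DataFrame({
        "primaryid": primaryids[conc_case[has_comor]],
        "caseid": caseids[conc_case[has_comor]],
        "indi_drug_seq": 2 + seq_within[has_comor],
        "indi_pt": np.array(_COMORBIDITY_PTS, dtype=object)[comor_pick[has_comor]],
        "_case": conc_case[has_comor],
    })
    indi = (
        pd.concat([ps_indi, comor_rows], ignore_index=True)
        .sort_values(["_case", "indi_drug_seq"], kind="stable")
        .drop(columns="_case")
        .reset_index(drop=True)
    )

    dictionary = pd.DataFrame(
        [(pt, soc, 1) for pt, soc, _ in config.pt_catalog], columns=["pt", "soc", "is_primary"]
    )

    tables = {"demo": demo, "drug": drug, "reac": reac, "ther": ther, "outc": outc, "indi": indi}
    truth = GroundTruth(
        rr_true={pt: float(config.effect_map.get(pt, 1.0)) for pt in pts},
        onset_true=dict(config.onset_map),
        n_cases=n,
        n_target_cases=int(target_mask.sum()),
        n_duplicates=n_dup,
        n_deleted=n_del,
        n_partial_dates=n_partial,
        n_reversed_dates=n_reversed,
        table_rows={k: len(v) for k, v in tables.items()},
    )
    return SyntheticCohort(tables=tables, deleted_caseids=list(deleted),
                           dictionary=dictionary, truth=truth)


def write_cohort(cohort: SyntheticCohort, directory: str | Path, quarter: str = "22Q2") -> Path:
    """Write the cohort as FAERS-style quarterly ASCII files.

    Emits ``DEMO<quarter>.txt`` … ``INDI<quarter>.txt`` ($-delimited, header
    row), ``deleted_cases.txt`` (one CASEID per line), ``pt_to_soc.tsv`` and
    ``ground_truth.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .faers_io import TABLE_PREFIXES

    for key, prefix in TABLE_PREFIXES.items():
        cohort.tables[key].to_csv(directory / f"{prefix}{quarter}.txt", sep="$", index=False)
    (directory / "deleted_cases.txt").write_text(
        "".join(f"{cid}\n" for cid in cohort.deleted_caseids)
    )
    cohort.dictionary.to_csv(directory / "pt_to_soc.tsv", sep="\t", index=False)
    cohort.truth.to_frame().to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return directory
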