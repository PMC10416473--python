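"""End-to-end screening pipeline: read → dedup → extract → map → screen → TTO.

The run log records the case count after every filtering stage (the
"flow-diagram funnel"); all CSV outputs are deterministic for fixed
inputs, so reruns are byte-identical (timestamps appear only in the log).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import descriptives, faers_io, signal_stats, tto
from ._util import round_half_up


@dataclass
class PipelineConfig:
    """Everything one screening run needs."""

    input_dir: str
    output_dir: str
    drug_synonyms: list[str] = field(default_factory=list)
    role: str = "PS"
    levels: tuple[str, ...] = ("pt", "soc")
    min_count: int = 3
    ebgm: str = "simple"
    soc_policy: str = "primary"
    deleted_cases_file: str | None = "deleted_cases.txt"
    dictionary_file: str = "pt_to_soc.tsv"

    def validate(self) -> None:
        if not self.drug_synonyms:
            raise ValueError("drug_synonyms must be nonempty")
        if self.ebgm not in ("simple", "mgps"):
            raise ValueError("ebgm must be 'simple' or 'mgps'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Writes ``cohort_summary.csv``, ``screen_pt.csv`` / ``screen_soc.csv``,
    ``tto_soc.csv`` and ``run.log`` under ``config.output_dir``.
    """
    config.validate()  # before any I/O
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {stage}: {message}")

    tables = faers_io.read_tables(in_dir)
    for key, df in tables.items():
        log("read", f"{key} {len(df)} rows")

    deleted: list[str] = []
    if config.deleted_cases_file:
        deleted_path = in_dir / config.deleted_cases_file
        if deleted_path.exists():
            deleted = faers_io.read_deleted_cases(deleted_path)
    demo, n_removed = faers_io.deduplicate(tables["demo"], deleted)
    log("dedup", f"{n_removed} rows removed, {len(demo)} cases retained")

    target = faers_io.extract_target_cases(tables["drug"], config.drug_synonyms, config.role)
    target &= set(demo["caseid"])
    log("extract", f"{len(target)} target-drug cases (role={config.role})")

    dictionary = faers_io.load_dictionary(in_dir / config.dictionary_file)
    reac = tables["reac"][tables["reac"]["caseid"].isin(set(demo["caseid"]))]
    events = faers_io.map_pt_to_soc(reac, dictionary, policy=config.soc_policy)
    log("map", f"{len(events)} event mentions, "
               f"{events.attrs.get('n_unmapped_pts', 0)} unmapped PTs")

    for level in config.levels:
        results = signal_stats.screen(
            events, target, level=level, min_count=config.min_count, ebgm=config.ebgm
        )
        signal_stats.format_report(results).to_csv(out_dir / f"screen_{level}.csv", index=False)
        log("screen", f"level={level}: {len(results)} terms scored, "
                      f"{results.attrs['n_signals']} signals in "
                      f"{results.attrs['n_signal_socs']} SOCs")

    cases = faers_io.build_cases(tables, deleted)
    cohort = cases[cases["caseid"].isin(target)].reset_index(drop=True)
    summary = descriptives.summarize_cohort(
        cohort, drugs=tables["drug"], indications=tables["indi"], target_role=config.role
    )
    summary.to_frame().to_csv(out_dir / "cohort_summary.csv", index=False)
    log("describe", f"{summary.n_cases} cohort cases summarised")

    target_events = events[events["caseid"].isin(target)]
    samples = tto.compute_tto(cohort, tables["ther"], groups=target_events, group_col="soc")
    tto_rows = []
    for name in sorted(samples, key=lambda g: (g != "all", g)):
        s = samples[name]
        summ = tto.summarize_tto(s)
        row: dict = {
            "group": name, "n": s.n,
            "n_excluded_partial": s.n_excluded_partial,
            "n_excluded_reversed": s.n_excluded_reversed,
            "n_excluded_missing": s.n_excluded_missing,
        }
        if not summ.empty:
            row.update(median=summ.median, q1=summ.q1, q3=summ.q3, min=summ.min, max=summ.max)
        try:
            fit = tto.fit_weibull(s)
            row.update(
                alpha=round_half_up(fit.alpha, 2),
                alpha_lo=round_half_up(fit.alpha_lo95, 2),
                alpha_hi=round_half_up(fit.alpha_hi95, 2),
                beta=round_half_up(fit.beta, 2),
                beta_lo=round_half_up(fit.beta_lo95, 2),
                beta_hi=round_half_up(fit.beta_hi95, 2),
                failure_type=fit.failure_type,
            )
        except tto.WeibullFitError as exc:
            row.update(failure_type=f"unfit ({exc})")
        tto_rows.append(row)
    pd.DataFrame(tto_rows).to_csv(out_dir / "tto_soc.csv", index=False)
    log("tto", f"{len(tto_rows)} groups analysed "
               f"(all-group n={samples['all'].n})")

    (out_dir / "run.log").write_text("".join(line + "\n" for line in log_lines))
    return out_dir
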