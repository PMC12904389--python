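"""End-to-end pipeline: ingest -> cohort -> 2x2 tables -> signal CSVs.

Stages, each logged with its record counts so the report-flow arithmetic
is auditable:

1. parse the four ASCII tables (from disk or the synthetic generator);
2. deduplicate cases (latest version wins);
3. select reports naming the target drug as primary suspect, then drop
   reports with no event term (every drop logged with a reason code);
4. build per-PT and per-SOC 2x2 tables, background margins taken over
   the whole ingested database;
5. compute ROR / PRR / BCPNN / EBGM per row, apply the all-four signal
   rule, and write ranked CSVs plus descriptive summaries.

Given identical inputs (and generator seed) every output file is
byte-identical between runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import descriptives as _desc
from .cohort import CohortSpec, ExclusionLog, apply_exclusions, select_target_reports
from .contingency import ContingencyTable, PtSocMap, build_pt_tables, build_soc_tables
from .io import (DemoRecord, DrugRecord, OutcRecord, ReacRecord, TableKind,
                 deduplicate_cases, parse_ascii_table)
from .stats import IcVariance, ZeroCell, compute_all, evaluate_signal, round_half_up
from .synthetic import GeneratedTables, SyntheticConfig, generate_dataset, generate_tables

logger = logging.getLogger("faerspv")

SIGNAL_COLUMNS = [
    "level", "term", "soc", "a", "ror", "ror_l", "ror_u", "prr", "prr_l",
    "prr_u", "chi2", "ic", "ic025", "ebgm", "ebgm05",
    "ror_pass", "prr_pass", "bcpnn_pass", "ebgm_pass", "combined",
]


@dataclass(frozen=True)
class PipelineOptions:
    zero_cell: ZeroCell = "none"
    ic_variance: IcVariance = "literal"
    rounding_decimals: int = 2


@dataclass
class PipelineConfig:
    """Exactly one of ``input_dir`` / ``generator`` must be given."""

    out_dir: Path
    input_dir: Optional[Path] = None
    generator: Optional[SyntheticConfig] = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    pt_soc_map: Optional[Path] = None
    options: PipelineOptions = field(default_factory=PipelineOptions)

    def validate(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError("exactly one of input_dir / generator must be set")
        if self.input_dir is not None and self.pt_soc_map is None:
            raise ValueError("pt_soc_map is required when reading an input directory")


@dataclass
class AnalysisResult:
    cohort_ids: set[str]
    cohort_demo: list[DemoRecord]
    exclusions: ExclusionLog
    pt_signals: pd.DataFrame
    soc_signals: pd.DataFrame
    demographics: _desc.DemographicsSummary
    time_to_onset: _desc.TimeToOnsetSummary
    annual: dict

    @property
    def n_combined_positive(self) -> int:
        if self.pt_signals.empty:
            return 0
        return int(self.pt_signals["combined"].sum())

    @property
    def socs_touched(self) -> int:
        if self.pt_signals.empty:
            return 0
        return int(self.pt_signals["soc"].nunique())


@dataclass(frozen=True)
class RunSummary:
    cohort_size: int
    n_pts_evaluated: int
    n_combined_positive: int
    n_socs_touched: int
    outputs: dict[str, Path]

    def line(self) -> str:
        return (f"cohort={self.cohort_size} pts_evaluated={self.n_pts_evaluated} "
                f"combined_positive={self.n_combined_positive} "
                f"socs_touched={self.n_socs_touched}")


def signal_table(
    tables: dict[str, ContingencyTable],
    level: str,
    pt_soc: Optional[PtSocMap],
    options: PipelineOptions = PipelineOptions(),
) -> pd.DataFrame:
    """Statistics + verdicts for every term with at least one target pair."""
    rows = []
    nd = options.rounding_decimals
    for term, t in tables.items():
        if t.a < 1:
            continue
        stats = compute_all(t, options.zero_cell, options.ic_variance)
        verdict = evaluate_signal(stats)
        rows.append({
            "level": level,
            "term": term,
            "soc": pt_soc.soc_of(term) if (level == "PT" and pt_soc) else term,
            "a": t.a,
            "ror": round_half_up(stats.ror, nd),
            "ror_l": round_half_up(stats.ror_ci[0], nd),
            "ror_u": round_half_up(stats.ror_ci[1], nd),
            "prr": round_half_up(stats.prr, nd),
            "prr_l": round_half_up(stats.prr_ci[0], nd),
            "prr_u": round_half_up(stats.prr_ci[1], nd),
            "chi2": round_half_up(stats.chi2, nd),
            "ic": round_half_up(stats.ic, nd),
            "ic025": round_half_up(stats.ic025, nd),
            "ebgm": round_half_up(stats.ebgm, nd),
            "ebgm05": round_half_up(stats.ebgm05, nd),
            "ror_pass": verdict.ror_pass,
            "prr_pass": verdict.prr_pass,
            "bcpnn_pass": verdict.bcpnn_pass,
            "ebgm_pass": verdict.ebgm_pass,
            "combined": verdict.combined,
        })
    df = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    return rank_top(df, k=None)


def rank_top(signals: pd.DataFrame, level: Optional[str] = None,
             k: Optional[int] = None) -> pd.DataFrame:
    """Sort descending by ROR (ties: larger a, then term), keep the first k.

    Undefined RORs sort last.  ``k`` beyond the table length returns all
    rows.
    """
    df = signals if level is None else signals[signals["level"] == level]
    df = df.copy()
    df["_ror"] = df["ror"].fillna(float("-inf"))
    df = df.sort_values(["_ror", "a", "term"], ascending=[False, False, True],
                        kind="mergesort").drop(columns="_ror")
    df = df.reset_index(drop=True)
    return df if k is None else df.head(k)


def analyze(
    demo: Sequence[DemoRecord],
    drugs: Sequence[DrugRecord],
    reac: Sequence[ReacRecord],
    outc: Sequence[OutcRecord],
    pt_soc: PtSocMap,
    cohort_spec: CohortSpec = CohortSpec(),
    options: PipelineOptions = PipelineOptions(),
) -> AnalysisResult:
    """Run the full analysis on parsed records (no file I/O)."""
    deduped = deduplicate_cases(demo)
    logger.info("ingested %d DEMO rows -> %d unique cases", len(demo), len(deduped))
    surviving = {d.report_id for d in deduped}
    reac_kept = [r for r in reac if r.report_id in surviving]

    target_all = select_target_reports(drugs, cohort_spec)
    logger.info("target-drug reports (any version): %d", len(target_all))
    kept, excl = apply_exclusions(target_all, deduped, reac_kept)
    logger.info("cohort after exclusions: %d kept, %d excluded", len(kept),
                len(excl.entries))

    pt_tables = build_pt_tables(reac_kept, kept)
    soc_tables = build_soc_tables(reac_kept, kept, pt_soc)
    pt_df = signal_table(pt_tables, "PT", pt_soc, options)
    soc_df = signal_table(soc_tables, "SOC", None, options)
    logger.info("evaluated %d PTs (%d combined-positive), %d SOCs",
                len(pt_df), int(pt_df["combined"].sum()) if len(pt_df) else 0,
                len(soc_df))

    cohort_demo = [d for d in deduped if d.report_id in kept]
    target_drug_rows = [d for d in drugs
                        if d.report_id in kept and cohort_spec.matches_name(d)]
    return AnalysisResult(
        cohort_ids=kept,
        cohort_demo=cohort_demo,
        exclusions=excl,
        pt_signals=pt_df,
        soc_signals=soc_df,
        demographics=_desc.demographics_summary(cohort_demo, outc),
        time_to_onset=_desc.time_to_onset_bins(cohort_demo, target_drug_rows),
        annual=_desc.annual_counts(cohort_demo),
    )


def analyze_generated(
    config: SyntheticConfig,
    cohort_spec: CohortSpec = CohortSpec(),
    options: PipelineOptions = PipelineOptions(),
) -> AnalysisResult:
    """Generate a synthetic database in memory and analyze it."""
    tables = generate_tables(config)
    return analyze(
        parse_ascii_table(tables.demo, TableKind.DEMO),
        parse_ascii_table(tables.drug, TableKind.DRUG),
        parse_ascii_table(tables.reac, TableKind.REAC),
        parse_ascii_table(tables.outc, TableKind.OUTC),
        tables.pt_soc,
        cohort_spec,
        options,
    )


def _write_outputs(result: AnalysisResult, out: Path) -> dict[str, Path]:
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals_pt": out / "signals_pt.csv",
        "signals_soc": out / "signals_soc.csv",
        "descriptives": out / "descriptives.csv",
        "time_to_onset": out / "time_to_onset.csv",
        "annual_counts": out / "annual_counts.csv",
        "exclusions": out / "exclusions.csv",
    }
    result.pt_signals.to_csv(paths["signals_pt"], index=False)
    result.soc_signals.to_csv(paths["signals_soc"], index=False)
    result.demographics.write_csv(paths["descriptives"])
    tto = result.time_to_onset
    pd.DataFrame(
        {"bin": list(tto.counts), "count": list(tto.counts.values())}
    ).to_csv(paths["time_to_onset"], index=False)
    pd.DataFrame(
        {"year": list(result.annual), "count": list(result.annual.values())}
    ).to_csv(paths["annual_counts"], index=False)
    result.exclusions.write_csv(paths["exclusions"])
    return paths


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the pipeline per the config and write the output bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if config.generator is not None:
            data_dir = out / "data"
            generate_dataset(config.generator, data_dir)
            logger.info("generated synthetic dataset in %s (seed=%d)",
                        data_dir, config.generator.seed)
            input_dir = data_dir
            map_path = config.pt_soc_map or data_dir / "pt_soc_map.csv"
        else:
            input_dir = Path(config.input_dir)
            map_path = Path(config.pt_soc_map)

        records = {}
        for kind in TableKind:
            path = input_dir / f"{kind.value}.txt"
            if not path.exists():
                raise FileNotFoundError(f"missing input table: {path}")
            with open(path) as fh:
                records[kind] = parse_ascii_table(fh, kind)
        pt_soc = PtSocMap.from_csv(map_path)

        result = analyze(records[TableKind.DEMO], records[TableKind.DRUG],
                         records[TableKind.REAC], records[TableKind.OUTC],
                         pt_soc, config.cohort, config.options)
        paths = _write_outputs(result, out)
        paths["run_log"] = log_path
        summary = RunSummary(
            cohort_size=len(result.cohort_ids),
            n_pts_evaluated=len(result.pt_signals),
            n_combined_positive=result.n_combined_positive,
            n_socs_touched=len(result.soc_signals),
            outputs=paths,
        )
        logger.info("summary: %s", summary.line())
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------

def _generator_from_dict(d: dict) -> SyntheticConfig:
    cfg = SyntheticConfig()
    known = set(SyntheticConfig.__dataclass_fields__)
    for key, value in d.items():
        if key not in known:
            raise ValueError(f"unknown generator option: {key}")
        if key == "date_range":
            import datetime as _dt
            value = tuple(
                v if isinstance(v, _dt.date) else _dt.date.fromisoformat(str(v))
                for v in value
            )
        if key == "injected_signals":
            value = tuple((str(pt), float(rr)) for pt, rr in value)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def load_config(path: Union[str, Path], out_dir: Union[str, Path, None] = None,
                seed: Optional[int] = None) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file.

    ``out_dir`` and ``seed`` given on the command line override the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    generator = _generator_from_dict(raw["generate"]) if "generate" in raw else None
    if generator is not None and seed is not None:
        generator.seed = seed
    cohort = CohortSpec(
        target_names=tuple(raw.get("target_names", CohortSpec().target_names))
    )
    options = PipelineOptions(
        zero_cell=raw.get("zero_cell", "none"),
        ic_variance=raw.get("ic_variance", "literal"),
    )
    cfg = PipelineConfig(
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "out")),
        input_dir=Path(raw["input_dir"]) if "input_dir" in raw else None,
        generator=generator,
        cohort=cohort,
        pt_soc_map=Path(raw["pt_soc_map"]) if "pt_soc_map" in raw else None,
        options=options,
    )
    cfg.validate()
    return cfg
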