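"""Synthetic spontaneous-reporting database with known signal structure.

Emulates the shape of a FAERS extract — DEMO/DRUG/REAC/OUTC quarterly
ASCII tables — for a multi-drug, multi-PT database with one designated
target drug.  Ground truth is controlled: each report names the target
drug as primary suspect with a configurable probability, and the
preferred terms of target-drug reports are drawn from the baseline PT
distribution with selected terms up-weighted by a known relative
reporting rate (then renormalized).  Setting every injected rate to 1
yields a null database for false-positive control.

Realism choices (and their limits): report counts per PT are governed by
a truncated-geometric number of reactions per report (mean just under
2); demographic fields carry missingness at configurable rates; receipt
dates are uniform over the extraction window; therapy start precedes
event onset by an exponential gap so time-to-onset bins are populated; a
fraction of cases is emitted twice with an incremented version number to
exercise deduplication.  Lexical drug-name noise and country structure
are deliberately absent.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .contingency import PtSocMap, unique_pairs
from .io import ReacRecord, TableKind

#: System organ classes used for the default PT -> SOC assignment.
DEFAULT_SOCS = (
    "Vascular disorders",
    "Nervous system disorders",
    "Musculoskeletal and connective tissue disorders",
    "Surgical and medical procedures",
    "Investigations",
    "Cardiac disorders",
    "Skin and subcutaneous tissue disorders",
    "Injury, poisoning and procedural complications",
    "General disorders and administration site conditions",
    "Gastrointestinal disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Renal and urinary disorders",
    "Blood and lymphatic system disorders",
    "Psychiatric disorders",
    "Infections and infestations",
    "Eye disorders",
    "Metabolism and nutrition disorders",
    "Hepatobiliary disorders",
    "Immune system disorders",
)

DEFAULT_TARGET_DRUG = "VORAPAXAR"
DEFAULT_TARGET_INGREDIENT = "VORAPAXAR SULFATE"

_DEFAULT_MISSINGNESS = {
    "sex": 0.23,
    "age": 0.67,
    "event_date": 0.30,
    "therapy_start": 0.80,
    "occupation": 0.01,
}
_DEFAULT_OUTCOME_PROBS = {
    "HO": 0.44, "OT": 0.32, "DE": 0.12, "LT": 0.06, "DS": 0.05, "RI": 0.01,
}


class ConfigError(ValueError):
    """Synthetic configuration failed validation; names the bad field."""


def default_pt_labels(n_pts: int) -> list[str]:
    width = max(4, len(str(n_pts)))
    return [f"PT_{i + 1:0{width}d}" for i in range(n_pts)]


def default_pt_soc_assignment(pt_labels: Sequence[str]) -> dict[str, str]:
    return {pt: DEFAULT_SOCS[i % len(DEFAULT_SOCS)] for i, pt in enumerate(pt_labels)}


@dataclass
class SyntheticConfig:
    """Full parameterization of the generator.

    The defaults describe the standard study conditions used throughout
    the test suite: 5,000 reports, a 4% target-drug share, 800 preferred
    terms with uniform baseline weights, and just under two reactions
    per report — under which a single injected relative reporting rate
    of 30 yields an expected target-event count around 14.
    """

    n_reports: int = 5000
    n_background_drugs: int = 40
    n_pts: int = 800
    pt_soc_assignment: Optional[dict[str, str]] = None
    target_drug_share: float = 0.04
    baseline_pt_weights: Optional[Sequence[float]] = None
    injected_signals: tuple[tuple[str, float], ...] = ()
    pts_per_report_distribution: dict = field(
        default_factory=lambda: {"kind": "truncated_geometric", "p": 0.5, "max": 8}
    )
    missingness_rates: dict = field(default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2004, 1, 1), _dt.date(2024, 12, 31))
    duplicate_fraction: float = 0.05
    outcome_report_fraction: float = 0.54
    outcome_probs: dict = field(default_factory=lambda: dict(_DEFAULT_OUTCOME_PROBS))
    target_drug_name: str = DEFAULT_TARGET_DRUG
    target_ingredient: str = DEFAULT_TARGET_INGREDIENT
    seed: int = 0

    # -- derived vocabularies -------------------------------------------------
    @property
    def pt_labels(self) -> list[str]:
        if self.pt_soc_assignment is not None:
            return sorted(self.pt_soc_assignment)
        return default_pt_labels(self.n_pts)

    def resolved_pt_soc(self) -> dict[str, str]:
        if self.pt_soc_assignment is not None:
            return dict(self.pt_soc_assignment)
        return default_pt_soc_assignment(self.pt_labels)

    def resolved_weights(self) -> np.ndarray:
        labels = self.pt_labels
        if self.baseline_pt_weights is None:
            return np.full(len(labels), 1.0 / len(labels))
        return np.asarray(self.baseline_pt_weights, dtype=float)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be a non-negative integer")
        if self.n_background_drugs < 1:
            raise ConfigError("n_background_drugs must be a positive integer")
        if self.pt_soc_assignment is None and self.n_pts < 1:
            raise ConfigError("n_pts must be a positive integer")
        if not 0 < self.target_drug_share < 1:
            raise ConfigError("target_drug_share must lie in (0, 1)")
        labels = self.pt_labels
        w = self.resolved_weights()
        if len(w) != len(labels):
            raise ConfigError("baseline_pt_weights length must equal the number of PTs")
        if np.any(w < 0) or abs(float(w.sum()) - 1.0) > 1e-9:
            raise ConfigError("baseline_pt_weights must be non-negative and sum to 1")
        label_set = set(labels)
        for pt, rr in self.injected_signals:
            if pt not in label_set:
                raise ConfigError(f"injected_signals: PT {pt!r} not in pt_soc_assignment")
            if rr < 1:
                raise ConfigError(f"injected_signals: relative rate for {pt!r} must be >= 1")
        dist = self.pts_per_report_distribution
        if dist.get("kind") != "truncated_geometric":
            raise ConfigError("pts_per_report_distribution: unknown kind")
        if not 0 < dist.get("p", 0) <= 1 or dist.get("max", 0) < 1:
            raise ConfigError("pts_per_report_distribution: need 0 < p <= 1 and max >= 1")
        for name, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigError(f"missingness_rates[{name!r}] must lie in [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise ConfigError("date_range start must not exceed end")
        if not 0 <= self.duplicate_fraction < 1:
            raise ConfigError("duplicate_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class GeneratedTables:
    """In-memory file images of one generated dataset."""

    demo: str
    drug: str
    reac: str
    outc: str
    pt_soc: PtSocMap

    def text(self, kind: TableKind) -> str:
        return getattr(self, kind.value.lower())


def _target_pt_weights(base: np.ndarray, labels: Sequence[str],
                       injected: Sequence[tuple[str, float]]) -> np.ndarray:
    w = base.copy()
    idx = {pt: i for i, pt in enumerate(labels)}
    for pt, rr in injected:
        w[idx[pt]] *= rr
    return w / w.sum()


def generate_tables(config: SyntheticConfig) -> GeneratedTables:
    """Generate the four table images for one configuration.

    Identical config (including seed) always yields identical text.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.pt_labels
    base_w = config.resolved_weights()
    target_w = _target_pt_weights(base_w, labels, config.injected_signals)
    miss = {**_DEFAULT_MISSINGNESS, **config.missingness_rates}
    dist = config.pts_per_report_distribution
    start, end = config.date_range
    span = (end - start).days
    outc_codes = list(config.outcome_probs)
    outc_p = np.array([config.outcome_probs[k] for k in outc_codes], float)
    outc_p = outc_p / outc_p.sum()
    bg_drugs = [f"DRUG_{i + 1:03d}" for i in range(config.n_background_drugs)]

    demo_rows: list[list[str]] = []
    drug_rows: list[list[str]] = []
    reac_rows: list[list[str]] = []
    outc_rows: list[list[str]] = []

    def emit_report(pid: str, caseid: str, version: int, fda: _dt.date,
                    event: Optional[_dt.date], age: str, sex: str, occp: str,
                    country: str, ps_name: str, ps_ai: str,
                    therapy: Optional[_dt.date], concomitants: list[str],
                    pts: list[str], outcome: Optional[str]) -> None:
        demo_rows.append([
            pid, caseid, str(version), fda.strftime("%Y%m%d"),
            event.strftime("%Y%m%d") if event else "", age, "YR" if age else "",
            sex, occp, country,
        ])
        drug_rows.append([
            pid, "1", "PS", ps_name, ps_ai,
            therapy.strftime("%Y%m%d") if therapy else "",
        ])
        for j, name in enumerate(concomitants, start=2):
            drug_rows.append([pid, str(j), "C", name, "", ""])
        for pt in pts:
            reac_rows.append([pid, pt])
        if outcome is not None:
            outc_rows.append([pid, outcome])

    for i in range(config.n_reports):
        caseid = str(10_000_000 + i)
        is_target = rng.random() < config.target_drug_share

        fda = start + _dt.timedelta(days=int(rng.integers(0, span + 1)))
        event: Optional[_dt.date] = None
        if rng.random() >= miss["event_date"]:
            event = fda - _dt.timedelta(days=int(rng.integers(0, 91)))
            if event < start:
                event = start
        therapy: Optional[_dt.date] = None
        if event is not None and rng.random() >= miss["therapy_start"]:
            therapy = event - _dt.timedelta(days=int(rng.exponential(30.0)))

        sex = "" if rng.random() < miss["sex"] else ("M" if rng.random() < 0.67 else "F")
        age = ""
        if rng.random() >= miss["age"]:
            age = str(int(np.clip(rng.normal(62, 12), 18, 95)))
        occp = "" if rng.random() < miss["occupation"] else str(
            rng.choice(["CN", "MD", "OT", "PH"], p=[0.59, 0.17, 0.14, 0.10])
        )
        country = "US" if rng.random() < 0.98 else ""

        if is_target:
            ps_name, ps_ai = config.target_drug_name, config.target_ingredient
            weights = target_w
        else:
            ps_name = bg_drugs[int(rng.integers(0, len(bg_drugs)))]
            ps_ai = ""
            weights = base_w
        n_con = int(rng.poisson(0.7))
        concomitants = [bg_drugs[int(k)] for k in rng.integers(0, len(bg_drugs), n_con)]

        k = min(int(rng.geometric(dist["p"])), int(dist["max"]))
        drawn = rng.choice(len(labels), size=k, replace=True, p=weights)
        pts = [labels[j] for j in sorted(set(int(x) for x in drawn))]

        outcome = None
        if rng.random() < config.outcome_report_fraction:
            outcome = outc_codes[int(rng.choice(len(outc_codes), p=outc_p))]

        emit_report(caseid + "1", caseid, 1, fda, event, age, sex, occp, country,
                    ps_name, ps_ai, therapy, concomitants, pts, outcome)
        if rng.random() < config.duplicate_fraction:
            fda2 = fda + _dt.timedelta(days=int(rng.integers(1, 31)))
            emit_report(caseid + "2", caseid, 2, fda2, event, age, sex, occp,
                        country, ps_name, ps_ai, therapy, concomitants, pts, outcome)

    from .io import TABLE_COLUMNS  # local import avoids a cycle at module load

    def render(kind: TableKind, rows: list[list[str]]) -> str:
        lines = ["$".join(TABLE_COLUMNS[kind])]
        lines.extend("$".join(r) for r in rows)
        return "\n".join(lines) + "\n"

    return GeneratedTables(
        demo=render(TableKind.DEMO, demo_rows),
        drug=render(TableKind.DRUG, drug_rows),
        reac=render(TableKind.REAC, reac_rows),
        outc=render(TableKind.OUTC, outc_rows),
        pt_soc=PtSocMap(config.resolved_pt_soc()),
    )


def generate_dataset(config: SyntheticConfig, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC tables plus the PT->SOC map to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = generate_tables(config)
    paths = {}
    for kind in TableKind:
        p = out / f"{kind.value}.txt"
        p.write_text(tables.text(kind))
        paths[kind.value] = p
    map_path = out / "pt_soc_map.csv"
    tables.pt_soc.to_csv(map_path)
    paths["PT_SOC_MAP"] = map_path
    return paths


def empirical_relative_rate(reac: Sequence[ReacRecord], target_set: set[str],
                            pt: str) -> float:
    """Observed reporting-rate ratio for one PT: target share / background share."""
    pairs = unique_pairs(reac)
    a = sum(1 for rid, p in pairs if p == pt and rid in target_set)
    b = sum(1 for rid, p in pairs if p == pt and rid not in target_set)
    c = sum(1 for rid, p in pairs if p != pt and rid in target_set)
    d = sum(1 for rid, p in pairs if p != pt and rid not in target_set)
    if a + c == 0 or b + d == 0 or b == 0:
        return float("nan")
    return (a / (a + c)) / (b / (b + d))
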