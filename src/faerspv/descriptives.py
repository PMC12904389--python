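"""Descriptive summaries of a spontaneous-report cohort.

Covers sex, age bins (<18, 18-65, >65), reporter occupation and country,
outcome severity, time to onset (days from therapy start to event onset,
binned <7 / 7-28 / 28-60 / >60) and annual report counts.

Two proportion conventions coexist in published descriptive tables:
dividing by the full cohort size, and dividing by the number of reports
where the characteristic is known.  Both are computed for every block;
neither is declared canonical.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .io import DemoRecord, DrugRecord, DrugRole, Occupation, OutcRecord, Sex
from .stats import round_half_up

#: One outcome per case, most severe first.
OUTCOME_SEVERITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

AGE_BINS = ("<18", "18-65", ">65", "unknown")
TTO_BINS = ("<7", "7-28", "28-60", ">60", "unknown")

_AGE_YEARS_PER_UNIT = {
    "YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.1775,
    "DY": 1 / 365.25, "HR": 1 / 8765.8,
}

_UNKNOWN_LABELS = {"unknown", "not reported"}


@dataclass(frozen=True)
class CategoryStat:
    count: int
    proportion: float        # count / cohort size, 2 dp
    percent: float           # 100 * count / cohort size, 2 dp
    proportion_known: float  # count / reports with the field known, 2 dp


@dataclass
class DemographicsSummary:
    cohort_size: int
    blocks: dict[str, dict[str, CategoryStat]] = field(default_factory=dict)

    def write_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["characteristic", "category", "count",
                        "proportion", "percent", "proportion_known"])
            for block, cats in self.blocks.items():
                for cat, s in cats.items():
                    w.writerow([block, cat, s.count, f"{s.proportion:.2f}",
                                f"{s.percent:.2f}", f"{s.proportion_known:.2f}"])


def _block(counts: dict[str, int], cohort_size: int) -> dict[str, CategoryStat]:
    known = sum(v for k, v in counts.items() if k not in _UNKNOWN_LABELS)
    out = {}
    for cat, n in counts.items():
        prop = n / cohort_size if cohort_size else 0.0
        prop_known = (n / known) if (known and cat not in _UNKNOWN_LABELS) else 0.0
        out[cat] = CategoryStat(
            count=n,
            proportion=round_half_up(prop, 2),
            percent=round_half_up(100 * prop, 2),
            proportion_known=round_half_up(prop_known, 2),
        )
    return out


def age_in_years(rec: DemoRecord) -> Optional[float]:
    if rec.age_value is None:
        return None
    factor = _AGE_YEARS_PER_UNIT.get(rec.age_unit or "YR")
    if factor is None:
        return None
    return rec.age_value * factor


def _age_bin(rec: DemoRecord) -> str:
    years = age_in_years(rec)
    if years is None:
        return "unknown"
    if years < 18:
        return "<18"
    if years <= 65:
        return "18-65"
    return ">65"


def demographics_summary(
    demo: Sequence[DemoRecord], outc: Sequence[OutcRecord] = ()
) -> DemographicsSummary:
    """Tally the cohort by the closed vocabularies.

    ``demo`` must be the deduplicated cohort; outcome rows are reduced to
    one code per report by severity precedence, and reports with no
    outcome row fall in a "not reported" category so every block's
    counts sum to the cohort size.
    """
    n = len(demo)
    summary = DemographicsSummary(cohort_size=n)

    sex_counts = Counter(r.sex.value for r in demo)
    summary.blocks["sex"] = _block(
        {s.value: sex_counts.get(s.value, 0) for s in Sex}, n
    )

    age_counts = Counter(_age_bin(r) for r in demo)
    summary.blocks["age"] = _block({b: age_counts.get(b, 0) for b in AGE_BINS}, n)

    occ_counts = Counter(r.occupation.value for r in demo)
    summary.blocks["reporter"] = _block(
        {o.value: occ_counts.get(o.value, 0) for o in Occupation}, n
    )

    country_counts = Counter(r.country or "unknown" for r in demo)
    summary.blocks["reporter_country"] = _block(dict(sorted(country_counts.items())), n)

    cohort_ids = {r.report_id for r in demo}
    sev = {code: i for i, code in enumerate(OUTCOME_SEVERITY)}
    worst: dict[str, str] = {}
    for rec in outc:
        if rec.report_id not in cohort_ids:
            continue
        cur = worst.get(rec.report_id)
        if cur is None or sev[rec.outcome_code] < sev[cur]:
            worst[rec.report_id] = rec.outcome_code
    outcome_counts = Counter(worst.values())
    block = {code: outcome_counts.get(code, 0) for code in OUTCOME_SEVERITY}
    block["not reported"] = n - len(worst)
    summary.blocks["outcome"] = _block(block, n)

    for name, cats in summary.blocks.items():
        total = sum(s.count for s in cats.values())
        assert total == n, f"block {name!r} counts {total} != cohort size {n}"
    return summary


@dataclass(frozen=True)
class TimeToOnsetSummary:
    counts: dict[str, int]
    negative_gaps: int  # therapy start after event onset; counted as unknown


def time_to_onset_bins(
    demo: Sequence[DemoRecord],
    drugs: Sequence[DrugRecord],
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> TimeToOnsetSummary:
    """Bin days from (earliest) suspect-drug therapy start to event onset.

    Partial or missing dates on either side put the case in the unknown
    bin; a negative gap is also unknown but tallied separately as a data
    quality warning.
    """
    starts: dict[str, object] = {}
    for d in drugs:
        if d.role != role or d.therapy_start_date is None:
            continue
        cur = starts.get(d.report_id)
        if cur is None or d.therapy_start_date < cur:
            starts[d.report_id] = d.therapy_start_date

    counts = {b: 0 for b in TTO_BINS}
    negative = 0
    for rec in demo:
        start = starts.get(rec.report_id)
        if rec.event_date is None or start is None:
            counts["unknown"] += 1
            continue
        days = (rec.event_date - start).days
        if days < 0:
            negative += 1
            counts["unknown"] += 1
        elif days < 7:
            counts["<7"] += 1
        elif days <= 28:
            counts["7-28"] += 1
        elif days <= 60:
            counts["28-60"] += 1
        else:
            counts[">60"] += 1
    return TimeToOnsetSummary(counts=counts, negative_gaps=negative)


def annual_counts(demo: Sequence[DemoRecord]) -> dict:
    """Report counts by year received; unknown years bucketed separately."""
    out: Counter = Counter()
    for rec in demo:
        out[rec.received_date.year if rec.received_date else "unknown"] += 1
    return dict(sorted(out.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])))
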