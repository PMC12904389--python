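"""Analysis-cohort selection: target-drug reports minus exclusions.

Three exclusion rules shape the cohort: (1) the drug of interest must be
listed in a suspect role (primary suspect by default) — enforced by
``select_target_reports``; (2) reports carrying no event preferred term
are dropped; (3) superseded case versions are dropped by deduplication
upstream.  Missing demographics alone never exclude a report: in
spontaneous-reporting practice large fractions of age and sex are
unknown, and those cases still carry event information.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Set, Union

from .io import DemoRecord, DrugRecord, DrugRole, ReacRecord

DEFAULT_TARGET_NAMES = ("vorapaxar", "zontivity")


@dataclass(frozen=True)
class CohortSpec:
    """Which drug names and role codes define the target cohort."""

    target_names: tuple[str, ...] = DEFAULT_TARGET_NAMES
    role_filter: frozenset[DrugRole] = frozenset({DrugRole.PRIMARY_SUSPECT})
    require_pt: bool = True

    def __post_init__(self):
        if not self.target_names:
            raise ValueError("target_names must be nonempty")

    def matches_name(self, record: DrugRecord) -> bool:
        hay = [record.verbatim_name.lower()]
        if record.active_ingredient:
            hay.append(record.active_ingredient.lower())
        return any(pat.lower() in h for pat in self.target_names for h in hay)


@dataclass(frozen=True)
class ExclusionEntry:
    report_id: str
    reason_code: str


@dataclass
class ExclusionLog:
    entries: list[ExclusionEntry] = field(default_factory=list)

    def add(self, report_id: str, reason: str) -> None:
        self.entries.append(ExclusionEntry(report_id, reason))

    def write_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["report_id", "reason_code"])
            for e in self.entries:
                w.writerow([e.report_id, e.reason_code])


def select_target_reports(
    drugs: Sequence[DrugRecord], spec: CohortSpec = CohortSpec()
) -> Set[str]:
    """Report ids where a drug record matches a target name in a kept role.

    Matching is a case-insensitive substring test on the verbatim name and
    on the active ingredient, so salt forms ("vorapaxar sulfate") and brand
    names both hit.
    """
    return {
        r.report_id
        for r in drugs
        if r.role in spec.role_filter and spec.matches_name(r)
    }


def apply_exclusions(
    cohort: Set[str],
    demo: Sequence[DemoRecord],
    reac: Sequence[ReacRecord],
) -> tuple[Set[str], ExclusionLog]:
    """Drop cohort reports without event terms or eliminated by dedup.

    ``demo`` must already be deduplicated; a cohort report id absent from
    it is a superseded case version.  Reports with zero REAC preferred
    terms carry no analyzable event and are dropped.  Every drop is
    logged with a reason code; kept and excluded ids partition the input.
    """
    surviving = {d.report_id for d in demo}
    with_pt = {r.report_id for r in reac if r.pt}
    kept: Set[str] = set()
    log = ExclusionLog()
    for rid in sorted(cohort):
        if rid not in surviving:
            log.add(rid, "superseded_duplicate")
        elif rid not in with_pt:
            log.add(rid, "no_event_term")
        else:
            kept.add(rid)
    return kept, log
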