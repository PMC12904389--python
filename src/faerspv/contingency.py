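"""2x2 contingency tables for drug-event disproportionality.

The counting unit throughout is the unique (report, PT) pair: a report
listing k distinct preferred terms contributes k pairs to the database
margins.  For an index event E and a target-drug report set T:

    a = pairs from T with E          b = pairs outside T with E
    c = pairs from T without E       d = pairs outside T without E

SOC-level tables roll the same pairs up by system organ class; each pair
contributes to exactly one SOC (no per-report SOC deduplication).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Set, Union

from .io import ReacRecord


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class PtSocMap:
    """Total PT -> SOC lookup; querying an unmapped PT is an error."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return pt in self._map

    def soc_of(self, pt: str) -> str:
        try:
            return self._map[pt]
        except KeyError:
            raise KeyError(f"PT {pt!r} has no SOC assignment") from None

    def items(self):
        return self._map.items()

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PtSocMap":
        """Read a two-column (pt, soc) CSV, with or without a header."""
        mapping = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if len(row) < 2 or (not mapping and row[0].strip().lower() == "pt"):
                    continue
                mapping[row[0].strip()] = row[1].strip()
        return cls(mapping)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pt", "soc"])
            for pt, soc in sorted(self._map.items()):
                w.writerow([pt, soc])


def unique_pairs(reac: Iterable[ReacRecord]) -> Set[tuple[str, str]]:
    """Distinct (report_id, PT) pairs; repeated listings count once."""
    return {(r.report_id, r.pt) for r in reac if r.pt}


def _tables_from_pairs(
    pairs: Set[tuple[str, str]],
    target_set: Set[str],
    key_of,
) -> dict[str, ContingencyTable]:
    tgt = Counter()
    oth = Counter()
    for rid, pt in pairs:
        (tgt if rid in target_set else oth)[key_of(pt)] += 1
    total_tgt = sum(tgt.values())
    total_oth = sum(oth.values())
    tables = {}
    for key in sorted(set(tgt) | set(oth)):
        a = tgt.get(key, 0)
        b = oth.get(key, 0)
        tables[key] = ContingencyTable(a=a, b=b, c=total_tgt - a, d=total_oth - b)
    return tables


def build_pt_tables(
    reac: Sequence[ReacRecord], target_set: Set[str]
) -> dict[str, ContingencyTable]:
    """One 2x2 table per preferred term versus the target-drug report set."""
    pairs = unique_pairs(reac)
    if not pairs:
        return {}
    return _tables_from_pairs(pairs, target_set, lambda pt: pt)


def build_soc_tables(
    reac: Sequence[ReacRecord], target_set: Set[str], pt_soc: PtSocMap
) -> dict[str, ContingencyTable]:
    """One 2x2 table per system organ class, rolling pairs up via the map."""
    pairs = unique_pairs(reac)
    if not pairs:
        return {}
    return _tables_from_pairs(pairs, target_set, pt_soc.soc_of)
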