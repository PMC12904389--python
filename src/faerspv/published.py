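"""Published vorapaxar reference values used for validation.

A published FAERS disproportionality study of vorapaxar (extraction
window 2004 Q1 - 2024 Q4; 185 deduplicated reports) reports descriptive
counts and a top-ten preferred-term signal table.  Those printed numbers
are embedded here as validation inputs: the descriptive counts drive
round-trip checks of the proportion logic, and the signal rows drive the
IC = log2(EBGM) identity check and the contingency back-solver.

The underlying raw extract is not redistributable, so database-level
headline counts (total reports, total positive signals) cannot be
recomputed here; only the per-row arithmetic is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

COHORT_SIZE = 185

SEX_COUNTS = {"male": 96, "female": 47, "unknown": 42}
AGE_COUNTS = {"<18": 0, "18-65": 26, ">65": 35, "unknown": 124}
REPORTER_COUNTS = {
    "consumer": 108,
    "physician": 32,
    "other health-professional": 25,
    "pharmacist": 19,
    "unknown": 1,
}
COUNTRY_COUNTS = {"US": 181, "unknown": 4}
#: One (most severe) outcome per outcome-reporting case.
OUTCOME_COUNTS = {"HO": 44, "OT": 32, "DE": 12, "LT": 6, "DS": 5, "RI": 1}
TTO_COUNTS = {"<7": 2, "7-28": 8, "28-60": 6, ">60": 9, "unknown": 160}


@dataclass(frozen=True)
class PublishedSignalRow:
    """One printed row of the top-ten PT signal table."""

    term: str
    n: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float


TOP_PT_SIGNALS: tuple[PublishedSignalRow, ...] = (
    PublishedSignalRow("amyotrophic lateral sclerosis", 3, 298.14, (95.53, 930.52),
                       295.19, (95.65, 910.97), 8.2, 0.52, 294.72, 94.43),
    PublishedSignalRow("gastrointestinal haemorrhage", 14, 34.27, (20.04, 58.6),
                       32.73, (19.62, 54.59), 5.03, 2.61, 32.72, 19.14),
    PublishedSignalRow("epistaxis", 11, 30.96, (16.95, 56.52),
                       29.86, (16.72, 53.35), 4.9, 2.26, 29.86, 16.35),
    PublishedSignalRow("dysstasia", 4, 27.74, (10.34, 74.4),
                       27.38, (10.34, 72.49), 4.78, 0.81, 27.4, 10.21),
    PublishedSignalRow("surgery", 4, 15.52, (5.79, 41.63),
                       15.33, (5.79, 40.58), 3.94, 0.67, 15.33, 5.71),
    PublishedSignalRow("haemorrhage", 7, 14.21, (6.71, 30.06),
                       13.9, (6.68, 28.91), 3.8, 1.36, 13.9, 6.57),
    PublishedSignalRow("rectal haemorrhage", 3, 14.17, (4.55, 44.20),
                       14.04, (4.55, 43.30), 3.81, 0.26, 14.04, 4.50),
    PublishedSignalRow("haematochezia", 3, 11.51, (3.69, 35.89),
                       11.41, (3.70, 35.17), 3.51, 0.20, 11.4, 3.66),
    PublishedSignalRow("haemoglobin decreased", 5, 9.88, (4.08, 23.91),
                       9.73, (4.08, 23.21), 3.28, 0.78, 9.73, 4.02),
    PublishedSignalRow("drug dose omission", 8, 9.13, (4.53, 18.44),
                       8.92, (4.50, 17.67), 3.16, 1.25, 8.92, 4.42),
)


def descriptive_fixture():
    """Synthetic 185-case cohort reproducing the published descriptive margins.

    Builds DemoRecord/OutcRecord/DrugRecord lists whose sex, age-bin,
    reporter, country, outcome and time-to-onset tallies equal the printed
    counts, so the summary logic can be validated against the printed
    proportions.  Attributes are assigned independently block by block;
    no joint structure is implied.
    """
    import datetime as _dt

    from .io import DemoRecord, DrugRecord, DrugRole, Occupation, Sex

    def expand(counts):
        out = []
        for key, n in counts.items():
            out.extend([key] * n)
        return out

    sexes = expand({Sex.MALE: 96, Sex.FEMALE: 47, Sex.UNKNOWN: 42})
    ages = expand({None: 124, 50.0: 26, 75.0: 35})  # unknown / 18-65 / >65
    occs = expand({
        Occupation.CONSUMER: 108, Occupation.PHYSICIAN: 32,
        Occupation.OTHER_HEALTH_PROFESSIONAL: 25, Occupation.PHARMACIST: 19,
        Occupation.UNKNOWN: 1,
    })
    countries = expand({"US": 181, None: 4})
    gaps = expand({3: 2, 10: 8, 40: 6, 100: 9, None: 160})
    outcome_codes = expand(OUTCOME_COUNTS)  # 100 cases; the rest report none

    base_event = _dt.date(2015, 6, 1)
    demo, outc, drugs = [], [], []
    for i in range(COHORT_SIZE):
        rid = f"F{i:03d}"
        gap = gaps[i]
        event = base_event if gap is not None else None
        demo.append(DemoRecord(
            report_id=rid, case_id=rid, case_version=1,
            received_date=_dt.date(2015, 7, 1), event_date=event,
            received_raw="20150701",
            event_raw="20150601" if event else "",
            age_value=ages[i], age_unit="YR" if ages[i] is not None else None,
            sex=sexes[i], occupation=occs[i], country=countries[i],
        ))
        start = event - _dt.timedelta(days=gap) if gap is not None else None
        drugs.append(DrugRecord(
            report_id=rid, drug_seq=1, role=DrugRole.PRIMARY_SUSPECT,
            verbatim_name="VORAPAXAR", active_ingredient="VORAPAXAR SULFATE",
            therapy_start_date=start,
        ))
        if i < len(outcome_codes):
            from .io import OutcRecord
            outc.append(OutcRecord(report_id=rid, outcome_code=outcome_codes[i]))
    return demo, outc, drugs
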