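# Methods

## Setting and counting model

Spontaneous-reporting databases such as FAERS accumulate voluntary
reports, each naming one or more drugs (with role codes) and one or more
adverse-event preferred terms (PTs, MedDRA semantics). Disproportionality
analysis asks whether a drug–event pair is reported more often than the
database background predicts. The counting unit here is the unique
(report, PT) pair: a report listing k distinct PTs contributes k pairs.
This is the standard convention under which a per-PT count "n" (= a) and
database-wide margins are mutually coherent; it also means one report
can contribute to several SOC-level tables through different PTs, and a
pair contributes to exactly one SOC. Whether SOC roll-ups should instead
deduplicate multiple same-SOC PTs within a report is not settled usage;
the pair-level roll-up is this package's documented choice.

Background margins (b, d) are computed over the entire ingested
database — all quarters, all drugs — not over any subset, matching the
full-extraction-window design the pipeline emulates.

## Cohort construction

A report enters the cohort when some drug record matches a target-name
pattern (case-insensitive substring over verbatim name and active
ingredient, so salt forms and brand names match) **and** carries the
primary-suspect role. Deduplication keeps, per case identifier, the
highest version number, breaking ties by latest receipt date then
largest report id; this is the standard convention for versioned
spontaneous reports ("report numbers and core information" comparisons
vary between analyses, and the exact key used elsewhere is not
recoverable). Reports with no event PT are excluded with reason code
`no_event_term`; superseded versions with `superseded_duplicate`.
Missing demographics never exclude a report — published cohorts of this
kind retain large age- and sex-unknown fractions, so missingness was
evidently tolerated at source.

## The four statistics

With cells a, b, c, d and N = a+b+c+d:

- ROR = ad/(bc); 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- PRR = a(c+d)/(c(a+b)); χ² is the uncorrected Pearson statistic
  (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)). Published threshold tables state a
  PRR CI criterion without printing a CI formula; the standard log-PRR
  delta-method standard error √(1/a − 1/(a+b) + 1/c − 1/(c+d)) is used.
  χ² is reported but does not gate the PRR verdict, since the threshold
  column of the source criteria names only a, PRR and the CI.
- BCPNN: the reported point IC is the unshrunk log₂(aN/((a+c)(a+b))) —
  in published tables the printed IC equals log₂ of the printed EBGM
  row by row, which identifies the unshrunk form. Shrinkage enters via
  r = N²/((a+b+1)(a+c+1)), E(IC) = log₂(aN²/((N+r)(a+b)(a+c))) and
  V(IC) = k·[(b+c+d+r−1)/((a+1)(N+r+1)) + (2+b+c+2d)/((a+b+1)(N+r+3))],
  with IC025 = E(IC) − 2√V(IC). The printed V(IC) formula circulating in
  the applied literature is typographically ambiguous about whether the
  1/ln 2 factor is squared and what it multiplies; the default takes
  k = 1/ln 2 applied to the whole bracket (the closest literal reading),
  and `variance="bate"` switches to k = 1/ln(2)², the delta-method
  scaling from natural log to log₂ used in the classical BCPNN
  derivation. IC025's role in the combined rule is sign-based, and both
  variants agree on sign behaviour in all regimes exercised here.
- EBGM = aN/((a+c)(a+b)) — the observed/expected ratio under row-column
  independence — with EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)).
  This is the simplified, closed-form EBGM convention of the applied
  signal-mining literature, not the full MGPS gamma-mixture posterior
  (a deliberate non-goal).

IC and EBGM are computed from the same core expression, so
IC = log₂(EBGM) holds exactly, not just approximately.

**Zero cells.** Any zero cell makes the frequentist statistics
undefined and the corresponding method fail; there is no silent 0.5
continuity correction. An explicit Haldane–Anscombe mode
(`zero_cell="haldane"`) exists for exploration. The a ≥ 3 gate already
removes most degenerate tables from the combined verdict.

**Combined rule.** ROR: a ≥ 3 ∧ ROR ≥ 2 ∧ CI lower > 1. PRR: a ≥ 3 ∧
PRR ≥ 2 ∧ CI lower > 1. BCPNN: IC025 > 0. EBGM: EBGM05 > 2. A positive
signal requires all four; requiring consensus across methods with
different small-count behaviour is the false-positive control.

**Monotonicity caveat.** ROR and PRR increase strictly in a with b, c, d
fixed. IC and EBGM do **not** in full generality:
d(ln EBGM)/da = 1/a + 1/N − 1/(a+b) − 1/(a+c), which is negative when a
dominates both margins and d > 0. In the signal-detection regime
a ≤ min(b, c) the bound 1/(a+b) + 1/(a+c) ≤ 1/a guarantees monotonicity,
and the property tests assert it there. Similarly, shrinkage places EBGM
between 1 and ROR: EBGM ≤ ROR exactly when ROR ≥ 1 (algebraically
equivalent to ad ≥ bc), which is the invariant the tests check.

**Rounding.** Output tables round half-up to two decimals, mirroring how
such tables are printed.

## Back-solving published rows

`recover_contingency` inverts a published signal-table row. Given a and
printed (ROR, ROR CI, PRR, EBGM), the ratio of ROR to PRR pins
b = a(PRR−1)/(ROR−PRR); substituting d = ROR·b·c/a makes the EBGM
equation one-dimensional in c (solved by bracketed root-finding on
log c); a Nelder–Mead polish on log(b, c, d) against all five published
quantities absorbs printing round-off; cells are then rounded, with a ±2
neighbourhood search for cells under 1000 (larger cells are insensitive
to ±1). If no integer table reproduces every quantity within 1% relative
error the row is reported as non-identifiable — a diagnostic, not an
exception — which is what happens for deliberately contradictory inputs.
The recovered background cells (c in the tens of thousands, d in the
tens of millions) are exactly the scale a two-decade full-database
extract implies, which is an informal consistency check of the pair
counting model.

## Synthetic databases and what they show

The generator emulates the structure the contingency model assumes, with
defaults fixed as the package's standard study conditions:

| parameter | default | rationale |
|---|---|---|
| n_reports | 5,000 | large enough for stable margins, small enough for Monte-Carlo loops |
| target_drug_share | 0.04 | ~200 target reports, the scale of a niche drug's cohort |
| n_pts | 800, uniform weights | baseline pair probability 1/800 puts an RR-30 PT at expected a ≈ 14, the a-count scale of the strongest published rows |
| PTs per report | truncated geometric, p = 0.5, max 8 (mean ≈ 1.96) | reports list multiple reactions; mean > 1 keeps c > 0 |
| dates | receipt uniform over 2004–2024; onset ≤ 90 d before receipt; therapy start an Exp(mean 30 d) gap before onset | populates every time-to-onset bin |
| missingness | sex 0.23, age 0.67, event date 0.30, therapy start 0.80, occupation 0.01 | matches the unknown fractions of published descriptive tables |
| outcomes | one code per ~54% of reports, HO-dominated categorical | matches published outcome margins |
| duplicate_fraction | 0.05 | emits full second versions to exercise deduplication |

Injected signals multiply the baseline PT weights for target-drug
reports and renormalize, so the configured relative reporting rate is
the generative ground truth the pipeline should recover. With all rates
at 1 the database is null.

Deliberate non-realism: drug-name lexical noise, country structure,
PT co-occurrence correlation, secular reporting trends and a long-tailed
PT frequency distribution are absent. Passing tests therefore
demonstrate that the pipeline recovers known generative structure and
controls false positives under clean conditions — not robustness to the
coding noise, duplication subtlety and confounding of real FAERS data.

## Validation design

Because the licensed raw extract behind the published vorapaxar study
cannot be redistributed, its headline counts (total reports, total
positive signals) are not recomputable here. Validation instead uses:
(i) exact reproduction of the printed descriptive percentages from their
marginal counts; (ii) the printed signal table's internal consistency
(IC vs log₂ EBGM within 0.01; EBGM05 from the ROR-CI-implied standard
error within 0.02); (iii) back-solving a printed row to an integer table
whose recomputed statistics agree within 1%; (iv) synthetic ground
truth — an RR-30 injection detected by the combined rule in ≥ 95 of 100
seeded databases, and a null combined-positive rate ≤ 5% of PTs over 20
seeds (observed well under 1%); (v) exact agreement of the pair counter
with a brute-force double loop; and (vi) byte-identical outputs under
identical configuration and seed. Problem sizes (5,000-report
databases, 100 + 20 seeds, 10,000 random tables) are chosen so the whole
validation runs in about a minute on one CPU while keeping Monte-Carlo
bands far from the acceptance thresholds.

## Known limitations

- The PRR confidence interval formula is a documented convention, not a
  reproduction of an undisclosed original.
- The V(IC) ambiguity cannot be resolved from printed sources; both
  variants are exposed, neither is claimed to be "the" original.
- Partial dates (year or year-month precision) are treated as unknown
  for interval arithmetic rather than imputed, which inflates the
  unknown time-to-onset bin relative to analyses that impute mid-period
  dates.
- SOC-level verdicts inherit the pair-level roll-up choice; analyses
  that deduplicate same-SOC PTs within a report will report smaller
  SOC a-cells.
- One outcome per case (severity precedence DE > LT > HO > DS > CA >
  RI > OT) is assumed when a report lists several outcome codes.
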