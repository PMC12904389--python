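"""Four disproportionality statistics and the combined signal rule.

Implements the reporting odds ratio (ROR), proportional reporting ratio
(PRR) with chi-squared, the BCPNN information component (IC) with its
lower credibility bound IC025, and the empirical Bayes geometric mean
(EBGM) with its lower one-sided bound EBGM05, on a 2x2 table

        event   other
 drug     a       c
 other    b       d

A preferred term is a positive signal only when all four methods pass
their thresholds simultaneously:

    ROR:   a >= 3, ROR >= 2, 95% CI lower bound > 1
    PRR:   a >= 3, PRR >= 2, 95% CI lower bound > 1
    BCPNN: IC025 > 0
    EBGM:  EBGM05 > 2

The reported point IC is the unshrunk log2 of the observed/expected
ratio, i.e. exactly log2(EBGM) — both are derived from the same core
expression a*N / ((a+c)(a+b)).  E(IC) and V(IC) enter only through
IC025.  Zero cells make the frequentist statistics undefined; no
continuity correction is applied unless ``zero_cell="haldane"`` is
requested (adds 0.5 to every cell).

``recover_contingency`` inverts the published summary statistics of a
signal row (a-count, ROR with CI, PRR, EBGM) back to an integer table,
for validating printed signal tables against the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

import numpy as np
from scipy import optimize

from .contingency import ContingencyTable

_NAN = float("nan")
_UNDEF_CI = (_NAN, _NAN)

IcVariance = Literal["literal", "bate"]
ZeroCell = Literal["none", "haldane"]


@dataclass(frozen=True)
class SignalStats:
    """All per-table quantities; undefined statistics are NaN."""

    a: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    ic: float
    e_ic: float
    v_ic: float
    ic025: float
    r_shrink: float
    ebgm: float
    ebgm05: float


@dataclass(frozen=True)
class SignalResult:
    ror_pass: bool
    prr_pass: bool
    bcpnn_pass: bool
    ebgm_pass: bool

    @property
    def combined(self) -> bool:
        return self.ror_pass and self.prr_pass and self.bcpnn_pass and self.ebgm_pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.125 -> 0.13), as in printed tables."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _cells(t: ContingencyTable, zero_cell: ZeroCell) -> tuple[float, float, float, float]:
    if zero_cell == "haldane":
        return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def _wald_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def compute_ror(
    t: ContingencyTable, zero_cell: ZeroCell = "none"
) -> tuple[float, tuple[float, float]]:
    """ROR = ad/(bc) with the log-scale Wald 95% CI.

    Any zero cell makes the statistic undefined (NaN) unless the
    Haldane-Anscombe correction is requested.
    """
    a, b, c, d = _cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return _NAN, _UNDEF_CI
    ror = (a * d) / (b * c)
    half = 1.96 * _wald_se(a, b, c, d)
    return ror, (ror * math.exp(-half), ror * math.exp(half))


def compute_prr(
    t: ContingencyTable, zero_cell: ZeroCell = "none"
) -> tuple[float, tuple[float, float], float]:
    """PRR = a(c+d)/(c(a+b)), chi-squared (no continuity correction), 95% CI.

    The CI uses the standard log-PRR standard error
    sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
    """
    a, b, c, d = _cells(t, zero_cell)
    n = a + b + c + d
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return _NAN, _UNDEF_CI, _NAN
    prr = a * (c + d) / (c * (a + b))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = (a * d - b * c) ** 2 * n / denom if denom > 0 else _NAN
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    half = 1.96 * math.sqrt(max(var, 0.0))
    return prr, (prr * math.exp(-half), prr * math.exp(half)), chi2


def compute_bcpnn(
    t: ContingencyTable,
    zero_cell: ZeroCell = "none",
    variance: IcVariance = "literal",
) -> tuple[float, float, float, float, float]:
    """BCPNN: returns (ic, e_ic, v_ic, ic025, r).

    ic    = log2( a N / ((a+c)(a+b)) )                 (unshrunk point IC)
    r     = N^2 / ((a+b+1)(a+c+1))                     (prior weight)
    e_ic  = log2( a N^2 / ((N+r)(a+b)(a+c)) )          (shrunk expectation)
    v_ic  = k * [ (b+c+d+r-1)/((a+1)(N+r+1))
                + (2+b+c+2d)/((a+b+1)(N+r+3)) ]
    ic025 = e_ic - 2 sqrt(v_ic)

    where k = 1/ln2 for the ``literal`` variance and 1/ln(2)^2 for the
    ``bate`` variant (classical delta-method scaling to the log2 scale).
    """
    a, b, c, d = _cells(t, zero_cell)
    n = a + b + c + d
    if a == 0 or (a + b) == 0 or (a + c) == 0:
        return _NAN, _NAN, _NAN, _NAN, _NAN
    core = a * n / ((a + c) * (a + b))
    ic = math.log2(core)
    r = n * n / ((a + b + 1) * (a + c + 1))
    e_ic = math.log2(a * n * n / ((n + r) * (a + b) * (a + c)))
    bracket = (b + c + d + r - 1) / ((a + 1) * (n + r + 1)) + (
        2 + b + c + 2 * d
    ) / ((a + b + 1) * (n + r + 3))
    k = 1 / math.log(2) if variance == "literal" else 1 / math.log(2) ** 2
    v_ic = k * bracket
    ic025 = e_ic - 2 * math.sqrt(v_ic)
    return ic, e_ic, v_ic, ic025, r


def compute_ebgm(
    t: ContingencyTable, zero_cell: ZeroCell = "none"
) -> tuple[float, float]:
    """EBGM = aN/((a+c)(a+b)); EBGM05 = exp(ln EBGM - 1.96 * Wald SE)."""
    a, b, c, d = _cells(t, zero_cell)
    n = a + b + c + d
    if min(a, b, c, d) == 0:
        return _NAN, _NAN
    ebgm = a * n / ((a + c) * (a + b))
    ebgm05 = ebgm * math.exp(-1.96 * _wald_se(a, b, c, d))
    return ebgm, ebgm05


def compute_all(
    t: ContingencyTable,
    zero_cell: ZeroCell = "none",
    variance: IcVariance = "literal",
) -> SignalStats:
    """Evaluate all four methods on one table."""
    ror, ror_ci = compute_ror(t, zero_cell)
    prr, prr_ci, chi2 = compute_prr(t, zero_cell)
    ic, e_ic, v_ic, ic025, r = compute_bcpnn(t, zero_cell, variance)
    ebgm, ebgm05 = compute_ebgm(t, zero_cell)
    return SignalStats(
        a=t.a, ror=ror, ror_ci=ror_ci, prr=prr, prr_ci=prr_ci, chi2=chi2,
        ic=ic, e_ic=e_ic, v_ic=v_ic, ic025=ic025, r_shrink=r,
        ebgm=ebgm, ebgm05=ebgm05,
    )


def _passes(x: float, threshold: float) -> bool:
    return math.isfinite(x) and x > threshold


def evaluate_signal(stats: SignalStats, a: Optional[int] = None) -> SignalResult:
    """Apply the per-method thresholds; any undefined statistic fails."""
    a = stats.a if a is None else a
    count_gate = a >= 3
    ror_pass = (
        count_gate
        and math.isfinite(stats.ror)
        and stats.ror >= 2
        and _passes(stats.ror_ci[0], 1.0)
    )
    prr_pass = (
        count_gate
        and math.isfinite(stats.prr)
        and stats.prr >= 2
        and _passes(stats.prr_ci[0], 1.0)
    )
    bcpnn_pass = _passes(stats.ic025, 0.0)
    ebgm_pass = _passes(stats.ebgm05, 2.0)
    return SignalResult(ror_pass, prr_pass, bcpnn_pass, ebgm_pass)


# ---------------------------------------------------------------------------
# Back-solver: published statistics -> integer contingency table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryResult:
    table: Optional[ContingencyTable]
    rel_errors: dict[str, float]
    max_rel_error: float
    identifiable: bool
    message: str


def _recovery_errors(
    t: ContingencyTable, a: int, ror: float, ror_ci: tuple[float, float],
    prr: float, ebgm: float,
) -> dict[str, float]:
    ror_c, ci_c = compute_ror(t)
    prr_c, _, _ = compute_prr(t)
    ebgm_c, _ = compute_ebgm(t)
    ref = {
        "ror": (ror_c, ror),
        "ror_lower": (ci_c[0], ror_ci[0]),
        "ror_upper": (ci_c[1], ror_ci[1]),
        "prr": (prr_c, prr),
        "ebgm": (ebgm_c, ebgm),
    }
    return {
        k: abs(calc - printed) / printed if math.isfinite(calc) else math.inf
        for k, (calc, printed) in ref.items()
    }


def recover_contingency(
    a: int,
    ror: float,
    ror_ci: tuple[float, float],
    prr: float,
    ebgm: float,
    tol: float = 0.01,
) -> RecoveryResult:
    """Recover integer (b, c, d) from published per-row statistics.

    Exploits two algebraic facts: the ratio ROR/PRR pins b through
    b = a(PRR-1)/(ROR-PRR), and EBGM is then linear in c once
    d = ROR*b*c/a is substituted.  The continuous solution seeds a
    Nelder-Mead polish on log(b, c, d) against all five published
    quantities (ROR, both CI bounds, PRR, EBGM), after which cells are
    rounded and locally searched.  If no integer table reproduces every
    quantity within ``tol`` relative error, the row is reported as
    non-identifiable rather than raising.
    """
    if a < 1 or min(ror, prr, ebgm, *ror_ci) <= 0:
        raise ValueError("a must be >= 1 and printed statistics positive")

    targets = np.log([ror, ror_ci[0], ror_ci[1], prr, ebgm])

    def predict(logbcd: np.ndarray) -> np.ndarray:
        b, c, d = np.exp(logbcd)
        n = a + b + c + d
        ror_c = a * d / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        prr_c = a * (c + d) / (c * (a + b))
        ebgm_c = a * n / ((a + c) * (a + b))
        return np.log(
            [ror_c, ror_c * math.exp(-1.96 * se), ror_c * math.exp(1.96 * se),
             prr_c, ebgm_c]
        )

    def objective(logbcd: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            pred = predict(logbcd)
        if not np.all(np.isfinite(pred)):
            return 1e9
        return float(np.sum((pred - targets) ** 2))

    # Algebraic seed (exact when the printed row is internally consistent).
    starts = []
    if ror > prr > 1:
        b0 = a * (prr - 1) / (ror - prr)

        def ebgm_gap(log_c: float) -> float:
            c0 = math.exp(log_c)
            d0 = ror * b0 * c0 / a
            n0 = a + b0 + c0 + d0
            return math.log(a * n0 / ((a + c0) * (a + b0))) - math.log(ebgm)

        try:
            lo, hi = math.log(1e-3), math.log(1e12)
            if ebgm_gap(lo) * ebgm_gap(hi) < 0:
                log_c0 = optimize.brentq(ebgm_gap, lo, hi, xtol=1e-12)
                c0 = math.exp(log_c0)
                starts.append(np.log([b0, c0, ror * b0 * c0 / a]))
        except (ValueError, OverflowError):
            pass
    # Generic multistart fallback covering several database scales.
    for scale in (1e2, 1e4, 1e6, 1e8):
        starts.append(np.log([max(a, 1) * 10.0, max(a, 1) * 10.0, scale]))

    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-12:
            break

    b_f, c_f, d_f = np.exp(best.x)
    # Integer refinement: small cells get a +/-2 neighbourhood search,
    # large cells are insensitive to +/-1 so rounding suffices.
    def neighbourhood(x: float) -> list[int]:
        base = int(round(x))
        if x < 1000:
            return sorted({max(v, 1) for v in range(base - 2, base + 3)})
        return [max(base, 1)]

    best_table, best_errs, best_max = None, {}, math.inf
    for b_i in neighbourhood(b_f):
        for c_i in neighbourhood(c_f):
            for d_i in neighbourhood(d_f):
                t = ContingencyTable(a=a, b=b_i, c=c_i, d=d_i)
                errs = _recovery_errors(t, a, ror, ror_ci, prr, ebgm)
                m = max(errs.values())
                if m < best_max:
                    best_table, best_errs, best_max = t, errs, m

    if best_max <= tol:
        return RecoveryResult(best_table, best_errs, best_max, True,
                              "recovered within tolerance")
    return RecoveryResult(
        best_table, best_errs, best_max, False,
        f"no integer table reproduces all statistics within "
        f"{tol:.0%} (best max relative error {best_max:.3g}); the published "
        f"row may be internally inconsistent",
    )
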