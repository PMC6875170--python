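"""Inference battery on the per-family statistics table.

Three lines of evidence distinguish the forces shaping TE codon usage:

* **Mutation pressure** - if GC-ward mutation bias drove GC3s, non-coding
  GC (a neutral proxy) should predict GC3s.  Tested by OLS R² of GC3s on
  non-coding GC, overall and per group, with leave-one-out sensitivity for
  outlier-driven fits.
* **Translational efficiency** - selection for fast translation predicts
  higher Fop in high-copy-number and highly expressed families.  Tested by
  OLS of Fop on copy number and on expression reads (raw and log10 scales;
  counts span orders of magnitude).
* **Translational accuracy** - selection against mistranslation predicts
  optimal-codon enrichment inside functional domains.  Tested per family by
  a 2x2 Fisher exact test of optimal/non-optimal codon counts in domain vs
  non-domain regions.  The two-sided p-value uses the minimum-likelihood
  rule; a small p with the domain Fop *lower* is significant heterogeneity
  but is not accuracy-consistent, so direction is reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon import CodingSequence
from .errors import ParameterError, UndefinedStatisticError

__all__ = [
    "FamilyStatsRow",
    "RegressionResult",
    "DomainTestResult",
    "ols_r_squared",
    "fisher_exact_2x2",
    "fisher_exact_enumerate",
    "domain_accuracy_test",
    "selection_report",
]

GROUPS = ("copia", "chromovirus", "gypsy_nonchromo", "transposon")


@dataclass
class FamilyStatsRow:
    family: str
    group: str
    nc: float
    fop: float
    gc3s: float
    noncoding_gc: float | None = None
    copy_number: int | None = None
    expression_reads: int | None = None


@dataclass
class RegressionResult:
    r_squared: float
    slope: float
    intercept: float
    n_points: int


@dataclass
class DomainTestResult:
    fop_domain: float
    fop_nondomain: float
    counts: tuple[tuple[int, int], tuple[int, int]]  # rows: domain/non-domain; cols: optimal/non-optimal
    p_value: float
    direction: str  # domain_higher | domain_lower | equal

    @property
    def accuracy_consistent(self) -> bool:
        """Significant AND in the direction translational accuracy predicts."""
        return self.direction == "domain_higher" and self.p_value < 0.05


def ols_r_squared(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """Ordinary least squares of y on x; R² is the squared Pearson r."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ParameterError(f"regression needs >= 3 points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("constant predictor: degenerate regression")
    res = stats.linregress(x, y)
    return RegressionResult(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(pts),
    )


def _table_margins(table) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ParameterError("Fisher table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise UndefinedStatisticError("Fisher test undefined: zero margin")
    return a, b, c, d


def fisher_exact_2x2(table, sidedness: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table by full hypergeometric enumeration.

    Exact rational arithmetic throughout; the two-sided p sums the
    probabilities of all tables with the observed margins whose likelihood
    does not exceed the observed table's (minimum-likelihood rule).
    """
    a, b, c, d = _table_margins(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(k_lo, k_hi + 1)
    }
    p_obs = pmf[a]
    if sidedness == "two-sided":
        total = sum(p for p in pmf.values() if p <= p_obs)
    elif sidedness == "greater":
        total = sum(p for k, p in pmf.items() if k >= a)
    elif sidedness == "less":
        total = sum(p for k, p in pmf.items() if k <= a)
    else:
        raise ParameterError(f"unknown sidedness {sidedness!r}")
    return float(min(total, Fraction(1)))


def fisher_exact_enumerate(table, sidedness: str = "two-sided") -> float:
    """Alias kept for clarity: the implementation *is* the enumeration."""
    return fisher_exact_2x2(table, sidedness)


def domain_accuracy_test(
    cds: CodingSequence,
    optimal_set: Iterable[str],
    domain_labels: Sequence[str] | None = None,
) -> DomainTestResult:
    """Test for optimal-codon enrichment in functional-domain codons.

    Codons are partitioned by ``cds.region_labels`` (or ``domain_labels``)
    into domain and non-domain sets (masked codons excluded); Fop is
    computed per partition and association tested with the Fisher exact
    test on (optimal, non-optimal) x (domain, non-domain) counts.
    """
    optimal = {c.upper() for c in optimal_set}
    labels = list(domain_labels) if domain_labels is not None else cds.region_labels
    if labels is None or len(labels) != len(cds.codons):
        raise ParameterError("per-codon domain labels are required")
    dom = [c for c, lab in zip(cds.codons, labels) if lab == "domain"]
    non = [c for c, lab in zip(cds.codons, labels) if lab == "non_domain"]
    if not dom or not non:
        raise UndefinedStatisticError(
            f"CDS {cds.id!r}: domain or non-domain partition is empty"
        )
    d_opt = sum(1 for c in dom if c in optimal)
    n_opt = sum(1 for c in non if c in optimal)
    counts = ((d_opt, len(dom) - d_opt), (n_opt, len(non) - n_opt))
    fop_d = d_opt / len(dom)
    fop_n = n_opt / len(non)
    p = fisher_exact_2x2(counts)
    if fop_d > fop_n:
        direction = "domain_higher"
    elif fop_d < fop_n:
        direction = "domain_lower"
    else:
        direction = "equal"
    return DomainTestResult(
        fop_domain=fop_d, fop_nondomain=fop_n, counts=counts,
        p_value=p, direction=direction,
    )


@dataclass
class Contrast:
    name: str
    x: str
    y: str
    rows: str  # group filter or "all"
    result: RegressionResult | None = None
    note: str = ""
    leave_one_out: dict[str, float] = field(default_factory=dict)
    ordinal: str | None = None


def _rows_df(rows: Sequence[FamilyStatsRow] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame([vars(r) for r in rows])
    df.loc[df["group"].isin(("chromovirus", "gypsy_nonchromo", "copia")), "te_class"] = "LTR"
    df["te_class"] = df["te_class"].fillna("transposon")
    return df


def _run_contrast(df: pd.DataFrame, name: str, x: str, y: str, loo: bool = False) -> Contrast:
    c = Contrast(name=name, x=x, y=y, rows=name)
    sub = df.dropna(subset=[x, y])
    if len(sub) == 2:
        lo, hi = sub.sort_values(x).iloc[0], sub.sort_values(x).iloc[-1]
        rel = "higher" if hi[y] > lo[y] else ("lower" if hi[y] < lo[y] else "equal")
        c.ordinal = (
            f"two members only: {hi['family']} has the higher {x} and the {rel} {y}"
        )
        c.note = "ordinal comparison only"
        return c
    if len(sub) < 3:
        c.note = f"skipped: only {len(sub)} usable rows"
        return c
    pts = list(zip(sub[x], sub[y]))
    try:
        c.result = ols_r_squared(pts)
    except UndefinedStatisticError as exc:
        c.note = f"skipped: {exc}"
        return c
    if loo and len(sub) > 3:
        for fam in sub["family"]:
            rest = sub[sub["family"] != fam]
            try:
                c.leave_one_out[fam] = ols_r_squared(
                    list(zip(rest[x], rest[y]))
                ).r_squared
            except (UndefinedStatisticError, ParameterError):
                c.leave_one_out[fam] = float("nan")
    return c


def selection_report(
    rows: Sequence[FamilyStatsRow] | pd.DataFrame,
    expression_transform: str = "log10",
) -> dict:
    """Run the full regression battery over a family statistics table.

    Contrasts: Nc~GC3s over all families; GC3s~non-coding GC over all
    families and per group (with leave-one-out sensitivity); Fop~copy
    number per group; Fop~expression per group on raw and log10(reads)
    scales.  Two-member groups are reported as an ordinal comparison;
    smaller groups are skipped with a reason.  No multiple-testing
    correction is applied; the report carries the number of regressions run.
    """
    df = _rows_df(rows)
    if expression_transform not in ("log10", "raw"):
        raise ParameterError("expression_transform must be 'log10' or 'raw'")
    df["log10_reads"] = np.log10(df["expression_reads"].astype(float) + 1.0)
    contrasts: list[Contrast] = []
    contrasts.append(_run_contrast(df, "nc_vs_gc3s/all", "gc3s", "nc"))
    contrasts.append(_run_contrast(df, "gc3s_vs_noncoding_gc/all", "noncoding_gc", "gc3s"))
    for grp in GROUPS:
        sub = df[df["group"] == grp]
        contrasts.append(
            _run_contrast(sub, f"gc3s_vs_noncoding_gc/{grp}", "noncoding_gc", "gc3s", loo=True)
        )
        contrasts.append(_run_contrast(sub, f"fop_vs_copy_number/{grp}", "copy_number", "fop"))
        for scale, col in (("raw", "expression_reads"), ("log10", "log10_reads")):
            contrasts.append(_run_contrast(sub, f"fop_vs_expression_{scale}/{grp}", col, "fop"))
    ltr = df[df["te_class"] == "LTR"]
    contrasts.append(_run_contrast(ltr, "fop_vs_copy_number/ltr", "copy_number", "fop"))
    report = {
        "n_regressions_run": sum(1 for c in contrasts if c.result is not None),
        "expression_transform_default": expression_transform,
        "contrasts": {},
    }
    for c in contrasts:
        entry: dict = {"note": c.note}
        if c.result is not None:
            entry.update(
                n=c.result.n_points,
                slope=c.result.slope,
                intercept=c.result.intercept,
                r_squared=c.result.r_squared,
            )
        if c.leave_one_out:
            entry["leave_one_out_r_squared"] = c.leave_one_out
        if c.ordinal:
            entry["ordinal"] = c.ordinal
        report["contrasts"][c.name] = entry
    return report
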