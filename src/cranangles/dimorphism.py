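"""Per-angle sexual-dimorphism testing.

For every angle column the two sex samples are first screened with the
Shapiro-Wilk normality test (per sex) and Levene's variance-equality test;
the mean/distribution comparison is then a pooled two-sided t-test when both
samples are normal *and* variances are equal, and the two-sided
Mann-Whitney U-test otherwise.  This is the most conservative reading of
the classical two-stage protocol; the conjunction is a pure function of the
three screening flags and is configurable.

No multiple-testing correction is applied by default (36 raw tests at
alpha = 0.05); a Holm adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AngleTable

MALE, FEMALE = "male", "female"


@dataclass
class DimorphismSettings:
    alpha: float = 0.05
    alpha_assumption: float = 0.05     # screening level for Shapiro-Wilk / Levene
    levene_center: str = "mean"        # "mean" | "median"
    t_variant: str = "pooled"          # "pooled" | "welch"
    mw_mode: str = "asymptotic"        # "asymptotic" (tie + continuity corrected) | "exact"
    holm: bool = False


@dataclass
class DimorphismRow:
    angle_code: str
    n_male: int
    mean_male: float
    sd_male: float
    min_male: float
    max_male: float
    n_female: int
    mean_female: float
    sd_female: float
    min_female: float
    max_female: float
    normality_p_male: float
    normality_p_female: float
    levene_p: float
    chosen_test: str       # "t" | "U" | "none"
    p_value: float
    significant: bool
    testable: bool = True


@dataclass
class DimorphismReport:
    rows: list[DimorphismRow]
    alpha: float = 0.05
    settings: DimorphismSettings = field(default_factory=DimorphismSettings)

    def significant_codes(self) -> list[str]:
        return [r.angle_code for r in self.rows if r.testable and r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows]).set_index("angle_code")


def describe_by_sex(table: AngleTable, code: str) -> dict[str, dict[str, float]]:
    """Per-sex n/mean/SD/min/max of one angle column, over present values only."""
    if code not in table.frame.columns:
        raise KeyError(f"unknown angle code {code!r}")
    out = {}
    for sex in (MALE, FEMALE):
        vals = table.frame.loc[table.sex == sex, code].dropna().to_numpy()
        if len(vals) == 0:
            out[sex] = {"n": 0, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
        else:
            out[sex] = {
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
    return out


def select_test(normal_m: bool, normal_f: bool, equal_var: bool) -> str:
    """Decision rule: pooled t only when both samples normal and variances equal."""
    return "t" if (normal_m and normal_f and equal_var) else "U"


def test_sex_difference(
    table: AngleTable, code: str, settings: DimorphismSettings | None = None
) -> DimorphismRow:
    """Screen assumptions and test one angle for a sex difference."""
    settings = settings or DimorphismSettings()
    desc = describe_by_sex(table, code)
    males = table.frame.loc[table.sex == MALE, code].dropna().to_numpy()
    females = table.frame.loc[table.sex == FEMALE, code].dropna().to_numpy()

    base = dict(
        angle_code=code,
        n_male=desc[MALE]["n"], mean_male=desc[MALE]["mean"], sd_male=desc[MALE]["sd"],
        min_male=desc[MALE]["min"], max_male=desc[MALE]["max"],
        n_female=desc[FEMALE]["n"], mean_female=desc[FEMALE]["mean"],
        sd_female=desc[FEMALE]["sd"], min_female=desc[FEMALE]["min"],
        max_female=desc[FEMALE]["max"],
    )
    if len(males) < 3 or len(females) < 3:
        return DimorphismRow(**base, normality_p_male=np.nan, normality_p_female=np.nan,
                             levene_p=np.nan, chosen_test="none", p_value=np.nan,
                             significant=False, testable=False)

    # constant samples break Shapiro-Wilk; treat them as grossly non-normal
    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0.0:
            return 0.0
        return float(stats.shapiro(x).pvalue)

    sw_m = _shapiro_p(males)
    sw_f = _shapiro_p(females)
    if np.ptp(males) == 0.0 and np.ptp(females) == 0.0:
        lev_p = 1.0
    else:
        lev_p = float(stats.levene(males, females, center=settings.levene_center).pvalue)

    a = settings.alpha_assumption
    chosen = select_test(sw_m >= a, sw_f >= a, lev_p >= a)
    if chosen == "t":
        equal_var = settings.t_variant == "pooled"
        p = float(stats.ttest_ind(males, females, equal_var=equal_var).pvalue)
    else:
        if np.ptp(np.concatenate([males, females])) == 0.0:
            p = 1.0  # identical constant samples: no evidence of difference
        else:
            method = "exact" if settings.mw_mode == "exact" else "asymptotic"
            p = float(stats.mannwhitneyu(males, females, alternative="two-sided",
                                         method=method, use_continuity=True).pvalue)
    return DimorphismRow(**base, normality_p_male=sw_m, normality_p_female=sw_f,
                         levene_p=lev_p, chosen_test=chosen, p_value=p,
                         significant=bool(p < settings.alpha))


def dimorphism_report(
    table: AngleTable, settings: DimorphismSettings | None = None
) -> DimorphismReport:
    """One DimorphismRow per angle column, with optional Holm adjustment."""
    settings = settings or DimorphismSettings()
    rows = [test_sex_difference(table, code, settings) for code in table.frame.columns]
    if settings.holm:
        testable = [r for r in rows if r.testable and np.isfinite(r.p_value)]
        order = np.argsort([r.p_value for r in testable])
        m = len(testable)
        adj_prev = 0.0
        adjusted = {}
        for rank, idx in enumerate(order):
            r = testable[idx]
            adj = min(1.0, max(adj_prev, (m - rank) * r.p_value))
            adjusted[r.angle_code] = adj
            adj_prev = adj
        for r in rows:
            if r.angle_code in adjusted:
                r.p_value = adjusted[r.angle_code]
                r.significant = bool(r.p_value < settings.alpha)
    return DimorphismReport(rows, settings.alpha, settings)


def render_report(report: DimorphismReport, fmt: str = "csv") -> str:
    """Render the report in the reference-table layout (CSV or markdown).

    Columns: per-sex n/Mean/SD/Min/Max and the p-value annotated with the
    chosen test code (t / U) and a ``*`` flag when significant.
    """
    header = ["Angle", "n_M", "Mean_M", "SD_M", "Min_M", "Max_M",
              "n_F", "Mean_F", "SD_F", "Min_F", "Max_F", "p"]
    lines = []
    for r in report.rows:
        if not r.testable:
            p_cell = "n/a"
        else:
            p_cell = "<0.001" if r.p_value < 0.001 else f"{r.p_value:.3f}"
            p_cell += f" {'*' if r.significant else ''}{r.chosen_test}".rstrip()
        cells = [r.angle_code,
                 str(r.n_male), f"{r.mean_male:.2f}", f"{r.sd_male:.2f}",
                 f"{r.min_male:.2f}", f"{r.max_male:.2f}",
                 str(r.n_female), f"{r.mean_female:.2f}", f"{r.sd_female:.2f}",
                 f"{r.min_female:.2f}", f"{r.max_female:.2f}", p_cell]
        lines.append(cells)
    if fmt == "markdown":
        out = ["| " + " | ".join(header) + " |",
               "|" + "---|" * len(header)]
        out += ["| " + " | ".join(c) + " |" for c in lines]
        return "\n".join(out)
    return "\n".join([",".join(header)] + [",".join(c) for c in lines])
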