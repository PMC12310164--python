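"""Study-level analysis of an AFO-condition cohort.

Given per-trial spatiotemporal outcomes for n participants under the five
walking conditions (no AFO, four spring stiffnesses), this module

* derives each participant's *best* condition — the condition with the
  greatest gait speed — and appends it as a sixth pseudo-condition;
* runs an omnibus test per outcome over the six conditions: one-way
  repeated-measures ANOVA when every condition passes Shapiro–Wilk
  normality, Friedman's test otherwise (the routing can be overridden);
* runs Wilcoxon signed-rank tests over all 15 condition pairs with Holm
  step-down correction, attaching the rank-biserial-style effect size
  r = |z| / sqrt(n) banded small (< 0.3) / medium (0.3–0.5) / large (> 0.5);
* tabulates mean best-minus-condition differences per outcome.

The *best* level is selected from the same data it is compared against,
so it is not statistically independent of its source conditions; every
report carries that caveat.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, IncompleteParticipantError
from .simulate import CONDITIONS, OUTCOME_COLUMNS

BEST = "best"
ALL_LEVELS = CONDITIONS + (BEST,)

INDEPENDENCE_CAVEAT = (
    "The 'best' level duplicates, per participant, the row of their "
    "fastest condition; comparisons against it are not independent of the "
    "source conditions and are biased toward favorable differences."
)


def effect_size_band(r: float) -> str:
    if r > 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    return "small"


# ---------------------------------------------------------------------------
# best-condition construction
# ---------------------------------------------------------------------------


def _check_complete(table: pd.DataFrame) -> None:
    counts = table.groupby("participant")["condition"].apply(
        lambda s: set(s) >= set(CONDITIONS)
    )
    bad = counts.index[~counts].tolist()
    if bad:
        raise IncompleteParticipantError(
            f"participants missing conditions: {bad}"
        )


def select_best_condition(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Append the per-participant 'best' pseudo-condition.

    ``table`` is long-form with columns ``participant``, ``condition`` and
    the outcome columns. The best condition is the argmax of gait speed
    over the five conditions; exact ties break toward no-AFO first, then
    ascending spring stiffness (logged in the returned best map's attrs).
    Returns (six-level table, per-participant best condition, winner
    counts over the five conditions).
    """
    _check_complete(table)
    table = table[table["condition"].isin(CONDITIONS)].copy()
    priority = {c: i for i, c in enumerate(CONDITIONS)}
    best_rows = []
    best_map = {}
    ties = []
    for pid, grp in table.groupby("participant"):
        speeds = grp.set_index("condition")["gait_speed"]
        top = speeds.max()
        winners = sorted(speeds.index[speeds == top], key=priority.get)
        if len(winners) > 1:
            ties.append(pid)
        best = winners[0]
        best_map[pid] = best
        row = grp[grp["condition"] == best].iloc[0].copy()
        row["condition"] = BEST
        best_rows.append(row)
    out = pd.concat([table, pd.DataFrame(best_rows)], ignore_index=True)
    best_series = pd.Series(best_map, name="best_condition")
    best_series.attrs["ties"] = ties
    counts = best_series.value_counts().reindex(list(CONDITIONS), fill_value=0)
    counts.name = "n_best"
    return out, best_series, counts


def outcome_matrix(table: pd.DataFrame, outcome: str,
                   levels: tuple[str, ...] = ALL_LEVELS) -> pd.DataFrame:
    """Wide participants x conditions matrix for one outcome."""
    wide = table.pivot_table(index="participant", columns="condition",
                             values=outcome, aggfunc="first")
    missing = [c for c in levels if c not in wide.columns]
    if missing:
        raise IncompleteParticipantError(f"conditions absent from table: {missing}")
    wide = wide[list(levels)]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise IncompleteParticipantError(f"participants with missing values: {bad}")
    return wide


# ---------------------------------------------------------------------------
# omnibus tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmnibusResult:
    test: str                 # 'repeated_anova' or 'friedman'
    statistic: float
    p: float
    df: tuple[float, float] | float
    shapiro_p: dict[str, float]


def repeated_measures_anova(wide: pd.DataFrame) -> tuple[float, float, tuple[float, float]]:
    """One-way repeated-measures ANOVA with subject blocking.

    F = MS_condition / MS_(condition x subject error).
    """
    if np.allclose(wide.to_numpy().std(axis=1), 0.0):
        raise DegenerateDataError("every participant has identical values across conditions")
    long = wide.reset_index().melt(id_vars="participant", var_name="condition",
                                   value_name="value")
    res = AnovaRM(long, depvar="value", subject="participant",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return (float(row["F Value"]), float(row["Pr > F"]),
            (float(row["Num DF"]), float(row["Den DF"])))


def friedman_test(wide: pd.DataFrame) -> tuple[float, float, float]:
    """Friedman's chi-square on within-subject ranks (tie-corrected)."""
    arr = wide.to_numpy()
    if np.allclose(arr.std(axis=1), 0.0):
        raise DegenerateDataError("every participant has identical values across conditions")
    stat, p = stats.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
    return float(stat), float(p), float(arr.shape[1] - 1)


def route_omnibus(
    wide: pd.DataFrame,
    alpha: float = 0.05,
    override: str | None = None,
) -> OmnibusResult:
    """Choose and run the omnibus test for one outcome.

    Shapiro–Wilk is applied per condition; if every condition is
    compatible with normality (p >= alpha) the repeated-measures ANOVA is
    used, otherwise Friedman's test. ``override`` ('anova' or 'friedman')
    bypasses the routing, e.g. to reproduce a published assignment.
    """
    if len(wide) < 5:
        raise DegenerateDataError("omnibus tests need at least 5 participants")
    shapiro_p: dict[str, float] = {}
    for cond in wide.columns:
        col = wide[cond].to_numpy()
        if np.ptp(col) == 0.0:
            shapiro_p[cond] = 0.0  # constant: certainly not normal
        else:
            shapiro_p[cond] = float(stats.shapiro(col).pvalue)
    if override not in (None, "anova", "friedman"):
        raise ValueError(f"unknown omnibus override {override!r}")
    use_anova = (override == "anova") if override else all(
        p >= alpha for p in shapiro_p.values()
    )
    if use_anova:
        f, p, df = repeated_measures_anova(wide)
        return OmnibusResult("repeated_anova", f, p, df, shapiro_p)
    chi2, p, df = friedman_test(wide)
    return OmnibusResult("friedman", chi2, p, df, shapiro_p)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank post hoc with Holm correction
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 12
) -> dict[str, float]:
    """Paired Wilcoxon signed-rank test with a tie-corrected z.

    Zero differences are dropped (classic Wilcoxon convention). The
    p-value comes from the exact null distribution when the number of
    nonzero differences is <= ``exact_max_n`` and their magnitudes are
    untied, otherwise from the tie-corrected normal approximation. The
    z statistic (used for the effect size) is always the tie-corrected
    normal deviate of W.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    nz = d[d != 0.0]
    n = len(nz)
    n_total = len(d)
    if n == 0:
        return {"W": 0.0, "z": 0.0, "p": 1.0, "n_nonzero": 0,
                "n_pairs": n_total, "degenerate": True}
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if var_w == 0 else (w_pos - mean_w) / math.sqrt(var_w)
    has_ties = bool((tie_counts > 1).any())
    if n <= exact_max_n and not has_ties:
        p = float(stats.wilcoxon(nz, zero_method="wilcox", method="exact").pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(p, 1.0)
    return {"W": min(w_pos, n * (n + 1) / 2.0 - w_pos), "z": float(z), "p": p,
            "n_nonzero": n, "n_pairs": n_total, "degenerate": False}


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, dominating the raw p)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def wilcoxon_holm_posthoc(
    wide: pd.DataFrame, alpha: float = 0.05, exact_max_n: int = 12
) -> pd.DataFrame:
    """All pairwise Wilcoxon signed-rank tests with Holm correction.

    One row per unordered condition pair: W, z, raw p, Holm-adjusted p,
    effect size r = |z| / sqrt(n pairs), its band, the mean difference
    (a - b), and a significance flag at the adjusted ``alpha``.
    """
    pairs = list(itertools.combinations(wide.columns, 2))
    rows = []
    for a, b in pairs:
        res = wilcoxon_signed_rank(wide[a].to_numpy(), wide[b].to_numpy(),
                                   exact_max_n=exact_max_n)
        r = abs(res["z"]) / math.sqrt(res["n_pairs"]) if res["n_pairs"] else 0.0
        rows.append({
            "level_a": a, "level_b": b,
            "W": res["W"], "z": res["z"], "p_raw": res["p"],
            "n_pairs": res["n_pairs"], "n_nonzero": res["n_nonzero"],
            "degenerate": res["degenerate"],
            "mean_difference": float(np.mean(wide[a].to_numpy() - wide[b].to_numpy())),
            "effect_size_r": r,
            "band": effect_size_band(r),
        })
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def mean_difference_table(table_with_best: pd.DataFrame) -> pd.DataFrame:
    """Mean (best - condition) per outcome and condition over participants."""
    rows = []
    for outcome in OUTCOME_COLUMNS:
        wide = outcome_matrix(table_with_best, outcome)
        for cond in CONDITIONS:
            rows.append({
                "outcome": outcome,
                "condition": cond,
                "mean_difference": float((wide[BEST] - wide[cond]).mean()),
            })
    return pd.DataFrame(rows)


@dataclass
class StatReport:
    """Omnibus + post hoc results for every outcome, plus summary tables."""

    n_participants: int
    omnibus: dict[str, OmnibusResult]
    pairwise: dict[str, pd.DataFrame]
    mean_differences: pd.DataFrame
    winner_counts: pd.Series
    best_condition: pd.Series
    alpha: float = 0.05
    caveat: str = INDEPENDENCE_CAVEAT

    def pairwise_tidy(self) -> pd.DataFrame:
        frames = []
        for outcome, df in self.pairwise.items():
            df = df.copy()
            df.insert(0, "outcome", outcome)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def analyze_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    routing_override: dict[str, str] | None = None,
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS,
) -> StatReport:
    """Full study analysis of a five-condition cohort table."""
    with_best, best_map, counts = select_best_condition(table)
    omnibus: dict[str, OmnibusResult] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    for outcome in outcomes:
        wide = outcome_matrix(with_best, outcome)
        override = (routing_override or {}).get(outcome)
        omnibus[outcome] = route_omnibus(wide, alpha=alpha, override=override)
        pairwise[outcome] = wilcoxon_holm_posthoc(wide, alpha=alpha)
    return StatReport(
        n_participants=int(with_best["participant"].nunique()),
        omnibus=omnibus,
        pairwise=pairwise,
        mean_differences=mean_difference_table(with_best),
        winner_counts=counts,
        best_condition=best_map,
        alpha=alpha,
    )


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    outliers = values[(values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)]
    return {"q1": q1, "median": med, "q3": q3, "mean": float(values.mean()),
            "n_outliers": int(len(outliers))}


def render_report(report: StatReport, table_with_best: pd.DataFrame | None = None,
                  table: pd.DataFrame | None = None) -> str:
    """Human-readable markdown report (box summaries per condition, omnibus
    results, significant Holm-corrected pairs, winner counts)."""
    if table_with_best is None and table is not None:
        table_with_best, _, _ = select_best_condition(table)
    lines = [
        "# Gait outcome report",
        "",
        f"Participants: {report.n_participants}; alpha = {report.alpha}",
        "",
        f"> Caveat: {report.caveat}",
        "",
        "## Best-condition winner counts",
        "",
    ]
    for cond, n in report.winner_counts.items():
        lines.append(f"- {cond}: {int(n)}")
    for outcome, om in report.omnibus.items():
        lines += ["", f"## {outcome}", ""]
        lines.append(
            f"Omnibus: {om.test} statistic = {om.statistic:.3f}, p = {om.p:.4g}"
        )
        if table_with_best is not None:
            wide = outcome_matrix(table_with_best, outcome)
            lines += ["", "| condition | Q1 | median | Q3 | mean | outliers |",
                      "|---|---|---|---|---|---|"]
            for cond in ALL_LEVELS:
                s = _box_stats(wide[cond].to_numpy())
                lines.append(
                    f"| {cond} | {s['q1']:.3f} | {s['median']:.3f} | "
                    f"{s['q3']:.3f} | {s['mean']:.3f} | {s['n_outliers']} |"
                )
        sig = report.pairwise[outcome]
        sig = sig[sig["significant"]]
        lines += ["", f"Significant Holm-corrected pairs ({len(sig)}):"]
        for _, row in sig.iterrows():
            lines.append(
                f"- {row['level_a']} vs {row['level_b']}: "
                f"p_holm = {row['p_holm']:.4g}, r = {row['effect_size_r']:.2f} "
                f"({row['band']}), mean diff = {row['mean_difference']:+.3f}"
            )
    return "\n".join(lines) + "\n"
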