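"""Statistical evaluation battery.

Spearman rank correlation with a Fisher-z confidence interval, mean-split
subgroup correlations (low vs high exhaled volume), one-way single-rater
intraclass correlation for inter-rater agreement, exact (Clopper–Pearson)
binomial proportion intervals for feasibility counts, and a study report
that assembles all of them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CorrelationResult",
    "SplitCorrelation",
    "ICCResult",
    "ProportionCI",
    "spearman_ci",
    "split_by_mean",
    "icc_oneway",
    "clopper_pearson",
    "study_report",
    "StudyReport",
]

EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class SplitCorrelation:
    mean_cut: float
    low: CorrelationResult
    high: CorrelationResult


@dataclass(frozen=True)
class ICCResult:
    icc: float
    p: float
    n_targets: int
    n_raters: int


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    point: float
    ci_low: float
    ci_high: float


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's r_s (midranks kept)."""
    n = xr.size
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = total = 0
    batch: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(n)):
        batch.append(perm)
        if len(batch) == 100_000:
            r = (yc[np.array(batch)] @ xc) / denom
            count += int(np.sum(np.abs(r) >= abs(r_obs) - 1e-12))
            total += len(batch)
            batch = []
    if batch:
        r = (yc[np.array(batch)] @ xc) / denom
        count += int(np.sum(np.abs(r) >= abs(r_obs) - 1e-12))
        total += len(batch)
    return count / total


def spearman_ci(x, y, *, alpha: float = 0.05) -> CorrelationResult:
    """Spearman rank correlation with Fisher-z CI and a two-sided p.

    Ranks use midranks for ties.  The confidence interval is Fisher's
    z-transform of r_s with variance 1/(n−3).  The p-value is exact (full
    permutation enumeration) for n ≤ 10 and the usual t-approximation
    otherwise.

    Raises
    ------
    ValueError
        Fewer than 4 paired observations, unequal lengths, missing values,
        or a constant input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")

    res = sps.spearmanr(x, y)
    r_s = float(res.statistic)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(sps.rankdata(x), sps.rankdata(y), r_s)
    else:
        p = float(res.pvalue)

    z_crit = sps.norm.ppf(1 - alpha / 2)
    se = 1.0 / math.sqrt(n - 3)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r_s, -1.0, 1.0))
    lo, hi = np.tanh([z - z_crit * se, z + z_crit * se])
    return CorrelationResult(r_s=r_s, ci_low=float(lo), ci_high=float(hi),
                             p=p, n=n)


def split_by_mean(
    table: pd.DataFrame, method: str, *, min_stratum: int = 4
) -> SplitCorrelation:
    """Correlation with exhaled volume in low- vs high-volume strata.

    The cut is the mean exhaled volume over that method's records; records
    with volume ≤ mean form the low stratum.  Mirrors the subgroup analysis
    that exposes the accessory-muscle effect at high lung volumes.
    """
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValueError(f"no records for method {method!r}")
    cut = float(sub["volume_l"].mean())
    low = sub[sub["volume_l"] <= cut]
    high = sub[sub["volume_l"] > cut]
    for name, stratum in (("low", low), ("high", high)):
        if len(stratum) < min_stratum:
            raise ValueError(
                f"{name} stratum has {len(stratum)} records; need "
                f">= {min_stratum}"
            )
    return SplitCorrelation(
        mean_cut=cut,
        low=spearman_ci(low["value"].to_numpy(), low["volume_l"].to_numpy()),
        high=spearman_ci(high["value"].to_numpy(), high["volume_l"].to_numpy()),
    )


def icc_oneway(ratings: np.ndarray) -> ICCResult:
    """One-way random-effects single-rater intraclass correlation, ICC(1,1).

    ``ratings`` is a complete (targets × raters) matrix.  From the one-way
    ANOVA mean squares, ICC = (MSB − MSW) / (MSB + (k−1)·MSW); the p-value is
    from the F test of between-target variance (F = MSB/MSW with n−1 and
    n(k−1) degrees of freedom).  Identical rater columns give exactly 1.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a (targets x raters) matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 targets and 2 raters")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete")
    row_means = m.mean(axis=1)
    grand = m.mean()
    if np.ptp(row_means) == 0 and np.ptp(m) == 0:
        raise ValueError("degenerate ratings: no variation across targets")
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
    if msw == 0.0:
        return ICCResult(icc=1.0, p=0.0, n_targets=n, n_raters=k)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw
    p = float(sps.f.sf(f, n - 1, n * (k - 1)))
    return ICCResult(icc=float(icc), p=p, n_targets=n, n_raters=k)


def clopper_pearson(k: int, n: int, *, alpha: float = 0.05) -> ProportionCI:
    """Exact two-sided binomial proportion interval (Beta-quantile form)."""
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return ProportionCI(k=k, n=n, point=k / n, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# study report


@dataclass
class StudyReport:
    summary: pd.DataFrame
    correlations: pd.DataFrame
    splits: pd.DataFrame
    icc: pd.DataFrame
    proportions: pd.DataFrame
    text: str


def _summary_frame(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for method, sub in table.groupby("method", sort=True):
        v = sub["value"]
        rows.append(
            {
                "method": method,
                "units": sub["units"].iloc[0],
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
                "n": len(v),
                "volume_mean_l": sub["volume_l"].mean(),
                "volume_sd_l": sub["volume_l"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def study_report(
    table: pd.DataFrame,
    ratings: dict[str, np.ndarray] | None = None,
    proportions: list[tuple[str, int, int]] | None = None,
    out_dir: str | Path | None = None,
    *,
    plots: bool = False,
) -> StudyReport:
    """Assemble the full evaluation: summaries, correlations, mean-split
    subgroup correlations, inter-rater ICC and exact proportion CIs.

    Writes ``summary.csv``, ``correlations.csv``, ``splits.csv``, ``icc.csv``,
    ``proportions.csv`` and ``report.txt`` (plus per-method scatter PNGs when
    ``plots``) into ``out_dir`` when given.  Sections with no input are
    omitted rather than failing.
    """
    methods = sorted(table["method"].unique())
    summary = _summary_frame(table)

    corr_rows, split_rows = [], []
    for method in methods:
        sub = table[table["method"] == method]
        r = spearman_ci(sub["value"].to_numpy(), sub["volume_l"].to_numpy())
        corr_rows.append(
            {"method": method, "r_s": r.r_s, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "p": r.p, "n": r.n}
        )
        try:
            sp = split_by_mean(table, method)
        except ValueError:
            continue
        for stratum, res in (("low", sp.low), ("high", sp.high)):
            split_rows.append(
                {"method": method, "stratum": stratum,
                 "mean_cut_l": sp.mean_cut, "r_s": res.r_s,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                 "n": res.n}
            )
    correlations = pd.DataFrame(corr_rows)
    splits = pd.DataFrame(split_rows)

    icc_rows = []
    for method, matrix in (ratings or {}).items():
        r = icc_oneway(np.asarray(matrix))
        icc_rows.append(
            {"method": method, "icc": r.icc, "p": r.p,
             "n_targets": r.n_targets, "n_raters": r.n_raters}
        )
    icc = pd.DataFrame(icc_rows)

    prop_rows = []
    for label, k, n in proportions or []:
        ci = clopper_pearson(k, n)
        prop_rows.append(
            {"label": label, "k": k, "n": n, "point": ci.point,
             "ci_low": ci.ci_low, "ci_high": ci.ci_high}
        )
    props = pd.DataFrame(prop_rows)

    lines = ["Diaphragm motion study report", "=" * 31, ""]
    lines.append("Per-method summary (measurement units as stated):")
    for _, r in summary.iterrows():
        prec = 1
        lines.append(
            f"  {r['method']:>6} [{r['units']}]: mean {r['mean']:.{prec}f}, "
            f"SD {r['sd']:.{prec}f}, range {r['min']:.{prec}f}-"
            f"{r['max']:.{prec}f}, n={int(r['n'])}"
        )
    lines.append("")
    lines.append("Spearman correlation with exhaled volume:")
    for _, r in correlations.iterrows():
        lines.append(
            f"  {r['method']:>6}: r_s = {r['r_s']:.2f} "
            f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}), "
            f"p = {r['p']:.3g}, n = {int(r['n'])}"
        )
    if not splits.empty:
        lines.append("")
        lines.append("Mean-split subgroup correlations (volume <= mean -> low):")
        for _, r in splits.iterrows():
            lines.append(
                f"  {r['method']:>6} {r['stratum']:>4}: r_s = {r['r_s']:.2f} "
                f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}), "
                f"n = {int(r['n'])}"
            )
    if not icc.empty:
        lines.append("")
        lines.append("Inter-rater agreement, one-way ICC(1,1):")
        for _, r in icc.iterrows():
            lines.append(
                f"  {r['method']:>6}: ICC = {r['icc']:.2f}, p = {r['p']:.3g} "
                f"({int(r['n_targets'])} targets x {int(r['n_raters'])} raters)"
            )
    if not props.empty:
        lines.append("")
        lines.append("Feasibility proportions (exact 95% CI):")
        for _, r in props.iterrows():
            lines.append(
                f"  {r['label']}: {100 * r['point']:.0f}% "
                f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), "
                f"{int(r['k'])}/{int(r['n'])}"
            )
    text = "\n".join(lines) + "\n"

    report = StudyReport(summary=summary, correlations=correlations,
                         splits=splits, icc=icc, proportions=props, text=text)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        correlations.to_csv(out / "correlations.csv", index=False)
        if not splits.empty:
            splits.to_csv(out / "splits.csv", index=False)
        if not icc.empty:
            icc.to_csv(out / "icc.csv", index=False)
        if not props.empty:
            props.to_csv(out / "proportions.csv", index=False)
        (out / "report.txt").write_text(text)
        if plots:
            _scatter_plots(table, out)
    return report


def _scatter_plots(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for method, sub in table.groupby("method"):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(sub["value"], sub["volume_l"], s=12, alpha=0.7)
        ax.set_xlabel(f"{method} [{sub['units'].iloc[0]}]")
        ax.set_ylabel("exhaled volume [L]")
        ax.set_title(f"{method} vs exhaled volume")
        fig.tight_layout()
        fig.savefig(out / f"scatter_{method}.png", dpi=120)
        plt.close(fig)
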