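"""Growth and feed-efficiency trait derivation from weekly records.

Weekly body weight (BW, g) and feed intake (FI, g, consumed since the
previous weighing) recorded between four and ten weeks of age yield, per
individual:

* BW4, BW6, BW9, BW10 — body weights at the measurement ages;
* ADG  — average daily gain (BW_end - BW_start) / (7 * weeks), g/day;
* FCR  — feed conversion ratio, interval FI / interval gain;
* RFI  — residual feed intake, the residual of the regression
  AFI = a + b*ADG + c*MBW^0.75 + e, where AFI is the mean daily feed
  intake over the interval and MBW the mean of the weekly body weights
  inside it.

The three intervals are anchored at week four: (4,6), (4,9), (4,10), named
by their end week.  Each trait is screened once for outliers outside
mean +/- 3.5 SD; the RFI screen is applied to the regression residuals after
the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RFIRegression",
    "PhenotypeError",
    "compute_adg",
    "compute_fcr",
    "compute_rfi",
    "remove_outliers",
    "derive_phenotypes",
    "phenotypic_correlations",
    "descriptive_statistics",
    "INTERVALS",
    "TRAITS",
]

log = logging.getLogger(__name__)

#: week-4-anchored growth intervals, keyed by end week
INTERVALS = {6: (4, 6), 9: (4, 9), 10: (4, 10)}
DAYS_PER_WEEK = 7

TRAITS = (
    ["BW4", "BW6", "BW9", "BW10"]
    + [f"ADG{k}" for k in (6, 9, 10)]
    + [f"FCR{k}" for k in (6, 9, 10)]
    + [f"RFI{k}" for k in (6, 9, 10)]
)


class PhenotypeError(ValueError):
    pass


@dataclass
class RFIRegression:
    """OLS fit AFI ~ 1 + ADG + MBW^0.75 with per-individual residuals."""

    a: float  # intercept, g/day
    b: float  # coefficient on ADG
    c: float  # coefficient on MBW^0.75, g/day per g^0.75
    residuals: pd.Series  # g/day, indexed by individual

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


def _bw_wide(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot long records to individuals x weeks body weights."""
    return records.pivot_table(index="id", columns="week", values="bw",
                               aggfunc="first")


def _fi_wide(records: pd.DataFrame) -> pd.DataFrame:
    return records.pivot_table(index="id", columns="week", values="fi",
                               aggfunc="first")


def compute_adg(records: pd.DataFrame, start_week: int, end_week: int) -> pd.Series:
    """Average daily gain (g/day) over [start_week, end_week].

    Individuals missing either endpoint weight get a missing value.
    """
    bw = _bw_wide(records)
    days = DAYS_PER_WEEK * (end_week - start_week)
    s = bw.get(start_week)
    e = bw.get(end_week)
    if s is None or e is None:
        raise PhenotypeError(f"no BW records at weeks {start_week}/{end_week}")
    return ((e - s) / days).rename(f"ADG{end_week}")


def compute_fcr(records: pd.DataFrame, start_week: int, end_week: int) -> pd.Series:
    """Feed conversion ratio: interval feed intake / interval weight gain.

    Non-positive gain makes the ratio meaningless; those cells are set
    missing and logged.
    """
    bw = _bw_wide(records)
    fi = _fi_wide(records)
    weeks = [w for w in fi.columns if start_week < w <= end_week]
    total_fi = fi[weeks].sum(axis=1, min_count=len(weeks))
    gain = bw.get(end_week) - bw.get(start_week)
    bad = gain <= 0
    if bad.any():
        log.warning("FCR%d: %d individuals with non-positive gain set missing",
                    end_week, int(bad.sum()))
    fcr = total_fi / gain.where(~bad)
    return fcr.rename(f"FCR{end_week}")


def compute_rfi(adg: pd.Series, mbw: pd.Series, afi: pd.Series) -> RFIRegression:
    """Regress average daily feed intake on ADG and metabolic body weight.

    MBW enters as MBW^0.75.  Ordinary least squares on the complete cases;
    residuals are the RFI values.  With an intercept the residuals sum to
    zero exactly.
    """
    df = pd.concat({"adg": adg, "mbw": mbw, "afi": afi}, axis=1).dropna()
    if len(df) < 4:
        raise PhenotypeError(f"need >= 4 complete cases for RFI, got {len(df)}")
    X = np.column_stack(
        [np.ones(len(df)), df["adg"].to_numpy(), df["mbw"].to_numpy() ** 0.75]
    )
    if np.linalg.matrix_rank(X) < 3:
        raise PhenotypeError(
            "RFI design matrix is rank deficient (ADG or MBW constant/collinear)"
        )
    coef, *_ = np.linalg.lstsq(X, df["afi"].to_numpy(), rcond=None)
    resid = df["afi"].to_numpy() - X @ coef
    return RFIRegression(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        residuals=pd.Series(resid, index=df.index, name="rfi"),
    )


def remove_outliers(values: pd.Series, n_sd: float = 3.5):
    """Set values outside mean +/- n_sd * SD to missing (single pass).

    Mean and SD come from the unfiltered vector, so the rule is applied
    exactly once; a constant vector (SD = 0) removes nothing.
    Returns (filtered series, DataFrame log of removals).
    """
    obs = values.dropna()
    if len(obs) < 2:
        return values.copy(), pd.DataFrame(columns=["id", "value", "lo", "hi"])
    mu, sd = obs.mean(), obs.std(ddof=1)
    lo, hi = mu - n_sd * sd, mu + n_sd * sd
    out = (values < lo) | (values > hi)
    removed = pd.DataFrame(
        {"id": values.index[out], "value": values[out].to_numpy(),
         "lo": lo, "hi": hi}
    )
    return values.where(~out), removed


def derive_phenotypes(
    records: pd.DataFrame, outlier_sd: float = 3.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full trait table from long records (columns: id, week, bw, fi).

    Per-trait outlier screening is independent — an individual may be
    missing for RFI6 yet present for BW6 — and the RFI regression is fitted
    on inputs that already passed their own screens, with the 3.5-SD rule
    then applied to its residuals.

    Returns (wide PhenotypeTable indexed by id, removal log).
    """
    records = records.copy()
    records["id"] = records["id"].astype(str)
    bw = _bw_wide(records)
    fi = _fi_wide(records)

    table = pd.DataFrame(index=bw.index)
    logs = []

    def screen(name: str, s: pd.Series) -> pd.Series:
        filt, rem = remove_outliers(s, outlier_sd)
        if not rem.empty:
            rem = rem.assign(trait=name)
            logs.append(rem)
        return filt

    for w in (4, 6, 9, 10):
        if w in bw.columns:
            table[f"BW{w}"] = screen(f"BW{w}", bw[w])

    for end, (start, _) in ((k, v) for k, v in INTERVALS.items()):
        if start not in bw.columns or end not in bw.columns:
            log.warning("interval %d-%d skipped: endpoint weeks missing",
                        start, end)
            continue
        adg = screen(f"ADG{end}", compute_adg(records, start, end))
        fcr = screen(f"FCR{end}", compute_fcr(records, start, end))
        table[f"ADG{end}"] = adg
        table[f"FCR{end}"] = fcr

        weeks = [w for w in bw.columns if start <= w <= end]
        mbw = bw[weeks].mean(axis=1)
        fi_weeks = [w for w in fi.columns if start < w <= end]
        days = DAYS_PER_WEEK * (end - start)
        afi = fi[fi_weeks].sum(axis=1, min_count=len(fi_weeks)) / days
        reg = compute_rfi(adg, mbw, afi)
        table[f"RFI{end}"] = screen(f"RFI{end}", reg.residuals)

    removal_log = (
        pd.concat(logs, ignore_index=True)[["trait", "id", "value", "lo", "hi"]]
        if logs
        else pd.DataFrame(columns=["trait", "id", "value", "lo", "hi"])
    )
    table.index.name = "id"
    return table, removal_log


def phenotypic_correlations(table: pd.DataFrame):
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Pairwise-complete deletion; pairs with fewer than 3 complete
    observations are missing.  Returns (r matrix, p matrix).
    """
    cols = table.columns
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            if len(sub) < 3:
                continue
            res = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def descriptive_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait N, mean, SD, min, max (the standard descriptive layout)."""
    return pd.DataFrame(
        {
            "N": table.count(),
            "Mean": table.mean(),
            "SD": table.std(ddof=1),
            "Min": table.min(),
            "Max": table.max(),
        }
    )
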