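"""Two-group statistics between low-pH and high-pH sites.

Each target family's per-site gene frequencies are compared between the
two soil groups with an unpaired two-sample t-test — pooled-variance
Student's t by default (df = n_a + n_b - 2), Welch's variant with
Satterthwaite degrees of freedom as an option.  Two-tailed p-values come
from the t distribution (scipy's regularized incomplete beta machinery).
No multiple-testing correction is applied by default, matching per-gene
reporting; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import HIGH_PH, LOW_PH, RunConfig
from .io import PhoscanError


class CompareError(PhoscanError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    family_name: str
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    t: float
    df: float
    p: float
    significant: bool
    degenerate: bool = False


def ttest_unpaired(a, b, variant: str = "pooled") -> tuple[float, float, float]:
    """Unpaired two-sample t-test; returns (t, df, two-tailed p).

    ``a`` and ``b`` need at least two finite observations each.  The
    statistic is computed from means and sample variances; degenerate
    inputs (zero variance in both groups) give t = 0, p = 1 for equal
    means and p = 0 (infinite t) for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CompareError("each group needs at least two observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise CompareError("non-finite value in a group")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "pooled":
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    elif variant == "welch":
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = float(na + nb - 2)
    else:
        raise CompareError(f"unknown t-test variant {variant!r}")
    if se2 <= 0:
        if ma == mb:
            return 0.0, df, 1.0
        return math.copysign(math.inf, ma - mb), df, 0.0
    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


#: column order of the comparison TSV
COMPARISON_COLUMNS = [
    "family", "mean_low", "mean_high", "sd_low", "sd_high",
    "t", "df", "p", "significant", "degenerate",
]


def compare_groups(
    abundance: pd.DataFrame,
    config: RunConfig | None = None,
    value_column: str = "frequency",
    variant: str | None = None,
    alpha: float | None = None,
    multiple_testing: str | None = None,
) -> pd.DataFrame:
    """Per-family low-pH vs high-pH test over the abundance table.

    ``abundance`` needs columns ``site_id``, ``group``, ``family`` and
    the chosen value column (per-site gene frequencies by default).  The
    t statistic is oriented low minus high, so a gene depleted in acid
    soils gets a negative t.  A family observed nowhere (all values
    equal in both groups with zero spread) is flagged degenerate and not
    significant.
    """
    if config is not None:
        variant = variant or config.ttest_variant
        alpha = alpha if alpha is not None else config.alpha
        multiple_testing = multiple_testing or config.multiple_testing
    variant = variant or "pooled"
    alpha = alpha if alpha is not None else 0.05
    multiple_testing = multiple_testing or "none"

    results = []
    for family, sub in abundance.groupby("family", sort=True):
        if config is not None and family in config.families:
            if config.families[family].role != "target":
                continue
        low = sub.loc[sub["group"] == LOW_PH, value_column].dropna().to_numpy()
        high = sub.loc[sub["group"] == HIGH_PH, value_column].dropna().to_numpy()
        if low.size < 2 or high.size < 2:
            raise CompareError(
                f"family {family}: each pH group needs >= 2 sites "
                f"(got {low.size} low, {high.size} high)"
            )
        t, df, p = ttest_unpaired(low, high, variant)
        degenerate = (low.var(ddof=1) == 0.0 and high.var(ddof=1) == 0.0)
        results.append(
            {
                "family": family,
                "mean_low": low.mean(),
                "mean_high": high.mean(),
                "sd_low": low.std(ddof=1),
                "sd_high": high.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
                "degenerate": degenerate,
            }
        )
    frame = pd.DataFrame(results)
    if frame.empty:
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    p_eff = frame["p"].to_numpy()
    if multiple_testing == "bh":
        p_eff = bh_adjust(p_eff)
        frame["p_adjusted"] = p_eff
    elif multiple_testing != "none":
        raise CompareError(f"unknown multiple_testing option {multiple_testing!r}")
    frame["significant"] = (p_eff < alpha) & ~frame["degenerate"]
    cols = COMPARISON_COLUMNS + (
        ["p_adjusted"] if "p_adjusted" in frame.columns else []
    )
    return frame[cols]
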