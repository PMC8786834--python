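"""Cohort statistics: tie-aware Spearman correlations, Mann-Whitney
comparisons, %GP4 grouping and the RSEM transform.

All tests are two-sided and no multiplicity correction is applied by
default (each comparison is exploratory); Benjamini-Hochberg adjustment is
available as an opt-in for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "spearman",
    "correlation_matrix",
    "mann_whitney",
    "group_by_gp4",
    "transform_rsem",
    "benjamini_hochberg",
    "CENSORED_GP4_VALUE",
]

#: numeric stand-in for censored "<5" %GP4 entries.  Any value strictly
#: inside (0, 5) produces identical ranks (ties with other "<5" entries,
#: above exact 0 and below exact 5); the midpoint is used for transparency.
CENSORED_GP4_VALUE = 2.5


@dataclass
class CorrelationResult:
    rs: float
    p: float
    n: int
    note: str = "midrank ties; t-approximation p"


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    sizes: tuple[int, int]
    u: float
    p: float
    direction: str  # 'greater', 'less' or 'equal' median of group a vs b
    mode: str
    flagged: bool = False


def _encode(values) -> np.ndarray:
    """Coerce a column to float, mapping censored '<5' entries to 2.5."""
    arr = np.asarray(values, dtype=object)
    out = np.empty(arr.size, dtype=float)
    for i, v in enumerate(arr.ravel()):
        if isinstance(v, str):
            v = v.strip()
            if v.startswith("<"):
                bound = float(v[1:])
                if not (0 < CENSORED_GP4_VALUE < bound):
                    raise ValueError(f"censored value {v!r} incompatible with policy")
                out[i] = CENSORED_GP4_VALUE
            else:
                out[i] = float(v)
        elif v is None:
            out[i] = np.nan
        else:
            out[i] = float(v)
    return out


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties and t-approximation p.

    Censored "<5" entries are mapped to a common value inside (0, 5) before
    ranking.  Pairs with missing values are deleted pairwise.  A constant
    vector leaves the coefficient undefined and raises.
    """
    xv, yv = _encode(x), _encode(y)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise ValueError("constant vector: Spearman correlation undefined")
    res = sps.spearmanr(xv, yv)
    return CorrelationResult(rs=float(res.statistic), p=float(res.pvalue), n=int(xv.size))


def correlation_matrix(
    cohort: pd.DataFrame,
    variables: list[str],
    *,
    exclude_flagged_for: tuple[str, ...] = ("pctGP4", "pctGP4_value"),
    exclusion_column: str = "excluded_from_correlation",
) -> pd.DataFrame:
    """Symmetric long-format Spearman matrix over cohort variables.

    Returns a tidy frame (var1, var2, rs, p, n).  If the cohort carries an
    exclusion flag column, flagged lesions are dropped from pairs touching
    %GP4 (whose assessment motivated the flag) and kept for imaging-only
    pairs.  No multiplicity correction is applied.
    """
    rows = []
    flags = (
        cohort[exclusion_column].astype(bool)
        if exclusion_column in cohort.columns
        else pd.Series(False, index=cohort.index)
    )
    for i, v1 in enumerate(variables):
        for v2 in variables[i:]:
            if v1 == v2:
                rows.append({"var1": v1, "var2": v2, "rs": 1.0, "p": 0.0, "n": len(cohort)})
                continue
            sub = cohort
            if v1 in exclude_flagged_for or v2 in exclude_flagged_for:
                sub = cohort[~flags]
            res = spearman(sub[v1], sub[v2])
            rows.append({"var1": v1, "var2": v2, "rs": res.rs, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def _enumeration_threshold(n1: int, n2: int) -> bool:
    return (n1 + n2) <= 12


def mann_whitney(a, b, mode: str = "auto", labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    ``mode='auto'`` uses the exact null distribution for combined n <= 12
    without ties and the tie-corrected normal approximation otherwise;
    'exact' or 'asymptotic' force either.  Identical pooled values return
    p = 1 with a flag rather than a division-by-zero.
    """
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([av, bv])
    ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (_enumeration_threshold(av.size, bv.size) and not ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")

    if np.unique(pooled).size == 1:
        return GroupComparison(
            labels=labels,
            sizes=(av.size, bv.size),
            u=av.size * bv.size / 2.0,
            p=1.0,
            direction="equal",
            mode=method,
            flagged=True,
        )
    res = sps.mannwhitneyu(av, bv, alternative="two-sided", method=method)
    med_a, med_b = np.median(av), np.median(bv)
    direction = "greater" if med_a > med_b else ("less" if med_a < med_b else "equal")
    return GroupComparison(
        labels=labels,
        sizes=(av.size, bv.size),
        u=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        direction=direction,
        mode=method,
    )


def group_by_gp4(
    cohort: pd.DataFrame,
    cutoff: float = 10.0,
    *,
    gp4_column: str = "pctGP4",
    exclude: list | None = None,
) -> dict[str, pd.DataFrame]:
    """Partition ISUP 2-3 lesions into low (<= cutoff) and high (> cutoff) %GP4.

    Censored "<5" entries fall in the low group (their true value is below
    any sensible cutoff); the boundary value itself is low.  ISUP grade 1
    lesions (pure pattern 3) are excluded, as is any lesion listed in
    ``exclude``.
    """
    vals = _encode(cohort[gp4_column])
    if np.any(~np.isfinite(vals)):
        raise ValueError("unknown %GP4 censoring: unparseable entries present")
    keep = cohort["ISUP"].astype(int) >= 2
    if exclude:
        keep &= ~cohort["lesion_id"].isin(exclude) if "lesion_id" in cohort.columns else keep
    low = cohort[keep & (vals <= cutoff)]
    high = cohort[keep & (vals > cutoff)]
    return {"low": low, "high": high}


def transform_rsem(values, variant: str = "plus-one") -> tuple[np.ndarray, dict]:
    """log2 transform of RSEM expression values.

    The default is ``log2(value + 1)`` (monotone, defined at zero).  The
    literal ``log2(value - 1)`` variant is retained for comparability with
    conventions that state it, but is undefined for values <= 1, which are
    masked to NaN; the choice is recorded in the returned metadata.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("RSEM values must be non-negative")
    if variant == "plus-one":
        out = np.log2(v + 1.0)
    elif variant == "minus-one":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(v > 1.0, np.log2(np.clip(v - 1.0, 1e-300, None)), np.nan)
    else:
        raise ValueError("variant must be 'plus-one' or 'minus-one'")
    return out, {"transform": f"log2(value {'+' if variant == 'plus-one' else '-'} 1)"}


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Optional BH adjustment (not applied by default anywhere)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
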