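"""Phenotype and expression statistics.

Survival-rate arithmetic for the bile-salt challenge assay, extreme-group
selection (the tolerant / non-tolerant split), 2^-ddCt relative expression
from qPCR cycle thresholds, and the two group tests used on phenotypes:
one-way ANOVA and Kruskal-Wallis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StrainPhenotype:
    """One strain's bile-salt challenge outcome."""

    strain_id: str
    region: str
    china_part: str
    cfu_before: float
    cfu_after: float

    @property
    def survival_rate(self) -> float:
        return survival_rate(self.cfu_before, self.cfu_after)


def survival_rate(cfu_before: float | Sequence[float], cfu_after: float | Sequence[float]) -> float:
    """Percent viable cells remaining after bile exposure: 100 * after / before.

    Replicate counts are averaged before taking the ratio.
    """
    before = float(np.mean(cfu_before))
    after = float(np.mean(cfu_after))
    if before <= 0:
        raise ValueError("cfu_before must be positive")
    if after < 0:
        raise ValueError("cfu_after must be non-negative")
    return 100.0 * after / before


def select_extremes(
    phenotypes: pd.DataFrame,
    n_top: int | None = None,
    n_bottom: int | None = None,
    high_threshold: float | None = None,
    low_threshold: float | None = None,
) -> tuple[list[str], list[str]]:
    """Split strains into tolerant / non-tolerant extreme groups.

    ``phenotypes`` needs columns ``strain`` and ``survival_rate``.  Either
    count mode (top ``n_top`` and bottom ``n_bottom`` strains by survival
    rate) or threshold mode (rate >= ``high_threshold`` vs rate <=
    ``low_threshold``).  Ties break deterministically by strain id and the
    returned groups always satisfy: every tolerant rate > every non-tolerant
    rate.
    """
    df = phenotypes[["strain", "survival_rate"]].copy()
    if df["strain"].duplicated().any():
        raise ValueError("duplicate strain ids in phenotype table")

    count_mode = n_top is not None or n_bottom is not None
    threshold_mode = high_threshold is not None or low_threshold is not None
    if count_mode == threshold_mode:
        raise ValueError("specify either counts (n_top/n_bottom) or thresholds, not both")

    if count_mode:
        if n_top is None or n_bottom is None or n_top < 1 or n_bottom < 1:
            raise ValueError("both n_top and n_bottom must be positive")
        if n_top + n_bottom > len(df):
            raise ValueError("n_top + n_bottom exceeds the number of strains")
        by_rate = df.sort_values(["survival_rate", "strain"], ascending=[False, True])
        tolerant = by_rate.head(n_top)
        nontolerant = by_rate.tail(n_bottom)
    else:
        if high_threshold is None or low_threshold is None:
            raise ValueError("both thresholds are required in threshold mode")
        if high_threshold <= low_threshold:
            raise ValueError("high_threshold must exceed low_threshold")
        tolerant = df[df["survival_rate"] >= high_threshold]
        nontolerant = df[df["survival_rate"] <= low_threshold]
        if tolerant.empty:
            warnings.warn("no strain reaches the high survival threshold", stacklevel=2)
        if nontolerant.empty:
            warnings.warn("no strain falls below the low survival threshold", stacklevel=2)

    if not tolerant.empty and not nontolerant.empty:
        if tolerant["survival_rate"].min() <= nontolerant["survival_rate"].max():
            raise ValueError(
                "tolerant and non-tolerant groups overlap in survival rate; "
                "adjust counts or thresholds"
            )
    return sorted(tolerant["strain"]), sorted(nontolerant["strain"])


def ddct_expression(records: pd.DataFrame) -> float:
    """2^-ddCt fold-change for one strain x gene from a Ct table.

    ``records`` needs columns ``condition`` ('treated'/'control'),
    ``ct_target`` and ``ct_reference``; replicates are averaged before
    differencing.  dCt = mean(ct_target) - mean(ct_reference) per condition;
    ddCt = dCt_treated - dCt_control; fold-change = 2^-ddCt.
    """
    conditions = set(records["condition"])
    if not {"treated", "control"} <= conditions:
        raise ValueError("records must contain both 'treated' and 'control' conditions")
    dct = {}
    for cond in ("treated", "control"):
        sub = records[records["condition"] == cond]
        dct[cond] = sub["ct_target"].mean() - sub["ct_reference"].mean()
    ddct = dct["treated"] - dct["control"]
    return float(2.0 ** (-ddct))


def _as_groups(groups: Iterable[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrs):
        raise ValueError("empty group")
    return arrs


def anova_oneway(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within with df (k-1, N-k).

    Degenerate layouts are resolved explicitly: zero between-group variance
    gives (F=0, p=1); zero within-group variance with non-zero between gives
    (F=inf, p=0).
    """
    arrs = _as_groups(groups)
    k = len(arrs)
    n_total = sum(len(a) for a in arrs)
    if n_total - k < 1:
        raise ValueError("need at least 2 values in some group for a finite F")
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_between <= 0:
        return 0.0, 1.0
    if ss_within <= 0:
        return float("inf"), 0.0
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, k - 1, n_total - k))
    return float(f), p


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction; p from chi2 with k-1 df.

    All-identical data gives (H=0, p=1).
    """
    arrs = _as_groups(groups)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def region_tests(phenotypes: pd.DataFrame, group_col: str = "region") -> dict[str, float]:
    """ANOVA and Kruskal-Wallis of survival rates across geographic groups."""
    groups = [g["survival_rate"].to_numpy() for _, g in phenotypes.groupby(group_col) if len(g) > 0]
    f, p_anova = anova_oneway(groups)
    h, p_kw = kruskal_wallis(groups)
    return {"F": f, "anova_p": p_anova, "H": h, "kruskal_p": p_kw, "n_groups": len(groups)}
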