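"""Normality-gated statistics and comparative-Ct expression analysis.

Group comparisons follow the decision rule common in cell-biology papers:
every group is checked for normality (Shapiro-Wilk); if all groups pass,
an ANOVA is applied (repeated-measures when a pairing structure exists),
otherwise the Kruskal-Wallis rank test.  The chosen branch is returned for
audit, making the dispatch a pure function of the normality p-values.

Correlations dispatch the same way: Pearson when both variables look
normal, Spearman otherwise.

qRT-PCR quantification uses the comparative Ct method with a reference
gene: dCt = Ct_target - Ct_ref, ddCt = dCt - dCt_calibrator, relative
expression = 2**(-ddCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedSamples",
    "DispatchResult",
    "normality_gated_test",
    "auto_correlation",
    "comparative_ct",
]

ALPHA_DEFAULT = 0.05


@dataclass
class GroupedSamples:
    """Values grouped by factor level, optionally paired across groups.

    When `paired` is True all groups must have equal length and index i of
    each group refers to the same subject.
    """

    groups: dict[str, np.ndarray]
    paired: bool = False

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in self.groups.items():
            if vals.size < 3:
                raise ValueError(f"group {name!r} needs n >= 3")
        if self.paired:
            sizes = {v.size for v in self.groups.values()}
            if len(sizes) != 1:
                raise ValueError("paired groups must have equal sizes")


@dataclass
class DispatchResult:
    test: str  # 'anova' | 'rm_anova' | 'kruskal' | 'pearson' | 'spearman'
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    significant: bool


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p; constant samples count as non-normal (p = 0)."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def normality_gated_test(samples: GroupedSamples, alpha: float = ALPHA_DEFAULT) -> DispatchResult:
    """Shapiro-Wilk per group, then ANOVA (all normal) or Kruskal-Wallis."""
    norm_p = {}
    any_constant = False
    for name, vals in samples.groups.items():
        if np.ptp(vals) == 0:
            any_constant = True
            warnings.warn(f"group {name!r} is constant; forcing nonparametric branch", stacklevel=2)
        norm_p[name] = _shapiro_p(vals)
    all_normal = (not any_constant) and all(p > alpha for p in norm_p.values())
    arrays = list(samples.groups.values())
    if all_normal:
        if samples.paired:
            from statsmodels.stats.anova import AnovaRM

            n = arrays[0].size
            long = pd.DataFrame(
                {
                    "value": np.concatenate(arrays),
                    "group": np.repeat(list(samples.groups.keys()), n),
                    "subject": np.tile(np.arange(n), len(arrays)),
                }
            )
            res = AnovaRM(long, "value", "subject", within=["group"]).fit()
            stat = float(res.anova_table["F Value"].iloc[0])
            p = float(res.anova_table["Pr > F"].iloc[0])
            test = "rm_anova"
        else:
            stat, p = sps.f_oneway(*arrays)
            test = "anova"
    else:
        if np.ptp(np.concatenate(arrays)) == 0:  # all values identical across groups
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*arrays)
        test = "kruskal"
    return DispatchResult(test, float(stat), float(p), norm_p, bool(p < alpha))


def auto_correlation(x: Sequence[float], y: Sequence[float], alpha: float = ALPHA_DEFAULT) -> DispatchResult:
    """Pearson when both variables pass Shapiro-Wilk, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    norm_p = {"x": _shapiro_p(x), "y": _shapiro_p(y)}
    if all(p > alpha for p in norm_p.values()):
        r, p = sps.pearsonr(x, y)
        test = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        test = "spearman"
    return DispatchResult(test, float(r), float(p), norm_p, bool(p < alpha))


def comparative_ct(table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression by the comparative Ct method.

    `table` columns: sample, ct_target, ct_reference.  The calibrator
    sample gets expression exactly 1.
    """
    required = {"sample", "ct_target", "ct_reference"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    if (table[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    if calibrator not in set(table["sample"]):
        raise ValueError(f"calibrator {calibrator!r} not present")
    out = table.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    cal_dct = float(out.loc[out["sample"] == calibrator, "delta_ct"].iloc[0])
    out["delta_delta_ct"] = out["delta_ct"] - cal_dct
    out["rel_expression"] = 2.0 ** (-out["delta_delta_ct"])
    return out
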