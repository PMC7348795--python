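"""Gated group comparison: normality check, then ANOVA/Tukey or KW/Dunn-Holm.

The procedure used to score the migration experiments:

1. Shapiro–Wilk on every group at alpha = 0.05.  If all groups look normal
   the comparison is parametric, otherwise non-parametric.
2. Parametric branch: one-way ANOVA omnibus, Tukey HSD post-hoc (Tukey's
   familywise control is used as-is, no extra adjustment).
   Non-parametric branch: Kruskal–Wallis omnibus, Dunn's rank post-hoc with
   Holm step-down adjustment over the all-pairs family.
3. Significance flags: ** for p < 0.01, * for p < 0.05, ns otherwise.

Dunn's test is implemented here directly (pooled mid-ranks with tie
correction, normal approximation), as is standard:

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1))  over tie groups of size t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import UsageError

ALPHA_GATE = 0.05


def flag(p: float) -> str:
    """Significance marker: '**' if p < 0.01, '*' if p < 0.05, 'ns' otherwise."""
    if not 0.0 <= p <= 1.0:
        raise UsageError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for label, values in out.items():
        if values.size < 3:
            raise UsageError(
                f"group {label!r} has {values.size} observations; need >= 3"
            )
    return out


def normality_gate(
    groups: dict[str, np.ndarray], alpha: float = ALPHA_GATE
) -> str:
    """Route a comparison: 'parametric' iff every group passes Shapiro–Wilk.

    Zero-variance (constant) groups cannot be tested and are routed
    non-parametric with a warning.
    """
    for label, values in _as_groups(groups).items():
        if np.ptp(values) == 0.0:
            warnings.warn(
                f"group {label!r} is constant; Shapiro-Wilk undefined, "
                "routing non-parametric",
                stacklevel=2,
            )
            return "nonparametric"
        if sps.shapiro(values).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below raw)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Dunn z tests on pooled mid-ranks, raw (unadjusted) p-values.

    Returns a frame with columns group_a, group_b, z, p_raw.
    """
    groups = _as_groups(groups)
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        size = groups[g].size
        mean_rank[g] = float(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(variance_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Outcome of the gated comparison.

    pairwise has one row per unordered group pair with the adjusted p-value
    and significance flag; `vs_control` restricts it to pairs involving the
    control group.
    """

    branch: str
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame
    control: str | None = None

    @property
    def vs_control(self) -> pd.DataFrame:
        if self.control is None:
            return self.pairwise
        mask = (self.pairwise["group_a"] == self.control) | (
            self.pairwise["group_b"] == self.control
        )
        return self.pairwise[mask].reset_index(drop=True)


def compare_groups(
    groups: dict[str, np.ndarray],
    control: str | None = None,
    alpha: float = ALPHA_GATE,
    branch: str | None = None,
) -> ComparisonReport:
    """Run the full gated procedure on labelled samples.

    Branches on the Shapiro–Wilk gate (or on an explicit `branch` of
    'parametric'/'nonparametric' when the analyst has fixed it), runs the
    omnibus test, then the matching all-pairs post-hoc (Tukey HSD or Dunn
    with Holm), and attaches significance flags to every pair.
    """
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise UsageError("need at least 2 groups to compare")
    if control is not None and control not in groups:
        raise UsageError(f"control group {control!r} not among {list(groups)}")
    if branch is None:
        branch = normality_gate(groups, alpha)
    elif branch not in ("parametric", "nonparametric"):
        raise UsageError("branch must be 'parametric' or 'nonparametric'")
    labels = list(groups)
    samples = [groups[g] for g in labels]
    if branch == "parametric":
        omnibus = sps.f_oneway(*samples)
        omnibus_name = "one-way ANOVA"
        hsd = sps.tukey_hsd(*samples)
        rows = [
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "adjusted_p": float(hsd.pvalue[i, j]),
            }
            for i, j in combinations(range(len(labels)), 2)
        ]
        pairwise = pd.DataFrame(rows)
    else:
        omnibus = sps.kruskal(*samples)
        omnibus_name = "Kruskal-Wallis"
        pairwise = dunn_test(groups)
        pairwise["adjusted_p"] = holm_adjust(pairwise["p_raw"].to_numpy())
        pairwise = pairwise[["group_a", "group_b", "z", "p_raw", "adjusted_p"]]
    pairwise["flag"] = [flag(p) for p in pairwise["adjusted_p"]]
    return ComparisonReport(
        branch=branch,
        omnibus_test=omnibus_name,
        omnibus_statistic=float(omnibus.statistic),
        omnibus_p=float(omnibus.pvalue),
        pairwise=pairwise,
        control=control,
    )
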