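"""Shared ANOVA / effect-size / post-hoc machinery.

One-way ANOVA with eta-squared, Bonferroni family adjustment, and Tukey
HSD pairwise comparisons summarized as a compact letter display: groups
sharing a letter are not significantly different.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["anova_oneway", "tukey_letters", "compare_groups"]


def anova_oneway(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across named groups, with eta^2 = SS_between / SS_total.

    Degenerate inputs (zero total variance) return F = 0, p = 1, eta^2 = 0:
    identical groups carry no evidence of a difference.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise ValueError("each group needs at least 2 observations")
    allv = np.concatenate(list(arrays.values()))
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values()))
    if ss_total <= 0:
        return {"F": 0.0, "p": 1.0, "eta_sq": 0.0, "ss_between": 0.0, "ss_total": 0.0}
    f, p = stats.f_oneway(*arrays.values())
    if np.isnan(f):  # identical groups with zero within-variance
        f, p = 0.0, 1.0
    return {
        "F": float(f),
        "p": float(p),
        "eta_sq": ss_between / ss_total,
        "ss_between": ss_between,
        "ss_total": ss_total,
    }


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * family_size)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, p * family_size)


def tukey_letters(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict[str, str]:
    """Tukey HSD pairwise comparisons condensed to a compact letter display.

    Builds the graph of non-significant pairs and assigns one letter per
    maximal clique (insertion order follows descending group means), so
    groups share a letter iff no member pair differs at level ``alpha``.
    """
    import networkx as nx

    names = sorted(groups, key=lambda k: -np.mean(groups[k]))
    if len(names) == 1:
        return {names[0]: "a"}
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    labels = np.concatenate([[k] * len(groups[k]) for k in names])
    if np.ptp(values) == 0:  # all observations identical: nothing distinguishable
        return {k: "a" for k in names}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero within-group variance
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    g = nx.Graph()
    g.add_nodes_from(names)
    summary = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    for _, row in summary.iterrows():
        if not row["reject"]:
            g.add_edge(str(row["group1"]), str(row["group2"]))
    cliques = list(nx.find_cliques(g))
    # order cliques by the best (highest-mean) member so 'a' marks the top group
    cliques.sort(key=lambda c: min(names.index(m) for m in c))
    letters: dict[str, str] = {k: "" for k in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member] += letter
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def compare_groups(
    groups: dict[str, np.ndarray], family_size: int = 1, alpha: float = 0.05
) -> dict:
    """ANOVA + Bonferroni adjustment + Tukey letters in one report.

    With a single group only the descriptive summary is returned (no
    comparison is possible).
    """
    if len(groups) == 1:
        ((name, vals),) = groups.items()
        return {
            "means": {name: float(np.mean(vals))},
            "sds": {name: float(np.std(vals, ddof=1))},
            "n": {name: int(len(vals))},
        }
    a = anova_oneway(groups)
    a["p_adjusted"] = bonferroni(a["p"], family_size)
    a["letters"] = tukey_letters(groups, alpha=alpha)
    a["means"] = {k: float(np.mean(v)) for k, v in groups.items()}
    a["sds"] = {k: float(np.std(v, ddof=1)) for k, v in groups.items()}
    a["n"] = {k: int(len(v)) for k, v in groups.items()}
    return a
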