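"""Group comparison and regression workflow for per-field tables.

The routing rule mirrors the study design: each response variable is
first gated by a pooled Shapiro-Wilk test at alpha = 0.05.  Normal
variables go to one-way ANOVA with unprotected Fisher-LSD pairwise
comparisons; non-normal variables go to Kruskal-Wallis (tie-corrected
H, midranks) with Dunn-type pairwise z-tests.  Pairwise outcomes are
summarised as a compact letter display: groups sharing no letter
differ at p < 0.05.  Relationships between the trophism indices and
the fractal dimension are quantified by simple linear regression
reporting the standardized slope (beta) and its two-sided p-value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "RegressionResult",
    "normality_gate",
    "compare_groups",
    "simple_regression",
    "fisher_lsd_pairwise",
    "dunn_pairwise",
    "compact_letter_display",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityResult:
    gate: str  # 'normal' | 'non-normal'
    w: float
    p: float


@dataclass
class ComparisonResult:
    variable: str
    grouping: str
    n: int
    gate: str
    test: str  # 'anova_fisher_lsd' | 'kruskal_wallis'
    statistic: float
    p_value: float
    pairwise_p: pd.DataFrame  # columns: group_a, group_b, p
    letters: dict[str, str]

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    response: str
    beta_standardized: float
    p_value: float
    n: int


def normality_gate(values, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk gate: 'normal' iff p >= alpha."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    w, p = sps.shapiro(x)
    return NormalityResult(gate="normal" if p >= alpha else "non-normal", w=float(w), p=float(p))


def fisher_lsd_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Unprotected Fisher-LSD pairwise t-tests on the pooled within-group MSE."""
    names = list(groups)
    all_x = [np.asarray(groups[g], dtype=float) for g in names]
    n_tot = sum(x.size for x in all_x)
    k = len(names)
    df = n_tot - k
    mse = sum(((x - x.mean()) ** 2).sum() for x in all_x) / df
    rows = []
    for (ga, xa), (gb, xb) in itertools.combinations(zip(names, all_x), 2):
        se = np.sqrt(mse * (1 / xa.size + 1 / xb.size))
        t = (xa.mean() - xb.mean()) / se if se > 0 else np.inf
        rows.append({"group_a": ga, "group_b": gb, "p": 2 * sps.t.sf(abs(t), df)})
    return pd.DataFrame(rows)


def dunn_pairwise(groups: dict[str, np.ndarray], adjust: str | None = None) -> pd.DataFrame:
    """Dunn-type pairwise z-tests on pooled midranks with tie correction.

    ``adjust`` in {None, 'bonferroni', 'holm'}; unadjusted by default.
    """
    names = list(groups)
    sizes = {g: np.asarray(groups[g], dtype=float).size for g in names}
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1 / sizes[ga] + 1 / sizes[gb]))
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else np.inf
        rows.append({"group_a": ga, "group_b": gb, "p": 2 * sps.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    m = len(out)
    if adjust == "bonferroni":
        out["p"] = np.minimum(out["p"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def compact_letter_display(
    group_order: list[str], pairwise_p: pd.DataFrame, alpha: float = ALPHA
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing no letter differ at p < alpha in the supplied
    pairwise table; splitting occurs only on significant pairs, so
    non-significant pairs keep a common letter whenever consistent.
    """
    columns: list[set[str]] = [set(group_order)]
    sig = [
        (r.group_a, r.group_b)
        for r in pairwise_p.itertuples()
        if r.p < alpha
    ]
    for a, b in sig:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns contained in another
        columns = []
        for c in sorted(new_cols, key=len, reverse=True):
            if c and not any(c <= kept for kept in columns):
                columns.append(c)
    # stable letter order: by first member in the caller's group order
    columns.sort(key=lambda c: min(group_order.index(g) for g in c))
    letters = {g: "" for g in group_order}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    grouping: str,
    alpha: float = ALPHA,
    posthoc_adjust: str | None = None,
) -> ComparisonResult:
    """Gate-routed omnibus comparison with post-hoc letters.

    Normal variables (pooled Shapiro-Wilk p >= alpha): one-way ANOVA F
    with Fisher-LSD pairwise letters. Otherwise: Kruskal-Wallis H with
    Dunn pairwise letters.  The post-hoc is protected: letters split
    only when the omnibus test itself rejects at ``alpha`` (otherwise
    every group shares one letter), which keeps the family-wise false
    split rate at the omnibus level.
    """
    df = table[[variable, grouping]].dropna()
    group_names = list(pd.unique(df[grouping]))
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups to compare")
    groups = {g: df.loc[df[grouping] == g, variable].to_numpy(float) for g in group_names}
    for g, x in groups.items():
        if x.size == 0:
            raise ValueError(f"empty group {g!r}")
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pooled = df[variable].to_numpy(float)
    gate = normality_gate(pooled, alpha=alpha)

    if gate.gate == "normal":
        stat, p = sps.f_oneway(*groups.values())
        pairwise = fisher_lsd_pairwise(groups)
        test = "anova_fisher_lsd"
    else:
        stat, p = sps.kruskal(*groups.values())
        pairwise = dunn_pairwise(groups, adjust=posthoc_adjust)
        test = "kruskal_wallis"
    if p < alpha:
        letters = compact_letter_display(group_names, pairwise, alpha=alpha)
    else:
        letters = {g: "a" for g in group_names}
    return ComparisonResult(
        variable=variable,
        grouping=grouping,
        n=int(pooled.size),
        gate=gate.gate,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        pairwise_p=pairwise,
        letters=letters,
    )


def simple_regression(x, y, predictor: str = "x", response: str = "y") -> RegressionResult:
    """Simple linear regression; beta is the standardized slope.

    For one predictor the standardized slope equals the Pearson
    correlation; the p-value is the two-sided t-test on the raw slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    fit = sps.linregress(x, y)
    sy = y.std(ddof=1)
    beta = float(fit.slope * x.std(ddof=1) / sy) if sy > 0 else 0.0
    return RegressionResult(
        predictor=predictor,
        response=response,
        beta_standardized=beta,
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
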