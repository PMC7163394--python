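"""Nested fixed-effect ANOVA and repeatability statistics.

Two models, both all-fixed with custom error-term mapping:

* full model (daily records):
  ``y = mu + breed + goat(breed) + day(goat) + period + breed:period + e``,
  where the day-within-goat effect tested against the residual measures the
  *within-period* repeatability (a large p-value = days agree = repeatable);
* simplified model (goat-period means): the same without the day term, with
  the breed effect tested against the goat-within-breed mean square.

Between-period repeatability of a trait is the intraclass ratio
``s2_between / (s2_between + s2_within)`` of the goat-period means, with the
between-goat component from the one-way ANOVA method of moments.
Sums of squares are sequential (term order as listed), computed by least
squares on growing design matrices, so mild unbalance from missing goat-days
is handled naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    response: str
    table: pd.DataFrame  # index: term; columns: df, ss, ms, F, p, error_term
    residual_ss: float
    residual_df: int

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


@dataclass
class RepeatabilityResult:
    trait: str
    sigma2_between: float
    sigma2_within: float

    @property
    def ratio(self) -> float:
        total = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / total if total > 0 else 0.0


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def _term_matrix(df: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    combined = df[cols[0]].astype(str)
    for c in cols[1:]:
        combined = combined + "|" + df[c].astype(str)
    return _dummies(combined)


def _sequential_anova(df: pd.DataFrame, response: str, terms: list[str],
                      error_map: dict[str, str]) -> AnovaResult:
    """Sequential (type-I) sums of squares by nested least-squares fits.

    ``terms`` are factor names or ``a:b`` interactions; dummies are appended
    in order and each term's SS is the drop in residual SSE, its df the gain
    in design-matrix rank (robust to the rank deficiency of nested dummies).
    """
    y = df[response].to_numpy(dtype=float)
    mask = np.isfinite(y)
    if not mask.all():
        df = df.loc[mask]
        y = y[mask]
    n = y.size
    X = np.ones((n, 1))
    rank_prev = 1
    sse_prev = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for term in terms:
        X = np.hstack([X, _term_matrix(df, term)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        rows.append({"term": term, "df": int(rank - rank_prev),
                     "ss": max(sse_prev - sse, 0.0)})
        rank_prev, sse_prev = rank, sse
    resid_df = n - rank_prev
    if resid_df <= 0:
        raise ValueError(
            "model is saturated (no residual degrees of freedom); "
            "terms are confounded with the residual"
        )
    resid_ms = sse_prev / resid_df
    table = pd.DataFrame(rows).set_index("term")
    if (table["df"] == 0).any():
        bad = table.index[table["df"] == 0].tolist()
        raise ValueError(f"terms fully confounded with earlier terms: {bad}")
    table["ms"] = table["ss"] / table["df"]
    Fs, ps, errs = [], [], []
    for term in table.index:
        denom_name = error_map.get(term, "residual")
        if denom_name == "residual":
            denom_ms, denom_df = resid_ms, resid_df
        else:
            denom_ms = table.loc[denom_name, "ms"]
            denom_df = int(table.loc[denom_name, "df"])
        F = table.loc[term, "ms"] / denom_ms if denom_ms > 0 else np.inf
        Fs.append(F)
        ps.append(float(stats.f.sf(F, table.loc[term, "df"], denom_df)))
        errs.append(denom_name)
    table["F"], table["p"], table["error_term"] = Fs, ps, errs
    return AnovaResult(response=response, table=table,
                       residual_ss=sse_prev, residual_df=resid_df)


FULL_TERMS = ["breed", "goat_id", "goat_id:day", "period", "breed:period"]
FULL_ERROR_MAP = {"breed": "goat_id"}
SIMPLE_TERMS = ["breed", "goat_id", "period", "breed:period"]
SIMPLE_ERROR_MAP = {"breed": "goat_id"}


def fit_full_anova(records: pd.DataFrame, response: str) -> AnovaResult:
    """Full nested model on daily records; the ``goat_id:day`` term is the
    day-within-breed-and-goat effect, tested on the residual."""
    counts = records.groupby(["goat_id", "period"]).size()
    if (counts < 2).all():
        raise ValueError("need >= 2 days per goat-period to separate the day "
                         "effect from the residual")
    return _sequential_anova(records, response, FULL_TERMS, FULL_ERROR_MAP)


def fit_simplified_anova(mean_table: pd.DataFrame, response: str) -> AnovaResult:
    """Simplified model on goat-period means; breed tested on goat-within-
    breed, period and breed:period on the residual."""
    return _sequential_anova(mean_table, response, SIMPLE_TERMS, SIMPLE_ERROR_MAP)


def within_period_repeatability(anova: AnovaResult,
                                threshold: float = 0.95) -> dict:
    """Within-period repeatability decision from the full model.

    A day-within-goat p-value above ``threshold`` (default 0.95) means the
    day effect is negligible relative to residual noise, i.e. consecutive
    days agree and the trait is repeatable within a period.
    """
    p = anova.p_value("goat_id:day")
    return {"trait": anova.response, "day_p": p,
            "repeatable": bool(p > threshold), "threshold": threshold}


def between_period_correlations(mean_table: pd.DataFrame,
                                response: str) -> pd.DataFrame:
    """Pearson correlations of per-goat means between every pair of periods.

    Pairwise-complete over goats; each cell carries r, its two-sided p-value
    and significance stars (* p<0.05, ** p<0.01).  Pairs with fewer than 3
    complete goats are NaN.
    """
    wide = mean_table.pivot(index="goat_id", columns="period", values=response)
    periods = list(wide.columns)
    rows = []
    for i, p1 in enumerate(periods):
        for p2 in periods[i + 1:]:
            pair = wide[[p1, p2]].dropna()
            if len(pair) < 3:
                rows.append({"period_1": p1, "period_2": p2, "n": len(pair),
                             "r": np.nan, "p": np.nan, "stars": ""})
                continue
            r, p = stats.pearsonr(pair[p1], pair[p2])
            stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append({"period_1": p1, "period_2": p2, "n": len(pair),
                         "r": float(r), "p": float(p), "stars": stars})
    out = pd.DataFrame(rows)
    out.insert(0, "trait", response)
    return out


def repeatability_ratio(mean_table: pd.DataFrame,
                        response: str) -> RepeatabilityResult:
    """Between-period repeatability: one-way variance decomposition of the
    goat-period means by goat.

    ``s2_within`` is the within-goat mean square across periods;
    ``s2_between`` is the method-of-moments between-goat component
    ``(MSB - MSW) / n0`` (``n0`` the effective periods per goat), truncated
    at zero.  The ratio estimates the squared correlation between repeated
    measures of the same goat at different periods.
    """
    sub = mean_table[["goat_id", response]].dropna()
    counts = sub.groupby("goat_id").size()
    counts = counts[counts >= 2]
    if counts.empty:
        raise ValueError("need >= 2 periods per goat for a repeatability ratio")
    sub = sub[sub["goat_id"].isin(counts.index)]
    g = len(counts)
    N = int(counts.sum())
    grand = sub[response].mean()
    by_goat = sub.groupby("goat_id")[response]
    ssb = float((counts * (by_goat.mean() - grand) ** 2).sum())
    ssw = float(((sub[response] - by_goat.transform("mean")) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    n0 = (N - float((counts**2).sum()) / N) / (g - 1)
    s2b = max((msb - msw) / n0, 0.0)
    return RepeatabilityResult(trait=response, sigma2_between=s2b,
                               sigma2_within=msw)


def ls_means(anova_df: pd.DataFrame, response: str, factor: str,
             error_ms: float, error_df: int, alpha: float = 0.05) -> pd.DataFrame:
    """Factor-level means with a compact letter display.

    Levels whose pairwise t-test (on the supplied error mean square) is not
    significant at ``alpha`` share a letter.  For balanced data these least-
    squares means coincide with arithmetic level means.
    """
    groups = anova_df.groupby(factor)[response]
    means = groups.mean()
    ns = groups.size()
    order = means.sort_values(ascending=False).index
    letters = {lvl: "" for lvl in order}
    current = 0
    assigned: list[set] = []
    for lvl in order:
        placed = False
        for grp in assigned:
            ref = max(grp, key=lambda l: means[l])
            se = np.sqrt(error_ms * (1 / ns[lvl] + 1 / ns[ref]))
            tval = abs(means[lvl] - means[ref]) / se if se > 0 else np.inf
            if stats.t.sf(tval, error_df) * 2 >= alpha:
                grp.add(lvl)
                placed = True
        if not placed:
            assigned.append({lvl})
    for i, grp in enumerate(assigned):
        for lvl in grp:
            letters[lvl] += chr(ord("a") + i)
    current = pd.DataFrame({
        "level": list(means.index),
        "mean": means.to_numpy(),
        "n": ns.to_numpy(),
        "letters": [letters[lvl] for lvl in means.index],
    })
    current.insert(0, "factor", factor)
    current.insert(0, "trait", response)
    return current
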