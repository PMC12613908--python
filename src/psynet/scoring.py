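"""Scale scoring, the 37-node matrix, the composite risk score and
Table-1-style descriptives.

Scoring conventions
-------------------
* PHQ-9 / GAD-7 / UCLA-3 totals: item sums (ranges 0-27, 0-21, 3-9).
* RSES total: sum after reverse-coding the five negatively worded items
  (range 0-30, higher = higher self-esteem).
* MSPSS subscales: 4-item means on the 1-7 response scale.
* SOI-R attitude/desire: 3-item means after reverse-coding item 6
  (config switch ``soi_score="sum"`` reproduces the summed 3-15 format;
  the two are affinely related, so rank-based networks are unaffected).
* SIHS subscales: item sums (higher = greater acceptance of one's
  sexual orientation, i.e. lower internalized homonegativity).

The composite high-risk sexual behavior score is the sum of the condom-use
code c (1 = no sex in the past six months, 2 = always condoms,
3 = sometimes, 4 = never) and the partner-count code m (1-5), so s = c + m
ranges 2-9. UAI (unprotected anal intercourse) is c in {3, 4}; MSP
(multiple sexual partnerships) is m >= 3 (two or more partners).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort, ConfigurationError
from .scales import DEFAULT_SCALE_MAP, Scale, ScaleMap

AGE_CUTOFF = 33  # approximates the sample mean age (33.4)

PHQ_CUTOFF = 10  # moderate-to-severe depression screen
GAD_CUTOFF = 10  # moderate-to-severe anxiety screen
UCLA_CUTOFF = 6  # common loneliness screening convention


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, Cohort):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expected a Cohort or DataFrame of raw items")


def _reverse_frame(scale: Scale, items: pd.DataFrame) -> pd.DataFrame:
    """Reverse-code the scale's negatively keyed items."""
    out = items.copy()
    lo, hi = scale.item_range
    for col in scale.reverse_items:
        out[col] = lo + hi - out[col]
    return out


class ScaleScorer(BaseEstimator, TransformerMixin):
    """Transformer from raw item responses to the 37-column node matrix.

    Parameters
    ----------
    scale_map : ScaleMap, default: the study map.
    item_polarity : {"aligned", "raw"}
        "aligned" (default) reverse-codes negatively worded item *nodes*
        onto a common direction (higher = more of the construct, e.g. more
        self-esteem); "raw" leaves item nodes as responded.
    soi_score : {"mean", "sum"}
        Subscale score convention for SOI-R facets.

    After :meth:`fit`, ``node_labels_`` and ``node_construct_`` describe
    the 37 nodes. :meth:`transform` returns the node matrix;
    :meth:`scale_totals` returns the conventional scale/subscale scores.
    """

    def __init__(self, scale_map=None, item_polarity="aligned", soi_score="mean"):
        self.scale_map = scale_map
        self.item_polarity = item_polarity
        self.soi_score = soi_score

    def _map(self) -> ScaleMap:
        return self.scale_map if self.scale_map is not None else DEFAULT_SCALE_MAP

    def fit(self, X, y=None):
        if self.item_polarity not in ("aligned", "raw"):
            raise ConfigurationError(f"item_polarity {self.item_polarity!r}")
        if self.soi_score not in ("mean", "sum"):
            raise ConfigurationError(f"soi_score {self.soi_score!r}")
        sm = self._map()
        df = _as_frame(X)
        for col in sm.item_columns():
            if col not in df.columns:
                raise ConfigurationError(f"item column {col!r} missing")
        self.scale_map_ = sm
        self.node_labels_ = sm.node_labels()
        self.node_construct_ = sm.node_construct()
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        """Raw items -> participants x 37 node matrix."""
        if not hasattr(self, "scale_map_"):
            self.fit(X)
        df = _as_frame(X)
        sm = self.scale_map_
        cols: dict[str, pd.Series] = {}
        for scale in sm.scales.values():
            items = df[list(scale.items)].astype(float)
            if items.isna().any().any():
                raise ValueError(
                    f"missing values in {scale.name} items; apply listwise "
                    "deletion before scoring nodes"
                )
            if scale.node_rule == "item":
                use = _reverse_frame(scale, items) if self.item_polarity == "aligned" else items
                for col in scale.items:
                    cols[col] = use[col]
            elif scale.node_rule == "subscale":
                scored = _reverse_frame(scale, items)
                for sub, members in scale.subscales.items():
                    agg = scored[list(members)]
                    how = scale.subscale_score
                    if scale.name == "SOI":
                        how = self.soi_score
                    cols[sub] = agg.sum(axis=1) if how == "sum" else agg.mean(axis=1)
        out = pd.DataFrame(cols, index=df.index)[self.node_labels_]
        return out

    def scale_totals(self, X) -> pd.DataFrame:
        """Conventional totals: PHQ, GAD, UCLA, RSES sums + 8 subscales."""
        if not hasattr(self, "scale_map_"):
            self.fit(X)
        df = _as_frame(X)
        sm = self.scale_map_
        cols: dict[str, pd.Series] = {}
        for scale in sm.scales.values():
            items = _reverse_frame(scale, df[list(scale.items)].astype(float))
            if scale.total_score == "sum":
                cols[f"{scale.name}_total"] = items.sum(axis=1)
            for sub, members in scale.subscales.items():
                how = self.soi_score if scale.name == "SOI" else scale.subscale_score
                agg = items[list(members)]
                cols[sub] = agg.sum(axis=1) if how == "sum" else agg.mean(axis=1)
        return pd.DataFrame(cols, index=df.index)


def score_scales(X, scale_map=None, item_polarity="aligned", soi_score="mean"):
    """Convenience wrapper: returns ``(scale_totals, node_matrix)``."""
    scorer = ScaleScorer(scale_map, item_polarity, soi_score).fit(X)
    return scorer.scale_totals(X), scorer.transform(X)


def composite_risk(X, scale_map: ScaleMap | None = None) -> pd.DataFrame:
    """Composite high-risk sexual behavior score per participant.

    Returns a frame with columns ``condom_use``, ``partner_count``,
    ``risk_score`` (= c + m, range 2-9), ``uai`` and ``msp`` flags.
    """
    sm = scale_map or DEFAULT_SCALE_MAP
    df = _as_frame(X)
    c = df[sm.condom_column].astype(float)
    m = df[sm.partner_column].astype(float)
    if not c.isin([1, 2, 3, 4]).all():
        bad = sorted(set(c[~c.isin([1, 2, 3, 4])]))
        raise ValueError(f"condom-use codes outside 1-4: {bad}")
    if not m.isin([1, 2, 3, 4, 5]).all():
        bad = sorted(set(m[~m.isin([1, 2, 3, 4, 5])]))
        raise ValueError(f"partner-count codes outside 1-5: {bad}")
    return pd.DataFrame(
        {
            "condom_use": c.astype(int),
            "partner_count": m.astype(int),
            "risk_score": (c + m).astype(int),
            "uai": c.isin([3, 4]),
            "msp": m >= 3,
        },
        index=df.index,
    )


def split_by_age(ages, cutoff: float = AGE_CUTOFF):
    """Partition into (age < cutoff, age >= cutoff) boolean masks."""
    age = np.asarray(pd.Series(ages).astype(float))
    if np.isnan(age).any():
        raise ValueError("missing ages; apply listwise deletion first")
    young = age < cutoff
    old = ~young
    if not old.any() or not young.any():
        warnings.warn("age split produced an empty group", stacklevel=2)
    return young, old


def _ttest(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return np.nan, np.nan
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _chi2(cat, group):
    tab = pd.crosstab(cat, group)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def descriptives(
    cohort, scale_map: ScaleMap | None = None, cutoff: float = AGE_CUTOFF
) -> dict:
    """Table-1-shaped descriptives with the age-group comparison.

    Continuous variables: mean (SD) per group + two-sample t-test.
    Categoricals: n (%) per group + Pearson chi-square (no continuity
    correction). Also reports screening prevalences: depression
    (PHQ-9 >= 10), anxiety (GAD-7 >= 10), both, loneliness (UCLA-3 >= 6),
    UAI and MSP.
    """
    sm = scale_map or DEFAULT_SCALE_MAP
    df = _as_frame(cohort)
    totals = ScaleScorer(sm).fit(df).scale_totals(df)
    risk = composite_risk(df, sm)
    young, old = split_by_age(df[sm.age_column], cutoff)
    groups = {"total": np.ones(len(df), bool), "young": young, "old": old}

    continuous = {"age": df[sm.age_column].astype(float)}
    for col in totals.columns:
        continuous[col] = totals[col]
    continuous["condom_use"] = risk["condom_use"].astype(float)
    continuous["partner_count"] = risk["partner_count"].astype(float)

    cont_rows = {}
    for name, series in continuous.items():
        row = {}
        for g, mask in groups.items():
            vals = series[mask]
            row[f"{g}_mean"] = float(vals.mean())
            row[f"{g}_sd"] = float(vals.std(ddof=1)) if mask.sum() > 1 else np.nan
        row["t"], row["p"] = _ttest(series[young], series[old])
        cont_rows[name] = row

    cat_rows = {}
    group_label = np.where(young, "young", "old")
    for name in sm.demographic_columns:
        if name not in df.columns:
            continue
        series = df[name]
        counts = {}
        for g, mask in groups.items():
            vc = series[mask].value_counts()
            denom = series[mask].notna().sum()
            counts[g] = {
                str(k): {"n": int(v), "pct": round(100.0 * v / denom, 1)}
                for k, v in vc.items()
            }
        chi2, p = _chi2(series, group_label)
        cat_rows[name] = {"counts": counts, "chi2": chi2, "p": p}

    flags = pd.DataFrame(
        {
            "depression": totals["PHQ_total"] >= PHQ_CUTOFF,
            "anxiety": totals["GAD_total"] >= GAD_CUTOFF,
            "both": (totals["PHQ_total"] >= PHQ_CUTOFF)
            & (totals["GAD_total"] >= GAD_CUTOFF),
            "loneliness": totals["UCLA_total"] >= UCLA_CUTOFF,
            "uai": risk["uai"],
            "msp": risk["msp"],
        }
    )
    prevalence = {}
    for name, col in flags.items():
        prevalence[name] = {
            g: {
                "n": int(col[mask].sum()),
                "pct": round(100.0 * col[mask].mean(), 1),
            }
            for g, mask in groups.items()
        }

    return {
        "n": {g: int(mask.sum()) for g, mask in groups.items()},
        "continuous": cont_rows,
        "categorical": cat_rows,
        "prevalence": prevalence,
        "age_cutoff": cutoff,
    }


def prevalence_pct(count: int, total: int) -> float:
    """Prevalence percentage rounded to one decimal (Table-1 convention)."""
    return round(100.0 * count / total, 1)
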