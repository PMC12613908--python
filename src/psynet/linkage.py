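"""Connection values: linking network nodes to high-risk sexual behavior.

The *connection value* of a node is its Spearman correlation with the
composite risk score (condom-use code + partner-count code). The linkage
analysis asks whether structurally central nodes carry larger connection
values: connection value is regressed on expected-influence centrality
across the 37 nodes (one point per node), with a LOWESS curve describing
the trend, separately for the total sample and the two age strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

LOWESS_FRACTION = 2 / 3
LOWESS_ITERATIONS = 3


def connection_values(
    nodes: pd.DataFrame, risk_score, strata: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Per-node Spearman correlation with the risk score, per stratum.

    ``strata`` maps stratum name -> boolean mask over participants; the
    total sample is always included as the first column. A stratum whose
    risk score has zero variance is reported as all-NaN (undefined).
    """
    risk = np.asarray(pd.Series(risk_score).astype(float))
    if len(risk) != len(nodes):
        raise ValueError("nodes and risk score are not aligned")
    strata = dict(strata or {})
    masks = {"total": np.ones(len(risk), bool), **strata}
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, bool)
        if mask.sum() < 10:
            raise ValueError(f"stratum {name!r} has fewer than 10 participants")
        sub_risk = risk[mask]
        if np.std(sub_risk) == 0:
            out[name] = pd.Series(np.nan, index=nodes.columns)
            continue
        vals = {}
        for col in nodes.columns:
            vals[col] = stats.spearmanr(nodes[col].to_numpy()[mask], sub_risk).statistic
        out[name] = pd.Series(vals)
    return pd.DataFrame(out)


class CentralityConnectionRegression(BaseEstimator):
    """OLS of connection value on node centrality, with a LOWESS trend.

    One observation per node. Both the raw slope and the standardized
    coefficient are reported, since the scale convention of the published
    coefficient is ambiguous.

    Attributes (after fit)
    ----------------------
    slope_, intercept_, pvalue_, r2_ : OLS summary (two-sided slope test).
    beta_std_ : standardized slope (equals the Pearson correlation).
    lowess_ : (x, fitted) curve evaluated on the observed x grid.
    """

    def __init__(
        self,
        lowess_fraction: float = LOWESS_FRACTION,
        lowess_iterations: int = LOWESS_ITERATIONS,
    ):
        self.lowess_fraction = lowess_fraction
        self.lowess_iterations = lowess_iterations

    def fit(self, centrality, connection):
        x = np.asarray(pd.Series(centrality).astype(float))
        y = np.asarray(pd.Series(connection).astype(float))
        if len(x) != len(y):
            raise ValueError("centrality and connection values are not aligned")
        if len(x) < 3:
            raise ValueError("need at least 3 node points to fit")
        res = stats.linregress(x, y)
        self.n_nodes_ = len(x)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.pvalue_ = float(res.pvalue)
        self.r2_ = float(res.rvalue**2)
        self.beta_std_ = float(res.rvalue)
        fitted = lowess(
            y,
            x,
            frac=self.lowess_fraction,
            it=self.lowess_iterations,
            return_sorted=True,
        )
        self.lowess_ = pd.DataFrame(fitted, columns=["centrality", "connection_value"])
        return self

    def summary(self) -> dict:
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "p_value": self.pvalue_,
            "r2": self.r2_,
            "beta_standardized": self.beta_std_,
            "n_nodes": self.n_nodes_,
        }


def centrality_vs_connection(
    profile: pd.DataFrame,
    cv: pd.DataFrame,
    stratum: str = "total",
    index: str = "expected_influence",
    **kwargs,
) -> CentralityConnectionRegression:
    """Regress one stratum's connection values on a centrality index."""
    if index not in profile.columns:
        raise ValueError(f"centrality index {index!r} not in profile")
    if stratum not in cv.columns:
        raise ValueError(f"stratum {stratum!r} not in connection-value table")
    x = profile[index].reindex(cv.index)
    if x.isna().any():
        raise ValueError("centrality profile and connection table nodes differ")
    return CentralityConnectionRegression(**kwargs).fit(x, cv[stratum])
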