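"""Permutation-based comparison of two group networks.

Three hypotheses, following the standard network-comparison-test design:

* **structure invariance** — M = max_ij |W1_ij - W2_ij|;
* **global strength** — S = | sum|W1| - sum|W2| | over unordered pairs;
* **edge invariance** — per-edge |delta| with Holm-corrected permutation
  p-values (only edges nonzero in at least one observed group network are
  tested).

Group labels are permuted over the pooled sample preserving group sizes;
both networks are re-estimated per permutation with the identical
configuration (Spearman + EBIC graphical lasso, selection re-run). All
p-values use the plus-one estimator p = (1 + #{stat* >= stat}) / (1 + B),
so they are never zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .ggm import EDGE_THRESHOLD, GaussianGraphicalModel


class NetworkComparisonTest(BaseEstimator):
    """Two-group permutation test of network structure and strength.

    Parameters
    ----------
    n_permutations : int, default 1000
    random_state : int, default 0
    test_edges : bool, default True
        Whether per-edge invariance tests are run.
    edge_alpha : float, default 0.05
        Family-wise level of the Holm-corrected edge tests.
    estimator_params : dict, optional
        Passed to :class:`GaussianGraphicalModel` for every estimation.

    Attributes (after fit)
    ----------------------
    m_, s_ : observed maximum edge difference and global-strength difference.
    p_m_, p_s_ : permutation p-values.
    edge_table_ : per-edge delta (group2 - group1), p_raw, p_holm,
        significant flag, direction relative to group 1 as reference.
    null_m_, null_s_ : permutation null distributions.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        random_state: int = 0,
        test_edges: bool = True,
        edge_alpha: float = 0.05,
        estimator_params: dict | None = None,
    ):
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.test_edges = test_edges
        self.edge_alpha = edge_alpha
        self.estimator_params = estimator_params

    def _estimate(self, arr, labels):
        params = self.estimator_params or {}
        return (
            GaussianGraphicalModel(**params)
            .fit(pd.DataFrame(arr, columns=labels))
            .partial_corr_
        )

    def fit(self, X1, X2):
        """Compare the networks of two participant groups (rows x nodes)."""
        if isinstance(X1, pd.DataFrame) and isinstance(X2, pd.DataFrame):
            if list(X1.columns) != list(X2.columns):
                raise ValueError("the two groups carry different node sets")
            labels = list(X1.columns)
            a1, a2 = X1.to_numpy(float), X2.to_numpy(float)
        else:
            a1, a2 = np.asarray(X1, float), np.asarray(X2, float)
            if a1.shape[1] != a2.shape[1]:
                raise ValueError("the two groups carry different node sets")
            labels = [f"V{i}" for i in range(a1.shape[1])]
        n1, n2 = len(a1), len(a2)
        if min(n1, n2) < 30:
            warnings.warn("a group has fewer than 30 rows; test underpowered",
                          stacklevel=2)
        p = a1.shape[1]
        iu = np.triu_indices(p, 1)

        W1 = self._estimate(a1, labels)
        W2 = self._estimate(a2, labels)
        d_obs = (W2 - W1)[iu]
        m_obs = float(np.abs(d_obs).max())
        s_obs = float(abs(np.abs(W1[iu]).sum() - np.abs(W2[iu]).sum()))
        tested = np.abs(W1[iu]) + np.abs(W2[iu]) > EDGE_THRESHOLD

        pooled = np.vstack([a1, a2])
        B = int(self.n_permutations)
        rng = np.random.default_rng([int(self.random_state) % (2**31), 307])
        null_m = np.empty(B)
        null_s = np.empty(B)
        edge_ge = np.zeros(int(tested.sum()))
        abs_obs_tested = np.abs(d_obs[tested])
        n_redrawn = 0
        for b in range(B):
            while True:
                perm = rng.permutation(n1 + n2)
                g1, g2 = pooled[perm[:n1]], pooled[perm[n1:]]
                if (g1.std(axis=0) > 0).all() and (g2.std(axis=0) > 0).all():
                    break
                n_redrawn += 1
            V1 = self._estimate(g1, labels)
            V2 = self._estimate(g2, labels)
            dd = (V2 - V1)[iu]
            null_m[b] = np.abs(dd).max()
            null_s[b] = abs(np.abs(V1[iu]).sum() - np.abs(V2[iu]).sum())
            if self.test_edges:
                edge_ge += np.abs(dd[tested]) >= abs_obs_tested

        self.feature_names_in_ = labels
        self.n_features_in_ = p
        self.weights_group1_ = W1
        self.weights_group2_ = W2
        self.m_ = m_obs
        self.s_ = s_obs
        self.null_m_ = null_m
        self.null_s_ = null_s
        self.p_m_ = float((1 + (null_m >= m_obs).sum()) / (1 + B))
        self.p_s_ = float((1 + (null_s >= s_obs).sum()) / (1 + B))
        self.n_redrawn_ = n_redrawn

        if self.test_edges:
            p_raw_tested = (1 + edge_ge) / (1 + B)
            rows = []
            k = 0
            for e, (i, j) in enumerate(zip(*iu)):
                if not tested[e]:
                    continue
                rows.append(
                    {
                        "node_i": labels[i],
                        "node_j": labels[j],
                        "weight_group1": W1[i, j],
                        "weight_group2": W2[i, j],
                        "delta": d_obs[e],
                        "p_raw": p_raw_tested[k],
                    }
                )
                k += 1
            table = pd.DataFrame(rows)
            if len(table):
                reject, p_holm, *_ = multipletests(
                    table["p_raw"], alpha=self.edge_alpha, method="holm"
                )
                table["p_holm"] = p_holm
                table["significant"] = reject
            else:
                table["p_holm"] = []
                table["significant"] = []
            table["direction"] = np.where(
                ~table.get("significant", pd.Series(dtype=bool)),
                "none",
                np.where(table["delta"] > 0, "stronger-in-group2", "weaker-in-group2"),
            )
            self.edge_table_ = table
        else:
            self.edge_table_ = None
        return self

    def significant_edges(self) -> pd.DataFrame:
        """Edges differing at the Holm-corrected level."""
        if self.edge_table_ is None:
            raise RuntimeError("per-edge testing was disabled")
        return self.edge_table_[self.edge_table_["significant"]].reset_index(drop=True)


def compare_networks(X1, X2, B: int = 1000, seed: int = 0, **kwargs):
    """Fit a :class:`NetworkComparisonTest` on two groups."""
    return NetworkComparisonTest(
        n_permutations=B, random_state=seed, **kwargs
    ).fit(X1, X2)
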