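"""Bootstrap accuracy of edge weights and case-dropping stability of
centrality indices.

Two distinct resampling schemes:

* **edge bootstrap** — B resamples of participants *with* replacement;
  the full estimation pipeline (Spearman -> EBIC graphical lasso) is
  re-run per resample and percentile 2.5/97.5 intervals are formed per
  edge.
* **case-dropping bootstrap** — for each drop proportion q, B subsamples
  *without* replacement of size ceil(n(1-q)); the correlation between the
  subsample centrality vector and the full-sample one is recorded. The
  correlation-stability (CS) coefficient is the largest q such that at
  least ``confidence`` (95%) of the correlations are >= ``threshold``
  (0.7); CS = 0 if no q on the grid qualifies. Values above 0.5 are
  conventionally read as a stable network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import INDICES, centrality_profile
from .ggm import GaussianGraphicalModel

#: Default drop-proportion grid (8 points, 0.05 .. 0.75).
DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0.05, 0.75, 8), 3))

CS_THRESHOLD = 0.7
CS_CONFIDENCE = 0.95


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"V{i}" for i in range(X.shape[1])]


def _fit(arr: np.ndarray, labels, params: dict) -> GaussianGraphicalModel:
    return GaussianGraphicalModel(**params).fit(pd.DataFrame(arr, columns=labels))


@dataclass
class EdgeBootstrapResult:
    table: pd.DataFrame  # node_i, node_j, estimate, boot_mean, ci_low, ci_high
    n_boot: int
    n_redrawn: int
    seed: int


def edge_bootstrap(
    X,
    B: int = 1000,
    seed: int = 0,
    estimator_params: dict | None = None,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap CIs for every edge weight.

    ``B = 0`` returns point estimates only. Resamples that produce a
    zero-variance node are redrawn (counted in ``n_redrawn``). B >= 100
    is required for interval output.
    """
    if 0 < B < 100:
        raise ValueError("need B >= 100 for percentile intervals (or B = 0)")
    params = estimator_params or {}
    arr, labels = _as_array(X)
    n, p = arr.shape
    full = _fit(arr, labels, params)
    iu = np.triu_indices(p, 1)
    est = full.partial_corr_[iu]

    rows = {
        "node_i": [labels[i] for i in iu[0]],
        "node_j": [labels[j] for j in iu[1]],
        "estimate": est,
    }
    n_redrawn = 0
    if B > 0:
        rng = np.random.default_rng([int(seed) % (2**31), 101])
        boots = np.empty((B, est.size))
        for b in range(B):
            while True:
                take = rng.integers(0, n, size=n)
                sub = arr[take]
                if (sub.std(axis=0) > 0).all():
                    break
                n_redrawn += 1
            boots[b] = _fit(sub, labels, params).partial_corr_[iu]
        rows["boot_mean"] = boots.mean(axis=0)
        rows["ci_low"] = np.percentile(boots, 2.5, axis=0)
        rows["ci_high"] = np.percentile(boots, 97.5, axis=0)
    return EdgeBootstrapResult(pd.DataFrame(rows), B, n_redrawn, seed)


@dataclass
class CaseDroppingResult:
    curve: pd.DataFrame  # drop, replicate, index, correlation
    cs: dict[str, float]
    full_profile: pd.DataFrame
    threshold: float
    confidence: float
    n_boot: int
    seed: int
    n_degenerate: int = 0

    def cs_from_curve(self) -> dict[str, float]:
        """Recompute CS from the stored curve (consistency check)."""
        return {
            ix: compute_cs(g, self.threshold, self.confidence)
            for ix, g in self.curve.groupby("index")
        }


def compute_cs(curve: pd.DataFrame, threshold: float, confidence: float) -> float:
    """Largest drop proportion with >= confidence share of correlations
    >= threshold; 0.0 if none qualifies."""
    ok = []
    for q, g in curve.groupby("drop"):
        share = float((g["correlation"] >= threshold).mean())
        if share >= confidence:
            ok.append(float(q))
    return max(ok) if ok else 0.0


def case_dropping_cs(
    X,
    indices=("strength", "expected_influence"),
    B: int = 1000,
    drop_grid=DEFAULT_DROP_GRID,
    threshold: float = CS_THRESHOLD,
    confidence: float = CS_CONFIDENCE,
    seed: int = 0,
    estimator_params: dict | None = None,
) -> CaseDroppingResult:
    """Case-dropping subset bootstrap of centrality stability.

    Penalty selection (EBIC over the full lambda path) is re-run inside
    every subsample, so selection uncertainty is propagated. A subsample
    correlation is set to 0 (and counted as degenerate) when either
    centrality vector has zero variance, e.g. on an empty network.
    """
    for ix in indices:
        if ix not in INDICES:
            raise ValueError(f"unknown centrality index {ix!r}; choose from {INDICES}")
    grid = sorted(float(q) for q in drop_grid)
    if not grid or grid[0] <= 0 or grid[-1] > 0.9:
        raise ValueError("drop grid must lie in (0, 0.9]")
    params = estimator_params or {}
    arr, labels = _as_array(X)
    n, p = arr.shape
    if n * (1 - grid[-1]) < p + 1:
        import warnings

        warnings.warn("largest drop leaves fewer cases than nodes", stacklevel=2)
    full = _fit(arr, labels, params)
    full_prof = centrality_profile(full.weights_, indices)

    rng = np.random.default_rng([int(seed) % (2**31), 211])
    recs = []
    n_degenerate = 0
    for q in grid:
        m = int(np.ceil(n * (1 - q)))
        for b in range(B):
            take = rng.choice(n, size=m, replace=False)
            sub = arr[take]
            if not (sub.std(axis=0) > 0).all():
                n_degenerate += 1
                for ix in indices:
                    recs.append((q, b, ix, 0.0))
                continue
            prof = centrality_profile(
                _fit(sub, labels, params).weights_, indices
            )
            for ix in indices:
                a_v = full_prof[ix].to_numpy()
                b_v = prof[ix].to_numpy()
                if a_v.std() == 0 or b_v.std() == 0:
                    n_degenerate += 1
                    r = 0.0
                else:
                    r = float(np.corrcoef(a_v, b_v)[0, 1])
                recs.append((q, b, ix, r))
    curve = pd.DataFrame(recs, columns=["drop", "replicate", "index", "correlation"])
    cs = {
        ix: compute_cs(curve[curve["index"] == ix], threshold, confidence)
        for ix in indices
    }
    return CaseDroppingResult(
        curve, cs, full_prof, threshold, confidence, B, seed, n_degenerate
    )
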