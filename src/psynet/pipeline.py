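"""Pipeline orchestration: run the analysis stages and write artifacts.

A run is driven by a configuration mapping (typically loaded from YAML):

.. code-block:: yaml

    output_dir: results/run1
    seed: 1
    stages: [simulate, score, estimate, centrality, stability, compare, link]
    input: null              # or a cohort CSV path
    synthetic: {n: 405}      # GeneratorConfig overrides
    scoring: {item_polarity: aligned, soi_score: mean}
    estimator: {gamma: 0.5, n_lambdas: 100}
    stability: {n_boot: 1000}
    nct: {n_permutations: 1000}

Artifacts are plain text (CSV/TSV/JSON) plus a run manifest recording the
seed, parameters and package versions; identical configuration and seed
reproduce identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import centrality_profile, profile_long, standardize_profile
from .cohort import Cohort, ConfigurationError, apply_listwise_deletion, read_cohort
from .ggm import GaussianGraphicalModel
from .linkage import centrality_vs_connection, connection_values
from .nct import NetworkComparisonTest
from .scoring import ScaleScorer, composite_risk, descriptives, split_by_age
from .stability import case_dropping_cs, edge_bootstrap
from .synthetic import GeneratorConfig, sample_cohort, build_ground_truth

log = logging.getLogger("psynet")

ALL_STAGES = ("simulate", "score", "estimate", "centrality", "stability",
              "compare", "link")

FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_csv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns {artifact name: path}."""
    if "output_dir" not in config:
        raise ConfigurationError("configuration lacks 'output_dir'")
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ALL_STAGES))
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in config.items() if k != "output_dir"},
        "notes": {},
    }

    def save(name: str, path: Path):
        artifacts[name] = str(path)

    # --- input ---------------------------------------------------------
    stage = "simulate" if "simulate" in stages else "input"
    try:
        if "simulate" in stages:
            gen = GeneratorConfig(seed=seed, **(config.get("synthetic") or {}))
            truth = build_ground_truth(gen)
            cohort_df, _latent = sample_cohort(truth, gen)
            cohort = Cohort(cohort_df, cohort_df.isna())
            p = out / "cohort.csv"
            cohort_df.to_csv(p, index=False)
            save("cohort", p)
            p = out / "ground_truth.json"
            p.write_text(json.dumps({
                "labels": truth.labels,
                "theta_template": truth.theta_template.to_numpy().round(6).tolist(),
                "shrink_factor": truth.shrink_factor,
                "bridges": [list(b) for b in truth.bridges],
                "seed": seed,
            }, indent=1))
            save("ground_truth", p)
            manifest["generator"] = {
                k: v for k, v in asdict(gen).items()
                if not isinstance(v, dict)
            }
        else:
            if not config.get("input"):
                raise ConfigurationError("no input file and no synthetic block")
            cohort = read_cohort(config["input"])
            cohort, report = apply_listwise_deletion(cohort)
            manifest["notes"]["listwise_deletion"] = {
                "removed": report.n_removed,
                "per_variable": report.per_variable_missing,
            }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    df = cohort.data if isinstance(cohort, Cohort) else cohort

    # --- score ---------------------------------------------------------
    scorer = ScaleScorer(**(config.get("scoring") or {})).fit(df)
    nodes = scorer.transform(df)
    risk = composite_risk(df)
    young, old = split_by_age(df["age"])
    strata = {"age_lt_33": young, "age_ge_33": old}
    if "score" in stages:
        try:
            p = out / "node_matrix.csv"
            _write_csv(nodes, p)
            save("node_matrix", p)
            p = out / "scores.csv"
            _write_csv(pd.concat([scorer.scale_totals(df), risk], axis=1), p)
            save("scores", p)
            p = out / "descriptives.json"
            p.write_text(json.dumps(descriptives(df), indent=1, default=float))
            save("descriptives", p)
        except Exception as e:  # noqa: BLE001
            raise StageError("score", e) from e

    est_params = config.get("estimator") or {}
    model = None

    def fitted():
        nonlocal model
        if model is None:
            model = GaussianGraphicalModel(**est_params).fit(nodes)
        return model

    # --- estimate ------------------------------------------------------
    if "estimate" in stages:
        try:
            m = fitted()
            p = out / "edge_list.tsv"
            m.edge_list().to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
            save("edge_list", p)
            p = out / "network.csv"
            _write_csv(m.weights_, p, index=True)
            save("network", p)
            per_node, per_construct = m.predictability(nodes)
            p = out / "predictability.csv"
            _write_csv(
                pd.concat(
                    [per_node.rename("R2"),
                     per_node.index.to_series().map(
                         scorer.node_construct_).rename("construct")],
                    axis=1,
                ),
                p,
                index=True,
            )
            save("predictability", p)
            manifest["notes"]["estimate"] = {
                "alpha": m.alpha_, "gamma": m.gamma, "n_edges": int(m.n_edges_),
                "predictability_by_construct": per_construct.round(4).to_dict(),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("estimate", e) from e

    # --- centrality ----------------------------------------------------
    profile = None
    if "centrality" in stages or "link" in stages:
        profile = centrality_profile(fitted().weights_)
    if "centrality" in stages:
        try:
            zs = standardize_profile(profile)
            p = out / "centrality.csv"
            _write_csv(
                pd.concat([profile, zs.add_prefix("z_")], axis=1), p, index=True
            )
            save("centrality", p)
            p = out / "centrality_long.csv"
            _write_csv(profile_long(profile), p)
            save("centrality_long", p)
        except Exception as e:  # noqa: BLE001
            raise StageError("centrality", e) from e

    # --- stability -----------------------------------------------------
    if "stability" in stages:
        try:
            stab_cfg = dict(config.get("stability") or {})
            n_boot = int(stab_cfg.pop("n_boot", 1000))
            eb = edge_bootstrap(nodes, B=n_boot, seed=seed,
                                estimator_params=est_params)
            p = out / "edge_bootstrap.csv"
            _write_csv(eb.table, p)
            save("edge_bootstrap", p)
            cd = case_dropping_cs(nodes, B=stab_cfg.pop("n_case_boot", 250),
                                  seed=seed, estimator_params=est_params,
                                  **stab_cfg)
            p = out / "stability_curve.csv"
            _write_csv(cd.curve, p)
            save("stability_curve", p)
            p = out / "stability.json"
            p.write_text(json.dumps({
                "cs": cd.cs, "threshold": cd.threshold,
                "confidence": cd.confidence, "n_boot": cd.n_boot,
                "seed": seed,
            }, indent=1))
            save("stability", p)
        except Exception as e:  # noqa: BLE001
            raise StageError("stability", e) from e

    # --- compare -------------------------------------------------------
    if "compare" in stages:
        try:
            nct_cfg = config.get("nct") or {}
            nct = NetworkComparisonTest(
                random_state=seed, estimator_params=est_params, **nct_cfg
            ).fit(nodes[young], nodes[old])
            p = out / "nct.json"
            p.write_text(json.dumps({
                "comparison": "age_lt_33 (group1, reference) vs age_ge_33 (group2)",
                "M": nct.m_, "p_M": nct.p_m_,
                "S": nct.s_, "p_S": nct.p_s_,
                "n_permutations": nct.n_permutations,
                "seed": seed,
            }, indent=1))
            save("nct", p)
            if nct.edge_table_ is not None:
                p = out / "nct_edges.csv"
                _write_csv(nct.edge_table_, p)
                save("nct_edges", p)
        except Exception as e:  # noqa: BLE001
            raise StageError("compare", e) from e

    # --- link ----------------------------------------------------------
    if "link" in stages:
        try:
            cv = connection_values(nodes, risk["risk_score"], strata)
            p = out / "connection_values.csv"
            _write_csv(cv, p, index=True)
            save("connection_values", p)
            summaries = {}
            curves = []
            for stratum in cv.columns:
                if stratum == "total":
                    prof = profile
                else:
                    mask = strata[stratum]
                    prof = centrality_profile(
                        GaussianGraphicalModel(**est_params)
                        .fit(nodes[mask]).weights_
                    )
                reg = centrality_vs_connection(prof, cv, stratum)
                summaries[stratum] = reg.summary()
                c = reg.lowess_.copy()
                c["stratum"] = stratum
                curves.append(c)
            p = out / "linkage_regression.json"
            p.write_text(json.dumps(summaries, indent=1))
            save("linkage_regression", p)
            p = out / "lowess_curves.csv"
            _write_csv(pd.concat(curves, ignore_index=True), p)
            save("lowess_curves", p)
        except Exception as e:  # noqa: BLE001
            raise StageError("link", e) from e

    manifest["artifacts"] = artifacts
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, default=str))
    artifacts["manifest"] = str(mp)
    return artifacts
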