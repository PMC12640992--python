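"""End-to-end orchestration: simulate/load -> cluster -> classify -> select ->
prognosis, from one config and one master seed.

The master seed fans out to per-stage seeds through a spawned SeedSequence in
fixed stage order (simulate, cluster, classifier, select, prognosis), so any
stage can be re-run independently and reproduces the same stream. Every run
writes a manifest recording the config snapshot, the derived seeds, input
file digests and the files each stage produced.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as pio
from .classifier import ClassifierConfig, CrossFusionClassifier
from .cluster import ConsensusClusterer
from .select import HubGeneSelector
from .survival import PrognosticModel
from .synth import SimulationConfig, simulate_expression, simulate_survival

STAGES = ("simulate", "cluster", "classifier", "select", "prognosis")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seeds(master_seed: int) -> dict:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31 - 1))
        for stage, child in zip(STAGES, children)
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(out, stage, message):
    line = f"[{stage}] {message}"
    print(line, file=sys.stderr)
    out.append(line)


_KNOWN_KEYS = {
    "": {"seed", "data", "simulate", "cluster", "classifier", "select", "prognosis"},
    "data": {"expr", "orientation", "surv", "genes"},
    "simulate": {
        "n_samples", "n_genes", "k_subtypes", "n_informative", "effect_size",
        "mixing", "censor_rate", "baseline_rate", "log_normal",
        "prognostic_genes", "surv_coefs",
    },
    "cluster": {"k", "k_candidates", "zscore", "n_top_genes"},
    "classifier": set(ClassifierConfig.__dataclass_fields__) - {"seed"},
    "select": {"n_folds", "n_trees", "top_n", "lambda_rule"},
    "prognosis": {"alpha", "top_m", "n_trees", "min_prop"},
}


def _validate_config(config: dict) -> None:
    bad = []
    for key in config:
        if key not in _KNOWN_KEYS[""]:
            bad.append(key)
    for block, allowed in _KNOWN_KEYS.items():
        if block and isinstance(config.get(block), dict):
            bad.extend(f"{block}.{k}" for k in config[block] if k not in allowed)
    if bad:
        raise ConfigError(f"unknown config key(s): {sorted(bad)}")
    if "data" not in config and "simulate" not in config:
        raise ConfigError("config needs a [data] or [simulate] block")


def run_all(config, out_dir, master_seed: Optional[int] = None) -> dict:
    """Execute the pipeline described by ``config`` (path to TOML or a dict).

    Returns the run manifest (also written to ``out_dir/manifest.json``).
    Stage failures raise :class:`StageError`; outputs of completed stages are
    retained.
    """
    if not isinstance(config, dict):
        config = tomllib.loads(Path(config).read_text())
    _validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if master_seed is None else int(master_seed)
    seeds = stage_seeds(seed)
    log: list = []
    manifest = {
        "config": config,
        "master_seed": seed,
        "stage_seeds": seeds,
        "input_digests": {},
        "outputs": {},
    }

    def record(stage, name, path):
        manifest["outputs"].setdefault(stage, {})[name] = str(path.name)

    # -- stage: data / simulate ------------------------------------------------
    surv = None
    truth = None
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            prog_genes = sim.pop("prognostic_genes", [])
            surv_coefs = sim.pop("surv_coefs", [])
            sc = SimulationConfig(seed=seeds["simulate"], **sim)
            X, truth, sim_manifest = simulate_expression(sc)
            manifest["simulation"] = sim_manifest
            pio.save_expression(X, out_dir / "expr.tsv")
            record("simulate", "expression", out_dir / "expr.tsv")
            pio.save_labels(X.sample_ids, truth, out_dir / "truth_labels.tsv")
            record("simulate", "truth_labels", out_dir / "truth_labels.tsv")
            if prog_genes:
                surv = simulate_survival(
                    X, prog_genes, surv_coefs,
                    baseline_rate=sc.baseline_rate, censor_rate=sc.censor_rate,
                    seed=seeds["simulate"] + 1,
                )
                pio.save_survival(surv, out_dir / "surv.tsv")
                record("simulate", "survival", out_dir / "surv.tsv")
            _log(log, "simulate", f"generated {X.n_genes}x{X.n_samples} cohort")
        else:
            data = config["data"]
            expr_path = Path(data["expr"])
            X = pio.load_expression(expr_path, data.get("orientation", "genes_by_samples"))
            manifest["input_digests"][str(expr_path)] = _digest(expr_path)
            if "surv" in data:
                surv_path = Path(data["surv"])
                surv = pio.load_survival(surv_path)
                manifest["input_digests"][str(surv_path)] = _digest(surv_path)
            _log(log, "data", f"loaded {X.n_genes}x{X.n_samples} cohort")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate" if "simulate" in config else "data", exc) from exc

    # -- stage: cluster ----------------------------------------------------------
    try:
        cl = dict(config.get("cluster", {}))
        gene_set = None
        if "data" in config and "genes" in config["data"]:
            gmt = pio.load_gmt(config["data"]["genes"])
            gene_set = pio.build_composite_geneset(gmt).all_genes()
        clusterer = ConsensusClusterer(
            k=cl.get("k"),
            k_candidates=cl.get("k_candidates", (2, 3, 4, 5, 6)),
            zscore=cl.get("zscore", True),
            gene_set=gene_set,
            n_top_genes=cl.get("n_top_genes", 2000),
            seed=seeds["cluster"],
        )
        clusters = clusterer.fit(X)
        clusters.to_frame().to_csv(out_dir / "labels.tsv", sep="\t", index=False)
        record("cluster", "labels", out_dir / "labels.tsv")
        if clusters.silhouette_report is not None:
            clusters.silhouette_report.to_frame().to_csv(
                out_dir / "silhouette.tsv", sep="\t", index=False
            )
            record("cluster", "silhouette", out_dir / "silhouette.tsv")
        _log(log, "cluster", f"k={clusters.k}, mean silhouette {clusters.mean_silhouette:.3f}")
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    labels = clusters.consensus

    # -- stage: classifier ---------------------------------------------------------
    if "classifier" in config:
        try:
            cfg = ClassifierConfig(seed=seeds["classifier"], **config["classifier"])
            fitted = CrossFusionClassifier(X, labels, config=cfg).fit()
            fitted.save(out_dir / "model")
            record("classifier", "model_dir", out_dir / "model")
            probs = fitted.predict_proba(X)
            import pandas as pd

            pd.DataFrame(
                probs, columns=[f"p{c}" for c in range(probs.shape[1])]
            ).assign(sample_id=X.sample_ids).to_csv(
                out_dir / "probs.tsv", sep="\t", index=False
            )
            record("classifier", "probabilities", out_dir / "probs.tsv")
            _log(log, "classifier", f"trained ({len(fitted.history)} epochs)")
        except Exception as exc:
            raise StageError("classifier", exc) from exc
    else:
        _log(log, "classifier", "no [classifier] block; stage skipped")

    # -- stage: select ----------------------------------------------------------
    if "select" in config:
        try:
            sel_cfg = dict(config["select"])
            selector = HubGeneSelector(
                X, labels,
                n_folds=sel_cfg.get("n_folds", 5),
                n_trees=sel_cfg.get("n_trees", 1000),
                top_n=sel_cfg.get("top_n", 30),
                lambda_rule=sel_cfg.get("lambda_rule", "1se"),
                seed=seeds["select"],
            )
            selection = selector.fit()
            selection.to_frame(X.gene_ids).to_csv(
                out_dir / "selection.tsv", sep="\t", index=False
            )
            record("select", "selection", out_dir / "selection.tsv")
            _log(log, "select", f"{len(selection.intersection)} hub genes")
        except Exception as exc:
            raise StageError("select", exc) from exc
    else:
        _log(log, "select", "no [select] block; stage skipped")

    # -- stage: prognosis ---------------------------------------------------------
    if "prognosis" in config and surv is not None:
        try:
            pr = dict(config.get("prognosis", {}))
            prog = PrognosticModel(
                X, surv,
                alpha=pr.get("alpha", 0.05),
                top_m=pr.get("top_m", 9),
                n_trees=pr.get("n_trees", 1000),
                min_prop=pr.get("min_prop", 0.1),
                seed=seeds["prognosis"],
            ).fit()
            prog.screen.to_csv(out_dir / "cox_screen.tsv", sep="\t", index=False)
            record("prognosis", "screen", out_dir / "cox_screen.tsv")
            imp = prog.forest.oob_trajectory
            imp.to_csv(out_dir / "oob_error.tsv", sep="\t", index=False)
            record("prognosis", "oob_error", out_dir / "oob_error.tsv")
            (out_dir / "risk_model.json").write_text(
                json.dumps(prog.risk_model.to_dict(), indent=1)
            )
            record("prognosis", "model", out_dir / "risk_model.json")
            prog.stratification.to_frame(prog.model.surv.sample_ids).to_csv(
                out_dir / "scores.tsv", sep="\t", index=False
            )
            record("prognosis", "scores", out_dir / "scores.tsv")
            for name, curve in prog.stratification.km_curves.items():
                curve.to_csv(out_dir / f"km_{name}.tsv", sep="\t", index=False)
                record("prognosis", f"km_{name}", out_dir / f"km_{name}.tsv")
            _log(
                log, "prognosis",
                f"C-index {prog.cindex:.3f}, cutoff {prog.risk_model.cutoff:.4g}",
            )
        except Exception as exc:
            raise StageError("prognosis", exc) from exc
    elif "prognosis" in config:
        _log(log, "prognosis", "no survival data available; stage skipped")
    else:
        _log(log, "prognosis", "no [prognosis] block; stage skipped")

    manifest["log"] = log
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
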