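"""End-to-end pipeline: simulate -> preprocess -> train -> networks -> stars.

Every stage writes its artifacts as headered TSV (probabilities with six
decimals) so two runs with the same config and seed produce byte-identical
outputs, and a JSON run log records the seed, hyper-parameters and
per-epoch accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gctio, networks, preprocessing, similarity, softmax, stars, synthetic
from .config import PipelineConfig
from .gctio import ATC_LETTERS, ExpressionTable

__all__ = ["PipelineStageError", "PipelineResult", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "train", "networks", "stars")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory bundle of everything the run produced."""

    expression: ExpressionTable | None = None
    labels: dict[str, set[str]] = field(default_factory=dict)
    truth: dict | None = None
    credible: ExpressionTable | None = None
    probability_matrix: pd.DataFrame | None = None
    dtn_t: pd.DataFrame | None = None
    er_combined: networks.ERMatrix | None = None
    er_stability: pd.DataFrame | None = None
    top_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dtn_se: pd.DataFrame | None = None
    dtn_st: pd.DataFrame | None = None
    rho_se: pd.Series | None = None
    rho_st: pd.Series | None = None
    star_calls: list[stars.StarCall] = field(default_factory=list)
    sd1: set[str] = field(default_factory=set)
    sd2: set[str] = field(default_factory=set)
    sd3: set[str] = field(default_factory=set)
    credible_stars: dict[str, set[str]] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)


def _write_rho(rho: pd.Series, path: Path) -> None:
    rho.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    synthetic_spec: synthetic.SyntheticSpec | None = None,
    run_cv: bool = True,
) -> PipelineResult:
    """Run the requested prefix of the pipeline, writing artifacts to
    ``out_dir``. Unknown stage names raise; any stage failure is re-raised
    as :class:`PipelineStageError` naming the stage."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    classes = list(ATC_LETTERS)
    log: dict = {"seed": config.seed, "hyper_parameters": config.to_dict(), "stages": []}

    # --- simulate (or load provided inputs) -------------------------------
    stage = "simulate"
    try:
        if config.expression_path:
            res.expression = gctio.read_gct(config.expression_path)
            res.labels = gctio.read_label_table(config.label_path)
            side_effects = (
                gctio.read_feature_sets(config.side_effect_path)
                if config.side_effect_path
                else None
            )
            fingerprints = (
                gctio.read_feature_sets(config.fingerprint_path)
                if config.fingerprint_path
                else None
            )
            res.truth = None
        else:
            spec = synthetic_spec or synthetic.SyntheticSpec(
                **{"seed": config.seed, **(config.synthetic or {})}
            )
            res.expression, res.labels, res.truth = synthetic.generate_cohort(spec)
            planted = res.truth["planted"]
            side_effects = synthetic.generate_side_effect_sets(res.labels, spec, planted)
            fingerprints = synthetic.generate_fingerprints(res.labels, spec, planted)
            if "simulate" in stages:
                gctio.write_gct(res.expression, out / "expression.gct")
                gctio.write_label_table(res.labels, out / "labels.tsv")
                gctio.write_feature_sets(side_effects, out / "side_effects.tsv")
                gctio.write_feature_sets(fingerprints, out / "fingerprints.tsv")
                with open(out / "truth.json", "w") as fh:
                    json.dump(res.truth, fh, indent=2, sort_keys=True)
        log["stages"].append(stage)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if stages[-1] == "simulate":
        res.run_log = log
        _dump_log(log, out)
        return res

    # --- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        res.credible = preprocessing.credible_table(
            res.expression, k=config.kmeans_k, seed=config.seed
        )
        gctio.write_gct(res.credible, out / "credible.gct")
        log["stages"].append(stage)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if stages[-1] == "preprocess":
        res.run_log = log
        _dump_log(log, out)
        return res

    # --- train ------------------------------------------------------------
    stage = "train"
    try:
        cred = res.credible
        sample_drugs = [cred.drug_of_sample[s] for s in cred.sample_ids]
        lb = softmax.make_label_matrix(sample_drugs, res.labels, classes)
        hyper = dict(
            learning_rate=config.learning_rate,
            lam=config.lam,
            batch_size=config.batch_size,
            iterations=config.iterations,
            averaging_window=config.averaging_window,
            training_threshold=config.training_threshold,
            validation_threshold=config.validation_threshold,
        )
        if run_cv:
            log["cross_validation"] = _cross_validate(cred, res.labels, classes, config)
        theta, history = softmax.train(cred.values, lb, seed=config.seed, **hyper)
        res.probability_matrix = softmax.averaged_probability_matrix(
            history.window_probabilities, sample_drugs, classes
        )
        gctio.write_matrix(res.probability_matrix, out / "probability_matrix.tsv")
        pred = np.argmax(softmax.softmax_probabilities(theta, cred.values), axis=1)
        conf = softmax.confusion_matrix(lb, pred)
        gctio.write_matrix(
            pd.DataFrame(conf, index=classes, columns=classes), out / "confusion_matrix.tsv", 0
        )
        log["training"] = {
            "loss": [round(v, 10) for v in history.loss],
            "train_accuracy": [round(v, 10) for v in history.train_accuracy],
        }
        log["stages"].append(stage)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if stages[-1] == "train":
        res.run_log = log
        _dump_log(log, out)
        return res

    # --- networks ---------------------------------------------------------
    stage = "networks"
    try:
        res.dtn_t = networks.build_dtn_t(res.probability_matrix, res.labels)
        gctio.write_matrix(res.dtn_t, out / "dtn_t.tsv")
        edges_long = res.dtn_t.stack()
        edges_long = edges_long[edges_long > 0].rename("probability")
        edges_long.index.names = ["drug", "atc"]
        edges_long.to_frame().to_csv(out / "edges.tsv", sep="\t", float_format="%.6f")
        res.er_stability = networks.er_threshold_stability(
            res.dtn_t, res.labels, config.er_threshold_grid
        )
        gctio.write_matrix(res.er_stability, out / "er_stability.tsv")
        res.er_combined = networks.combined_er(res.dtn_t, res.labels, config.combine_thresholds)
        gctio.write_matrix(res.er_combined.er, out / "er_combined.tsv")
        res.top_pairs = networks.top_er_pairs(res.er_combined.er, 5)
        pd.DataFrame(res.top_pairs, columns=["X", "Y", "ER"]).to_csv(
            out / "er_top_pairs.tsv", sep="\t", index=False, float_format="%.6f"
        )
        if side_effects is not None:
            sim_se = similarity.similarity_network(side_effects, "jaccard")
            gctio.write_matrix(sim_se, out / "similarity_se.tsv")
            communities = similarity.atc_communities(res.labels, classes)
            res.dtn_se = similarity.node_to_community(sim_se, communities)
            gctio.write_matrix(res.dtn_se, out / "dtn_se.tsv")
            res.rho_se = similarity.cross_network_spearman(res.dtn_t, res.dtn_se)
            _write_rho(res.rho_se, out / "rho_se.tsv")
        if fingerprints is not None:
            sim_st = similarity.similarity_network(fingerprints, "tanimoto")
            gctio.write_matrix(sim_st, out / "similarity_st.tsv")
            communities = similarity.atc_communities(res.labels, classes)
            res.dtn_st = similarity.node_to_community(sim_st, communities)
            gctio.write_matrix(res.dtn_st, out / "dtn_st.tsv")
            res.rho_st = similarity.cross_network_spearman(res.dtn_t, res.dtn_st)
            _write_rho(res.rho_st, out / "rho_st.tsv")
        log["stages"].append(stage)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if stages[-1] == "networks":
        res.run_log = log
        _dump_log(log, out)
        return res

    # --- stars ------------------------------------------------------------
    stage = "stars"
    try:
        res.star_calls = stars.find_stars(res.dtn_t, config.star_threshold)
        res.sd1 = stars.sd1(res.star_calls)
        if res.rho_se is not None:
            res.sd2 = stars.sd_by_correlation(res.star_calls, res.rho_se, config.rho_threshold)
        if res.rho_st is not None:
            res.sd3 = stars.sd_by_correlation(res.star_calls, res.rho_st, config.rho_threshold)
        res.credible_stars = stars.credible_star_set(res.sd1, res.sd2, res.sd3)
        table = stars.star_table(res.star_calls, res.credible_stars)
        table.to_csv(out / "stars.tsv", sep="\t", index=False, float_format="%.6f")
        cred_rows = [
            {"drug": d, "supports": ";".join(sorted(res.credible_stars[d]))}
            for d in sorted(res.credible_stars)
        ]
        pd.DataFrame(cred_rows, columns=["drug", "supports"]).to_csv(
            out / "credible_stars.tsv", sep="\t", index=False
        )
        log["star_counts"] = {
            "stars": len({c.drug_id for c in res.star_calls}),
            "SD1": len(res.sd1),
            "SD2": len(res.sd2),
            "SD3": len(res.sd3),
            "credible": len(res.credible_stars),
        }
        log["stages"].append(stage)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    res.run_log = log
    _dump_log(log, out)
    return res


def _cross_validate(
    cred: ExpressionTable,
    labels: dict[str, set[str]],
    classes: list[str],
    config: PipelineConfig,
) -> list[dict]:
    """Drug-level k-fold cross-validation; returns per-fold accuracy curves."""
    splits = softmax.k_fold_split(cred.drugs, config.k_folds, seed=config.seed)
    folds = []
    for fold_i, (train_drugs, val_drugs) in enumerate(splits):
        tr = set(train_drugs)
        tr_idx = [i for i, s in enumerate(cred.sample_ids) if cred.drug_of_sample[s] in tr]
        va_idx = [i for i in range(len(cred.sample_ids)) if i not in set(tr_idx)]
        sd = [cred.drug_of_sample[s] for s in cred.sample_ids]
        lb_tr = softmax.make_label_matrix([sd[i] for i in tr_idx], labels, classes)
        lb_va = softmax.make_label_matrix([sd[i] for i in va_idx], labels, classes)
        _, hist = softmax.train(
            cred.values[tr_idx],
            lb_tr,
            learning_rate=config.learning_rate,
            lam=config.lam,
            batch_size=config.batch_size,
            iterations=config.iterations,
            averaging_window=1,
            training_threshold=config.training_threshold,
            validation_threshold=config.validation_threshold,
            seed=config.seed + fold_i,
            val=(cred.values[va_idx], lb_va),
        )
        folds.append(
            {
                "fold": fold_i,
                "n_validation_drugs": len(val_drugs),
                "train_accuracy": [round(v, 10) for v in hist.train_accuracy],
                "validation_accuracy": [round(v, 10) for v in hist.val_accuracy],
            }
        )
    return folds


def _dump_log(log: dict, out: Path) -> None:
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
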