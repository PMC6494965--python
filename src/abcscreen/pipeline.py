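"""End-to-end orchestration: simulate -> train -> validate.

Each stage reads and writes the standard on-disk formats (fingerprint CSV,
label CSV, long-format plate-read CSV, TSV reports, JSON manifests) so the
stages can be run independently or chained. Every run writes a manifest
carrying the master seed, a config hash, input hashes and any warnings, and
two runs with identical manifests produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_seed, sha256_of
from .efficacy import compute_efficacy_table, read_plate_reads, write_efficacy_tsv
from .enrichment import enrich_all, write_enrichment_tsv
from .fingerprints import (
    FingerprintMatrix,
    build_matrix,
    compute_maccs_many,
    filter_constant_keys,
    nearest_training_neighbor,
    read_structures,
    write_similarity_edges,
)
from .model import (
    CVConfig,
    FittedModel,
    LearnerSpec,
    PredictionSet,
    confusion_and_metrics,
    default_learners,
    load_model,
    marginalized_cv,
    performance_table,
    permutation_importance,
    rank_auc,
    reduced_learners,
    select_best_params,
    spearman_permutation_test,
    train_final_model,
)
from .simulate import (
    DrugGrowthSpec,
    FingerprintSimConfig,
    GrowthSimConfig,
    generate_fingerprint_dataset,
    labels_from_csv,
    labels_to_csv,
    simulate_growth_curves,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_train", "run_validate"]


@dataclass
class PipelineConfig:
    """Single configuration object for all stages, loadable from YAML."""

    out_dir: str = "abcscreen_out"
    seed: int = 0
    # simulate
    n_drugs: int = 400
    n_planted: int = 6
    planted_effect: float = 1.5
    n_validation_drugs: int = 24
    # enrichment
    alpha: float = 0.05
    fdr_m_total: int | None = None
    # efficacy
    epsilon: float = 0.1
    # modeling
    n_folds: int = 10
    n_repeats: int = 5
    learner_scale: str = "reduced"  # "reduced" or "default"
    threshold_confusion: float = 0.5
    threshold_call: float = 0.15
    # inputs (set when not simulating)
    structures: str | None = None
    labels: str | None = None
    plate_reads: str | None = None
    model_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cv_config(self) -> CVConfig:
        return CVConfig(
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            seed=derive_seed(self.seed, 31),
            threshold_confusion=self.threshold_confusion,
            threshold_call=self.threshold_call,
        )

    def learners(self) -> dict[str, LearnerSpec]:
        if self.learner_scale == "default":
            return default_learners()
        return reduced_learners()


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, inputs: dict[str, str],
                    captured: list[str]) -> Path:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": sha256_of(asdict(config)),
        "input_hashes": inputs,
        "warnings": captured,
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _default_growth_config(labels: pd.Series, seed: int, n_drugs: int | None = None) -> GrowthSimConfig:
    """Growth design matching the labels: sensitive drugs are substrates."""
    rng = np.random.default_rng(derive_seed(seed, 37))
    drugs = []
    ids = list(labels.index)[: n_drugs if n_drugs else len(labels)]
    for drug_id in ids:
        if int(labels.loc[drug_id]) == 1:
            ic_par = float(rng.uniform(2.0, 6.0))
            ic_abc = float(rng.uniform(0.15, 0.5))
            drugs.append(DrugGrowthSpec(drug_id, True, ic_par, ic_abc))
        else:
            ic = float(rng.uniform(0.8, 3.0))
            drugs.append(DrugGrowthSpec(drug_id, False, ic, ic))
    return GrowthSimConfig(drugs=tuple(drugs), seed=derive_seed(seed, 38))


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write a synthetic training dataset: fingerprints, labels, plate reads, truth.

    Planted keys are spread over the key range with alternating effect signs;
    the label model targets the screen's ~1/3 sensitive fraction.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    planted = tuple(
        (int(k), config.planted_effect * (1 if i % 2 == 0 else -1))
        for i, k in enumerate(np.linspace(5, 160, config.n_planted).round().astype(int))
    )
    sim = FingerprintSimConfig(
        n_drugs=config.n_drugs,
        planted_keys=planted,
        seed=derive_seed(config.seed, 41),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        matrix, labels, truth = generate_fingerprint_dataset(sim)
        growth_cfg = _default_growth_config(labels, config.seed, n_drugs=min(24, config.n_drugs))
        plate = simulate_growth_curves(growth_cfg)
    paths = {
        "fingerprints": out / "fingerprints.csv",
        "labels": out / "labels.csv",
        "plate_reads": out / "plate_reads.csv",
        "truth": out / "truth.json",
    }
    matrix.to_csv(paths["fingerprints"])
    labels_to_csv(labels, paths["labels"])
    plate.to_csv(paths["plate_reads"], index=False, float_format="%.6f")
    truth.to_json(paths["truth"])
    paths["manifest"] = _write_manifest(
        out, "simulate", config,
        {k: sha256_of(p.read_bytes()) for k, p in paths.items() if k != "manifest"},
        [str(w.message) for w in caught],
    )
    return paths


def run_train(config: PipelineConfig) -> dict[str, Any]:
    """Enrichment + five-learner marginalized CV + final GBM model + importance.

    Reads fingerprints/labels from the output directory (or the paths named
    in the config), filters constant keys, and writes the enrichment TSV,
    a per-method performance TSV, the persisted best-GBM model and its
    permutation-importance TSV.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fp_path = Path(config.structures or out / "fingerprints.csv")
    label_path = Path(config.labels or out / "labels.csv")
    matrix = FingerprintMatrix.read_csv(fp_path)
    labels = labels_from_csv(label_path)

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        retained = filter_constant_keys(matrix)
        results, significant = enrich_all(
            retained, labels, alpha=config.alpha, m_total=config.fdr_m_total
        )
        write_enrichment_tsv(results, out / "enrichment.tsv", alpha=config.alpha)

        cv = config.cv_config()
        summaries = {}
        grid_aucs_by_method = {}
        for method, spec in config.learners().items():
            preds, grid_aucs = marginalized_cv(
                retained, labels, spec, cv, return_grid_scores=True
            )
            summaries[method] = confusion_and_metrics(preds, threshold=cv.threshold_confusion)
            grid_aucs_by_method[method] = grid_aucs
        perf = performance_table(summaries, out / "performance.tsv")

        gbm_spec = config.learners()["gbm"]
        best = select_best_params(gbm_spec.grid, grid_aucs_by_method["gbm"])
        model = train_final_model(
            retained, labels, gbm_spec, best, seed=derive_seed(config.seed, 43)
        )
        model.save(out / "model.joblib")
        importance = permutation_importance(
            model, retained, labels, n_permutations=20, seed=derive_seed(config.seed, 47)
        )
        pd.DataFrame(
            {
                "key_id": [s.key_id for s in importance],
                "score": [s.score for s in importance],
                "rank": [s.rank for s in importance],
            }
        ).sort_values("rank").to_csv(out / "importance.tsv", sep="\t", index=False,
                                     float_format="%.4f")
    captured = [str(w.message) for w in caught]
    manifest = _write_manifest(
        out, "train", config,
        {"fingerprints": sha256_of(fp_path.read_bytes()), "labels": sha256_of(label_path.read_bytes())},
        captured,
    )
    return {
        "retained_keys": len(retained.key_ids),
        "n_significant": len(significant),
        "significant_keys": [r.key_id for r in significant],
        "performance": perf,
        "best_gbm_params": best,
        "model_path": out / "model.joblib",
        "manifest": manifest,
    }


def run_validate(config: PipelineConfig) -> dict[str, Any]:
    """Score new drugs with the trained model against measured efficacy.

    Needs the persisted model, plate reads for the validation drugs and their
    fingerprints. Produces the efficacy TSV, per-drug predictions joined with
    nearest training neighbors, and a report JSON with Spearman rho +
    permutation p, AUC (drugs with positive efficacy category = positives),
    and substrate calls at the low threshold.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_path = Path(config.model_path or out / "model.joblib")
    if not model_path.exists():
        raise FileNotFoundError(f"model artifact not found: {model_path}")
    model = load_model(model_path)

    plate_path = Path(config.plate_reads or out / "validation_plate_reads.csv")
    plate = read_plate_reads(plate_path)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        eff_table, _ = compute_efficacy_table(plate, epsilon=config.epsilon)
        write_efficacy_tsv(eff_table, out / "validation_efficacy.tsv")

        fp_path = Path(config.structures or out / "validation_fingerprints.csv")
        vmatrix_full = FingerprintMatrix.read_csv(fp_path)
        # restrict to the model's retained training keys for prediction
        keep = [vmatrix_full.key_ids.index(k) for k in model.key_ids]
        vmatrix = FingerprintMatrix(
            drug_ids=list(vmatrix_full.drug_ids),
            key_ids=list(model.key_ids),
            bits=vmatrix_full.bits[:, keep],
        )
        preds = model.predict_proba(vmatrix)

        merged = preds.to_frame(threshold_call=config.threshold_call).merge(
            eff_table, on="drug_id", how="inner"
        )
        if merged.empty:
            raise ValueError("no overlap between predicted drugs and efficacy table")

        rho, perm_p = spearman_permutation_test(
            merged["probability"], merged["mean_score"],
            n_perm=10_000, seed=derive_seed(config.seed, 53),
        )
        y = (merged["category"] == "sensitive").astype(int).to_numpy()
        auc = None
        if 0 < y.sum() < y.size:
            auc = rank_auc(merged["probability"].to_numpy(), y)
        else:
            warnings.warn("validation set has a single efficacy class; AUC undefined")
        calls = (merged["probability"] >= config.threshold_call).astype(int)
        tp = int(((calls == 1) & (y == 1)).sum())
        fp = int(((calls == 1) & (y == 0)).sum())

        # nearest training neighbors on the full 166-key profiles, if available
        train_fp = Path(config.out_dir) / "fingerprints.csv"
        neighbor_frame = None
        if train_fp.exists():
            training = FingerprintMatrix.read_csv(train_fp)
            if training.key_ids == vmatrix_full.key_ids:
                edges = nearest_training_neighbor(vmatrix_full, training)
                write_similarity_edges(edges, out / "nearest_neighbors.tsv")
                neighbor_frame = pd.DataFrame(
                    {
                        "drug_id": [e.query_id for e in edges],
                        "nearest_training_neighbor": [e.neighbor_id for e in edges],
                        "tanimoto": [e.tanimoto for e in edges],
                    }
                )
    if neighbor_frame is not None:
        merged = merged.merge(neighbor_frame, on="drug_id", how="left")
    merged.to_csv(out / "validation_table.csv", index=False, float_format="%.6f")

    report = {
        "n_drugs": int(merged.shape[0]),
        "spearman_rho": rho,
        "permutation_p": perm_p,
        "auc": auc,
        "n_substrate_calls": int(calls.sum()),
        "true_positive_calls": tp,
        "false_positive_calls": fp,
        "threshold_call": config.threshold_call,
    }
    (out / "validation_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(
        out, "validate", config,
        {"plate_reads": sha256_of(plate_path.read_bytes()),
         "fingerprints": sha256_of(fp_path.read_bytes()),
         "model": sha256_of(model_path.read_bytes())},
        [str(w.message) for w in caught],
    )
    return report
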