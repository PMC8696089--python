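"""Stage-wise additive ensemble of sparse log-ratio regressors.

Each stage trains a fresh relaxation against the logit-space predictions of
the current model (a fixed offset -- exactly residual fitting under logistic
loss), discretizes it by cross-validated thresholding with the lambda-SE
rule, and keeps the resulting ratio only if it beats the "no ratio" sentinel.
Training stops at the sentinel or at ``max_ratios``.  Stages are therefore
ordered by explanatory power: the first ratio is the most predictive, the
second predicts its residual, and so on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .data import BalancePartition, CompositionMatrix, validate_outcome
from .discretize import DiscretizedRatio, refit_linear, select_threshold_nested
from .optim import RelaxationFitConfig
from .ratios import exact_ratio

logger = logging.getLogger("codaratio")

SERIALIZATION_VERSION = 1


@dataclass
class EnsembleModel:
    """An ordered sequence of sparse log-ratio regressors plus provenance."""

    ratios: list[DiscretizedRatio]
    ratio_type: str
    lam: float
    base_rate_logit: float
    feature_names: list[str]
    fit_config: RelaxationFitConfig | None = None
    provenance: dict = field(default_factory=dict)
    train_auc: list[float] | None = None

    @property
    def n_stages(self) -> int:
        return len(self.ratios)

    @property
    def active_features(self) -> list[str]:
        seen: list[str] = []
        for ratio in self.ratios:
            for j in ratio.partition.j_plus + ratio.partition.j_minus:
                name = self.feature_names[j]
                if name not in seen:
                    seen.append(name)
        return seen


def _stage_seeds(seed: int, stage: int) -> tuple[int, int]:
    """Deterministic (relaxation seed, CV fold seed) for a stage."""
    state = np.random.SeedSequence([int(seed), int(stage)]).generate_state(2)
    return int(state[0] % (2**31)), int(state[1] % (2**31))


def fit_ensemble(x: CompositionMatrix, y, lam: float = 1.0, max_ratios: int = 5,
                 cfg: RelaxationFitConfig | None = None, *, cv_folds: int = 5,
                 metric: str = "xent") -> EnsembleModel:
    """Fit the full stage-wise model.

    Always returns a model; with zero accepted ratios it is the base-rate
    classifier.  Deterministic for fixed inputs and cfg.seed.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if max_ratios < 1:
        raise ValueError("max_ratios must be >= 1")
    cfg = cfg if cfg is not None else RelaxationFitConfig()
    y = validate_outcome(y, x.n, require_both_classes=True)
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    base_rate_logit = float(np.log(ybar / (1 - ybar)))

    offset = np.zeros(x.n)
    ratios: list[DiscretizedRatio] = []
    aucs: list[float] = []
    stage_records = []
    for stage in range(1, max_ratios + 1):
        relax_seed, fold_seed = _stage_seeds(cfg.seed, stage)
        chosen, _, _ = select_threshold_nested(
            x, y, offset, replace(cfg, seed=relax_seed), lam=lam,
            folds=cv_folds, seed=fold_seed, metric=metric,
        )
        stage_records.append({
            "stage": stage, "relaxation_seed": relax_seed, "cv_fold_seed": fold_seed,
            "t_hat": chosen.t, "n_active": chosen.n_active,
            "cv_score_mean": chosen.cv_score_mean, "cv_score_se": chosen.cv_score_se,
        })
        logger.info(
            "stage %d: t_hat=%.4f n_active=%d cv=%.4f+-%.4f",
            stage, chosen.t, chosen.n_active, chosen.cv_score_mean, chosen.cv_score_se,
        )
        if chosen.n_active == 0:
            break
        alpha, beta = refit_linear(x, y, offset, chosen.partition, cfg.ratio_type)
        ratios.append(DiscretizedRatio(chosen.partition, chosen.t, alpha, beta, cfg.ratio_type))
        offset = offset + alpha + beta * exact_ratio(x, chosen.partition, cfg.ratio_type)
        aucs.append(float(roc_auc_score(y, offset)))

    return EnsembleModel(
        ratios=ratios,
        ratio_type=cfg.ratio_type,
        lam=float(lam),
        base_rate_logit=base_rate_logit,
        feature_names=list(x.feature_names),
        fit_config=cfg,
        provenance={"seed": int(cfg.seed), "cv_folds": int(cv_folds),
                    "metric": metric, "stages": stage_records},
        train_auc=aucs,
    )


def _resolve_columns(model: EnsembleModel, x: CompositionMatrix) -> dict[int, int]:
    """Map model feature indices (only those a ratio uses) to x columns by name."""
    lookup = {name: j for j, name in enumerate(x.feature_names)}
    needed = sorted({j for r in model.ratios for j in r.partition.j_plus + r.partition.j_minus})
    missing = [model.feature_names[j] for j in needed if model.feature_names[j] not in lookup]
    if missing:
        raise KeyError(f"input is missing model features: {', '.join(missing)}")
    return {j: lookup[model.feature_names[j]] for j in needed}


def predict_logit(model: EnsembleModel, x: CompositionMatrix) -> np.ndarray:
    """Additive logit prediction; the empty model predicts the base rate."""
    if not model.ratios:
        return np.full(x.n, model.base_rate_logit)
    colmap = _resolve_columns(model, x)
    logits = np.zeros(x.n)
    for ratio in model.ratios:
        part = BalancePartition(
            tuple(colmap[j] for j in ratio.partition.j_plus),
            tuple(colmap[j] for j in ratio.partition.j_minus),
        )
        logits += ratio.alpha_hat + ratio.beta_hat * exact_ratio(x, part, ratio.ratio_type)
    return logits


def predict_proba(model: EnsembleModel, x: CompositionMatrix) -> np.ndarray:
    return expit(predict_logit(model, x))


def summarize(model: EnsembleModel) -> dict:
    """Ranked per-stage report: feature names, coefficients, cumulative AUC."""
    stages = []
    for k, ratio in enumerate(model.ratios):
        stage = {
            "stage": k + 1,
            "ratio_type": ratio.ratio_type,
            "numerator": [model.feature_names[j] for j in ratio.partition.j_plus],
            "denominator": [model.feature_names[j] for j in ratio.partition.j_minus],
            "t_hat": ratio.t_hat,
            "alpha": ratio.alpha_hat,
            "beta": ratio.beta_hat,
        }
        if model.train_auc is not None and k < len(model.train_auc):
            stage["cumulative_train_auc"] = model.train_auc[k]
        stages.append(stage)
    return {
        "ratio_type": model.ratio_type,
        "lambda": model.lam,
        "n_stages": model.n_stages,
        "base_rate_logit": model.base_rate_logit,
        "stages": stages,
    }


def format_summary(model: EnsembleModel) -> str:
    """Human-readable stage report."""
    report = summarize(model)
    lines = [
        f"ratio type      : {report['ratio_type']}",
        f"lambda          : {report['lambda']}",
        f"stages accepted : {report['n_stages']}",
        f"base-rate logit : {report['base_rate_logit']:.6f}",
    ]
    for st in report["stages"]:
        lines.append(
            f"stage {st['stage']}: log[{'num' if model.ratio_type == 'amalgamation' else 'gmean'}("
            f"{', '.join(st['numerator'])}) / ("
            f"{', '.join(st['denominator'])})]  "
            f"alpha={st['alpha']:.4f} beta={st['beta']:.4f}"
            + (f" train_auc={st['cumulative_train_auc']:.4f}"
               if "cumulative_train_auc" in st else "")
        )
    if not report["stages"]:
        lines.append("no ratio beat the base-rate classifier (model predicts the base rate)")
    return "\n".join(lines)


def to_json(model: EnsembleModel) -> str:
    """Versioned, human-readable serialization (bit-exact round trip)."""
    doc = {
        "version": SERIALIZATION_VERSION,
        "ratio_type": model.ratio_type,
        "lambda": model.lam,
        "stages": [
            {
                "numerator": [model.feature_names[j] for j in r.partition.j_plus],
                "denominator": [model.feature_names[j] for j in r.partition.j_minus],
                "alpha": r.alpha_hat,
                "beta": r.beta_hat,
            }
            for r in model.ratios
        ],
        "base_rate_logit": model.base_rate_logit,
        "seed": int(model.provenance.get("seed", 0)) if model.provenance else 0,
    }
    return json.dumps(doc, indent=2)


def from_json(text: str) -> EnsembleModel:
    doc = json.loads(text)
    if doc.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model document version {doc.get('version')!r}")
    feature_names: list[str] = []
    index: dict[str, int] = {}

    def _idx(name: str) -> int:
        if name not in index:
            index[name] = len(feature_names)
            feature_names.append(name)
        return index[name]

    ratios = []
    for st in doc["stages"]:
        part = BalancePartition(
            tuple(_idx(n) for n in st["numerator"]),
            tuple(_idx(n) for n in st["denominator"]),
        )
        ratios.append(DiscretizedRatio(part, float("nan"), st["alpha"], st["beta"], doc["ratio_type"]))
    return EnsembleModel(
        ratios=ratios,
        ratio_type=doc["ratio_type"],
        lam=doc["lambda"],
        base_rate_logit=doc["base_rate_logit"],
        feature_names=feature_names,
        provenance={"seed": doc.get("seed", 0)},
    )


def selection_stability(x: CompositionMatrix, y, n_resamples: int = 10,
                        cfg: RelaxationFitConfig | None = None, seed: int = 0,
                        *, lam: float = 1.0, train_frac: float = 0.8,
                        cv_folds: int = 5, metric: str = "xent") -> pd.DataFrame:
    """Stage-1 selection frequency across stratified resamples.

    Refits the first ratio on ``n_resamples`` independent ``train_frac``
    subsamples (stratified by outcome) and counts, per feature, how often it
    enters the stage-1 numerator or denominator.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    cfg = cfg if cfg is not None else RelaxationFitConfig()
    y = validate_outcome(y, x.n, require_both_classes=True)
    counts = pd.DataFrame(
        0, index=list(x.feature_names), columns=["numerator", "denominator"], dtype=int
    )
    for r in range(n_resamples):
        rs = int(np.random.SeedSequence([int(seed), r]).generate_state(1)[0] % (2**31))
        idx, _ = train_test_split(
            np.arange(x.n), train_size=train_frac, stratify=y, random_state=rs
        )
        model = fit_ensemble(
            x.subset_samples(np.sort(idx)), y[np.sort(idx)], lam=lam, max_ratios=1,
            cfg=replace(cfg, seed=rs), cv_folds=cv_folds, metric=metric,
        )
        if model.ratios:
            part = model.ratios[0].partition
            for j in part.j_plus:
                counts.iloc[j, 0] += 1
            for j in part.j_minus:
                counts.iloc[j, 1] += 1
    return counts
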