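"""Discretization: turn a trained soft assignment into a sparse partition.

Thresholding the soft assignment at t in (0, 1] yields a hard partition
(J+ = {j : w_tilde_j > t}, J- = {j : w_tilde_j < -t}).  Each candidate
threshold is scored by stratified cross-validation of a univariate logistic
refit on the exact ratio, and the sparsest candidate whose mean CV score is
within lambda standard errors of the best is selected (the lambda-SE rule;
lambda = 1 by default, lambda = 0 recovers the plain argmax).  The sentinel
t = 1 always yields the empty partition and is scored as the offset-only
model, so a ratio is kept only when it beats "no ratio" under the same rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import BalancePartition, CompositionMatrix, validate_outcome
from .optim import RelaxationFitConfig, cross_entropy_loss, fit_relaxation
from .ratios import exact_ratio, soft_assign

logger = logging.getLogger("codaratio")

MAX_ABS_BETA = 50.0
SCORE_METRICS = ("auc", "xent")


@dataclass
class ThresholdCandidate:
    """One point of the threshold sweep, with its CV score."""

    t: float
    partition: BalancePartition
    cv_score_mean: float
    cv_score_se: float
    n_active: int


@dataclass
class DiscretizedRatio:
    """A selected sparse log-ratio with its full-training-set refit."""

    partition: BalancePartition
    t_hat: float
    alpha_hat: float
    beta_hat: float
    ratio_type: str


def sentinel_candidate(mean: float = float("nan"), se: float = float("nan")) -> ThresholdCandidate:
    """The t = 1 'no ratio' candidate (both sides empty)."""
    return ThresholdCandidate(1.0, BalancePartition((), ()), mean, se, 0)


def threshold_partition(w_tilde, t: float) -> BalancePartition:
    """Hard partition at threshold t: strict inequalities on w_tilde."""
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold t must lie in (0, 1]")
    w_tilde = np.asarray(w_tilde, dtype=float)
    j_plus = tuple(np.flatnonzero(w_tilde > t).tolist())
    j_minus = tuple(np.flatnonzero(w_tilde < -t).tolist())
    return BalancePartition(j_plus, j_minus)


def candidate_grid(w_tilde) -> list[float]:
    """Thresholds to sweep: midpoints between consecutive distinct |w_tilde|
    values (so each grid point cleanly admits the next feature, avoiding
    knife-edge ties with the strict inequality), restricted to valid
    partitions, plus the sentinel t = 1."""
    w_tilde = np.asarray(w_tilde, dtype=float)
    mags = np.unique(np.abs(w_tilde))
    mags = mags[(mags > 0) & (mags < 1)]
    grid: list[float] = []
    prev = 0.0
    for v in mags:
        t = (prev + v) / 2.0
        prev = float(v)
        if not 0.0 < t < 1.0:
            continue
        if threshold_partition(w_tilde, t).is_valid:
            grid.append(t)
    grid.append(1.0)
    return grid


def _fit_intercept(y, offset, tol: float = 1e-10, max_iter: int = 100) -> float:
    """1-D Newton MLE for an intercept-only logistic model with offset."""
    y = np.asarray(y, dtype=float)
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    alpha = float(np.log(ybar / (1 - ybar)) - np.mean(offset))
    for _ in range(max_iter):
        mu = expit(offset + alpha)
        g = float(np.sum(mu - y))
        h = float(np.sum(mu * (1 - mu)))
        if abs(g) < tol or h <= 0:
            break
        alpha -= g / h
    return alpha


def _fit_univariate_logit(r, y, offset, max_beta: float = MAX_ABS_BETA,
                          tol: float = 1e-8, max_iter: int = 100) -> tuple[float, float]:
    """Damped-Newton MLE of y ~ alpha + beta*r with fixed logit offset.

    Deterministic; on (near-)separation |beta| is capped at ``max_beta`` and
    alpha refitted given the capped slope.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)

    if np.ptp(r) < 1e-12:
        # constant ratio carries no information: beta = 0 by convention
        return _fit_intercept(y, offset), 0.0

    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    alpha = float(np.log(ybar / (1 - ybar)) - offset.mean())
    beta = 0.0

    def total_loss(a, b):
        f = offset + a + b * r
        return float(np.sum(np.logaddexp(0.0, f) - y * f))

    loss = total_loss(alpha, beta)
    capped = False
    for _ in range(max_iter):
        f = offset + alpha + beta * r
        mu = expit(f)
        g0 = float(np.sum(mu - y))
        g1 = float(np.sum((mu - y) * r))
        if max(abs(g0), abs(g1)) < tol:
            break
        wts = mu * (1 - mu)
        h00 = float(np.sum(wts))
        h01 = float(np.sum(wts * r))
        h11 = float(np.sum(wts * r * r))
        det = h00 * h11 - h01 * h01
        if det <= 1e-300:
            capped = True
            break
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        s = 1.0
        new_a, new_b, new_loss = alpha, beta, loss
        for _ in range(40):
            cand_a = alpha - s * step0
            cand_b = beta - s * step1
            cand_loss = total_loss(cand_a, cand_b)
            if cand_loss <= loss + 1e-12:
                new_a, new_b, new_loss = cand_a, cand_b, cand_loss
                break
            s /= 2.0
        if (new_a, new_b) == (alpha, beta):
            break
        alpha, beta, loss = new_a, new_b, new_loss
        if abs(beta) > max_beta:
            capped = True
            break

    if capped or abs(beta) > max_beta:
        logger.warning(
            "univariate logistic refit hit the |beta| <= %.0f cap "
            "(data likely separable along the ratio)", max_beta,
        )
        beta = math.copysign(max_beta, beta if beta != 0 else 1.0)
        alpha = _fit_intercept(y, offset + beta * r)
    return float(alpha), float(beta)


def refit_linear(x, y, offset, part: BalancePartition, ratio_type: str = "balance") -> tuple[float, float]:
    """Maximum-likelihood (alpha, beta) for y ~ exact ratio score, fixed offset."""
    part.require_valid()
    y = validate_outcome(y)
    offset = np.zeros(y.size) if offset is None else np.asarray(offset, dtype=float)
    r = exact_ratio(x, part, ratio_type)
    return _fit_univariate_logit(r, y, offset)


def _held_out_score(y_test, logits_test, metric: str) -> float:
    if metric == "auc":
        return float(roc_auc_score(y_test, logits_test))
    if metric == "xent":
        return -cross_entropy_loss(logits_test, y_test)
    raise ValueError(f"unknown score metric {metric!r}; choose from {SCORE_METRICS}")


def _cv_partition_score(x, y, offset, part: BalancePartition | None, ratio_type: str,
                        folds: int, seed: int, metric: str) -> tuple[float, float]:
    """Stratified k-fold CV score of the exact-ratio refit (offset-only model
    when ``part`` is None or degenerate)."""
    y = validate_outcome(y, require_both_classes=True)
    offset = np.zeros(y.size) if offset is None else np.asarray(offset, dtype=float)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    class_min = int(np.bincount(y).min())
    if class_min < folds:
        raise ValueError(
            f"minority class has {class_min} samples < {folds} folds; every fold "
            "needs both classes -- use fewer folds or more data"
        )
    use_ratio = part is not None and part.is_valid
    r = exact_ratio(x, part, ratio_type) if use_ratio else np.zeros(y.size)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    scores = []
    for train, test in skf.split(np.zeros(y.size), y):
        if use_ratio:
            a, b = _fit_univariate_logit(r[train], y[train], offset[train])
        else:
            a, b = _fit_intercept(y[train], offset[train]), 0.0
        logits = offset[test] + a + b * r[test]
        scores.append(_held_out_score(y[test], logits, metric))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(folds))


def cv_score_threshold(x, y, offset, w_tilde, t: float, folds: int = 5, seed: int = 0,
                       ratio_type: str = "balance", metric: str = "xent") -> tuple[float, float]:
    """Cross-validated (mean, standard error) score of the partition at t."""
    part = threshold_partition(w_tilde, t)
    part.require_valid()
    return _cv_partition_score(x, y, offset, part, ratio_type, folds, seed, metric)


def lambda_se_rule(candidates: list[ThresholdCandidate], lam: float) -> ThresholdCandidate:
    """Sparsest candidate with mean score within lam SEs of the best.

    Ties on sparsity break toward larger t.  An empty candidate list returns
    the sentinel (no ratio).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not candidates:
        return sentinel_candidate()
    best = max(candidates, key=lambda c: (c.cv_score_mean, c.t))
    cutoff = best.cv_score_mean - lam * best.cv_score_se
    qualifying = [c for c in candidates if c.cv_score_mean >= cutoff]
    return min(qualifying, key=lambda c: (c.n_active, -c.t))


def select_threshold(x, y, offset, w_tilde, *, ratio_type: str = "balance", lam: float = 1.0,
                     folds: int = 5, seed: int = 0, metric: str = "xent"
                     ) -> tuple[ThresholdCandidate, list[ThresholdCandidate]]:
    """Sweep the candidate grid, CV-score every threshold (sentinel included,
    scored as the offset-only model) and apply the lambda-SE rule.

    Returns the selected candidate and the full scored table.  A selected
    candidate with ``n_active == 0`` means "keep no ratio".
    """
    w_tilde = np.asarray(w_tilde, dtype=float)
    offset = np.zeros(np.asarray(y).size) if offset is None else np.asarray(offset, dtype=float)
    candidates: list[ThresholdCandidate] = []
    for t in candidate_grid(w_tilde):
        if t >= 1.0:
            mean, se = _cv_partition_score(x, y, offset, None, ratio_type, folds, seed, metric)
            candidates.append(sentinel_candidate(mean, se))
        else:
            part = threshold_partition(w_tilde, t)
            mean, se = _cv_partition_score(x, y, offset, part, ratio_type, folds, seed, metric)
            candidates.append(ThresholdCandidate(float(t), part, mean, se, part.n_active))
    return lambda_se_rule(candidates, lam), candidates


def select_threshold_nested(x: CompositionMatrix, y, offset, cfg: RelaxationFitConfig, *,
                            lam: float = 1.0, folds: int = 5, seed: int = 0,
                            metric: str = "xent"
                            ) -> tuple[ThresholdCandidate, list[ThresholdCandidate], "np.ndarray"]:
    """Threshold selection with per-fold relaxation training (honest CV).

    The threshold t plays the role of a regularization parameter, so it is
    cross-validated the way a lasso path is: each fold trains its *own*
    relaxation on the fold's training part, thresholds that fold's soft
    assignment at every t of the common grid, refits (alpha, beta) on the
    training part and scores the held-out part.  The grid and the candidate
    partitions reported come from a relaxation trained on the full data;
    only the scores are fold-wise.  A fold whose partition at some t is
    degenerate contributes the offset-only score there.  The sentinel t = 1
    is scored as the offset-only model in every fold, so a ratio survives
    only if its sparsity level genuinely beats "no ratio" out of sample.

    Returns (selected candidate, scored table, full-data soft assignment).
    """
    y = validate_outcome(y, x.n, require_both_classes=True)
    offset = np.zeros(x.n) if offset is None else np.asarray(offset, dtype=float)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    class_min = int(np.bincount(y).min())
    if class_min < folds:
        raise ValueError(
            f"minority class has {class_min} samples < {folds} folds; every fold "
            "needs both classes -- use fewer folds or more data"
        )

    state_full = fit_relaxation(x, y, offset, cfg)
    wt_full = soft_assign(state_full.w)
    grid = candidate_grid(wt_full)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    scores = np.empty((folds, len(grid)))
    for k, (train, test) in enumerate(skf.split(np.zeros(y.size), y)):
        x_train = x.subset_samples(train)
        state_k = fit_relaxation(x_train, y[train], offset[train], cfg)
        wt_k = soft_assign(state_k.w)
        alpha_null = _fit_intercept(y[train], offset[train])
        null_score = _held_out_score(y[test], offset[test] + alpha_null, metric)
        for c, t in enumerate(grid):
            part = threshold_partition(wt_k, t) if t < 1.0 else None
            if part is None or not part.is_valid:
                scores[k, c] = null_score
                continue
            r = exact_ratio(x, part, ratio_type=cfg.ratio_type)
            a, b = _fit_univariate_logit(r[train], y[train], offset[train])
            scores[k, c] = _held_out_score(y[test], offset[test] + a + b * r[test], metric)

    means = scores.mean(axis=0)
    ses = scores.std(axis=0, ddof=1) / np.sqrt(folds)
    candidates: list[ThresholdCandidate] = []
    for c, t in enumerate(grid):
        if t >= 1.0:
            candidates.append(sentinel_candidate(float(means[c]), float(ses[c])))
        else:
            part = threshold_partition(wt_full, t)
            candidates.append(
                ThresholdCandidate(float(t), part, float(means[c]), float(ses[c]), part.n_active)
            )
    return lambda_se_rule(candidates, lam), candidates, wt_full
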