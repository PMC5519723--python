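"""Maximum-likelihood estimation of the three disease-symptom models.

All three models operate on the binary record matrix with symptom columns
``x_i`` and disease columns ``y_j``:

* **L1 logistic regression** — one classifier per disease, symptoms as
  features, regularization strength chosen per disease by seeded 3-fold
  cross-validated log-loss.
* **Naive Bayes** — closed-form smoothed conditionals
  ``p(x_i=1 | y_j)``, Laplace pseudocount chosen per disease by held-out
  predictive log-likelihood over the same folds.
* **Noisy OR** — a two-layer Bayesian network in which a present disease j
  fails to turn on symptom i with probability ``f_ij`` and a leak ``l_i``
  turns the symptom on when all parents are off::

      P(x_i = 1 | y_1..y_n) = 1 - (1 - l_i) * prod_j f_ij ** y_j

  With fully observed diseases the joint log-likelihood separates exactly
  across symptoms, so the joint MLE is computed symptom-by-symptom with
  L-BFGS on log-odds-transformed parameters, a moment-based initialization,
  and a monotone accepted-iterate trace.

Probabilities are clamped to ``[EPS, 1 - EPS]`` with ``EPS = 1e-6``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss

from .matrix import RecordMatrix

logger = logging.getLogger(__name__)

#: numerical clamp for all probabilities
EPS = 1e-6
#: clamp used when mapping initial values to the log-odds scale
_INIT_CLIP = 1e-3

DEFAULT_L1_GRID: tuple[float, ...] = tuple(np.logspace(-4, 1, 6))
DEFAULT_PSEUDOCOUNT_GRID: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0)
DEFAULT_FOLDS = 3


class DegenerateLabelError(ValueError):
    """Disease column is constant; per-disease models cannot be fit."""


def clamp(p: np.ndarray | float, eps: float = EPS):
    return np.clip(p, eps, 1.0 - eps)


# -- cross-validation folds ------------------------------------------------


def _stratified_folds(
    labels: np.ndarray, record_ids: Sequence[str], folds: int, seed: int
) -> np.ndarray:
    """Fold assignment per record, stratified by label.

    Records are keyed by id (sorted, then shuffled with the seed) before
    dealing round-robin into folds, so the assignment does not depend on the
    order in which patients appear in the matrix.
    """
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    order = np.argsort(np.asarray(record_ids, dtype=object))
    for label in (0, 1):
        stratum = [i for i in order if labels[i] == label]
        stratum = list(rng.permutation(stratum))
        for pos, idx in enumerate(stratum):
            assignment[idx] = pos % folds
    return assignment


def _check_folds(labels: np.ndarray, assignment: np.ndarray, folds: int) -> bool:
    for f in range(folds):
        held = labels[assignment == f]
        if held.size == 0 or held.min() == held.max():
            return False
    return True


# -- logistic regression ---------------------------------------------------


@dataclass
class LogisticModel:
    """Per-disease L1 logistic regression over symptom indicators."""

    disease_id: str
    symptom_ids: list[str]
    weights: np.ndarray
    intercept: float
    l1_strength: float
    cv_losses: dict[float, float] = field(default_factory=dict)


def _fit_l1(X: np.ndarray, y: np.ndarray, l1_strength: float) -> LogisticRegression:
    C = 1.0 / max(l1_strength, 1e-12)
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        max_iter=1000,
        tol=1e-8,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def fit_logistic(
    matrix: RecordMatrix,
    disease: str,
    l1_grid: Sequence[float] = DEFAULT_L1_GRID,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> LogisticModel:
    """Fit the per-disease classifier, selecting L1 strength by CV log-loss.

    Ties in mean held-out log-loss are broken toward stronger regularization.
    A single-value grid skips model selection entirely.
    """
    y = matrix.column(disease).astype(int)
    if y.min() == y.max():
        raise DegenerateLabelError(f"degenerate label for disease {disease!r}")
    X = matrix.symptom_block().astype(float)
    symptom_ids = matrix.symptom_ids
    if disease in symptom_ids:
        raise ValueError(f"{disease!r} is a symptom column, not a disease")
    l1_grid = sorted(set(float(v) for v in l1_grid))
    cv_losses: dict[float, float] = {}
    if len(l1_grid) == 1:
        best = l1_grid[0]
    else:
        assignment = _stratified_folds(y, matrix.patients, folds, seed)
        usable = _check_folds(y, assignment, folds)
        if not usable:
            logger.warning(
                "CV folds for %s lack both classes; defaulting to strongest "
                "regularization",
                disease,
            )
            best = max(l1_grid)
        else:
            for l1 in l1_grid:
                losses = []
                for f in range(folds):
                    tr, te = assignment != f, assignment == f
                    if y[tr].min() == y[tr].max():
                        losses = None
                        break
                    clf = _fit_l1(X[tr], y[tr], l1)
                    p = clf.predict_proba(X[te])[:, 1]
                    losses.append(log_loss(y[te], clamp(p), labels=[0, 1]))
                if losses is None:
                    logger.warning("skipping l1=%g for %s: degenerate fold", l1, disease)
                    continue
                cv_losses[l1] = float(np.mean(losses))
            if not cv_losses:
                best = max(l1_grid)
            else:
                # ties toward stronger regularization: sort by (loss, -l1)
                best = min(cv_losses, key=lambda l1: (round(cv_losses[l1], 12), -l1))
    clf = _fit_l1(X, y, best)
    return LogisticModel(
        disease_id=disease,
        symptom_ids=symptom_ids,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        l1_strength=float(best),
        cv_losses=cv_losses,
    )


# -- naive Bayes -----------------------------------------------------------


@dataclass
class NaiveBayesModel:
    """Per-disease smoothed conditionals p(x_i=1 | y_j) for both label values."""

    disease_id: str
    symptom_ids: list[str]
    p_present: np.ndarray
    p_absent: np.ndarray
    pseudocount: float
    class_prior: float
    cv_loglik: dict[float, float] = field(default_factory=dict)


def _nb_conditionals(X: np.ndarray, y: np.ndarray, alpha: float):
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    s1 = X[y == 1].sum(axis=0)
    s0 = X[y == 0].sum(axis=0)
    p_present = (s1 + alpha) / (n1 + 2.0 * alpha)
    p_absent = (s0 + alpha) / (n0 + 2.0 * alpha)
    return clamp(p_present), clamp(p_absent)


def fit_naive_bayes(
    matrix: RecordMatrix,
    disease: str,
    pseudocount_grid: Sequence[float] = DEFAULT_PSEUDOCOUNT_GRID,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> NaiveBayesModel:
    """Closed-form smoothed conditionals; pseudocount chosen by held-out
    predictive log-likelihood of the symptoms given the label."""
    y = matrix.column(disease).astype(int)
    if y.min() == y.max():
        raise DegenerateLabelError(f"degenerate label for disease {disease!r}")
    X = matrix.symptom_block().astype(float)
    grid = sorted(set(float(a) for a in pseudocount_grid))
    if any(a <= 0 for a in grid):
        raise ValueError("pseudocounts must be positive")
    cv_ll: dict[float, float] = {}
    if len(grid) == 1:
        best = grid[0]
    else:
        assignment = _stratified_folds(y, matrix.patients, folds, seed)
        if not _check_folds(y, assignment, folds):
            logger.warning(
                "CV folds for %s lack both classes; defaulting to strongest smoothing",
                disease,
            )
            best = max(grid)
        else:
            for alpha in grid:
                total = 0.0
                ok = True
                for f in range(folds):
                    tr, te = assignment != f, assignment == f
                    if y[tr].min() == y[tr].max():
                        ok = False
                        break
                    pp, pa = _nb_conditionals(X[tr], y[tr], alpha)
                    p = np.where(y[te, None] == 1, pp[None, :], pa[None, :])
                    total += float(
                        (X[te] * np.log(p) + (1 - X[te]) * np.log1p(-p)).sum()
                    )
                if not ok:
                    logger.warning("skipping alpha=%g for %s: degenerate fold", alpha, disease)
                    continue
                cv_ll[alpha] = total
            if not cv_ll:
                best = max(grid)
            else:
                best = max(cv_ll, key=lambda a: (round(cv_ll[a], 9), a))
    pp, pa = _nb_conditionals(X, y, best)
    prior = (y.sum() + best) / (len(y) + 2.0 * best)
    return NaiveBayesModel(
        disease_id=disease,
        symptom_ids=matrix.symptom_ids,
        p_present=pp,
        p_absent=pa,
        pseudocount=float(best),
        class_prior=float(prior),
        cv_loglik=cv_ll,
    )


# -- noisy OR --------------------------------------------------------------


@dataclass
class NoisyOrModel:
    """Jointly fitted noisy-OR network over all diseases and symptoms.

    ``failure[i, j]`` is f_ij for symptom i and disease j; ``leak[i]`` is
    l_i.  ``ll_traces`` holds, per symptom, the accepted-iterate (monotone)
    trace of that symptom's log-likelihood contribution.
    """

    disease_ids: list[str]
    symptom_ids: list[str]
    failure: np.ndarray
    leak: np.ndarray
    log_likelihood: float = float("nan")
    initial_log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    ll_traces: list[list[float]] = field(default_factory=list)

    def failure_for(self, disease_id: str, symptom_id: str) -> float:
        i = self.symptom_ids.index(symptom_id)
        j = self.disease_ids.index(disease_id)
        return float(self.failure[i, j])


def noisy_or_symptom_prob(
    parent_states: np.ndarray, failure_row: np.ndarray, leak: float
) -> float:
    """P(x_i = 1 | y) = 1 - (1 - l_i) * prod_{j: y_j = 1} f_ij."""
    y = np.asarray(parent_states)
    f = np.asarray(failure_row, dtype=float)
    if y.shape != f.shape:
        raise ValueError("parent_states and failure_row must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("parent states must be binary")
    if ((f < 0) | (f > 1)).any() or not 0.0 <= leak <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - (1.0 - leak) * np.prod(np.where(y == 1, f, 1.0)))


def _symptom_probs(Y: np.ndarray, failure: np.ndarray, leak: np.ndarray) -> np.ndarray:
    """(n_patients, n_symptoms) matrix of noisy-OR on-probabilities."""
    log_f = np.log(clamp(failure))  # (s, d)
    log_q = Y @ log_f.T + np.log1p(-clamp(leak))[None, :]
    return 1.0 - np.exp(log_q)


def noisy_or_log_likelihood(model: NoisyOrModel, matrix: RecordMatrix) -> float:
    """Sum of Bernoulli log-probabilities of observed symptoms given diseases."""
    if matrix.n_patients == 0:
        return 0.0
    if model.disease_ids != matrix.disease_ids or model.symptom_ids != matrix.symptom_ids:
        raise ValueError("model axes do not match matrix axes")
    Y = matrix.disease_block().astype(float)
    X = matrix.symptom_block().astype(float)
    P = clamp(_symptom_probs(Y, model.failure, model.leak))
    return float((X * np.log(P) + (1.0 - X) * np.log1p(-P)).sum())


def _symptom_nll(theta, U, n1, n0):
    """Negative log-likelihood and gradient for one symptom, grouped data.

    theta = logit([f_1..f_d, l]); U is (groups, d) unique disease rows,
    n1/n0 the symptom-on/off record counts per group.
    """
    f = expit(theta[:-1])
    l = expit(theta[-1])
    log_q = U @ np.log(f) + np.log1p(-l)
    q = np.exp(log_q)
    p = 1.0 - q
    p_c = clamp(p)
    q_c = clamp(q)
    ll = float(n1 @ np.log(p_c) + n0 @ np.log(q_c))
    # d ll / d logit(f_j) = sum_g u_gj (n0_g - n1_g q_g / p_g) (1 - f_j)
    ratio = n0 - n1 * (q_c / p_c)
    grad_f = (U * ratio[:, None]).sum(axis=0) * (1.0 - f)
    grad_l = float(-(ratio.sum()) * l)
    grad = np.concatenate([grad_f, [grad_l]])
    return -ll, -grad


def fit_noisy_or(
    matrix: RecordMatrix,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> NoisyOrModel:
    """Joint maximum-likelihood fit of all failure and leak probabilities.

    Diseases are fully observed, so the likelihood separates across symptoms;
    each symptom's (failure row, leak) is optimized by L-BFGS on the log-odds
    scale from a moment-based initialization (leak = symptom rate among
    disease-free records, failure from the pairwise rate difference).
    Iterates that do not improve the likelihood are rejected from the
    recorded trace, and the best accepted iterate is returned, so the final
    log-likelihood never falls below the initial one.  The fit itself is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    del seed  # deterministic: moment init, no stochastic steps
    d_idx, s_idx = matrix.disease_indices, matrix.symptom_indices
    if len(d_idx) == 0 or len(s_idx) == 0:
        raise ValueError("need at least one disease and one symptom column")
    if not np.isin(matrix.cells, (0, 1)).all():
        raise ValueError("matrix must be binary")
    Y = matrix.disease_block().astype(float)
    X = matrix.symptom_block().astype(float)
    n, d = Y.shape
    s = X.shape[1]

    U, inv = np.unique(Y, axis=0, return_inverse=True)
    group_sizes = np.bincount(inv, minlength=U.shape[0]).astype(float)

    disease_free = Y.sum(axis=1) == 0
    if disease_free.any():
        leak0 = X[disease_free].mean(axis=0)
    else:
        leak0 = X.mean(axis=0) * 0.5
    rate_given = np.empty((s, d))
    rate_without = np.empty((s, d))
    for j in range(d):
        on = Y[:, j] == 1
        rate_given[:, j] = X[on].mean(axis=0) if on.any() else 0.0
        rate_without[:, j] = X[~on].mean(axis=0) if (~on).any() else 0.0
    failure0 = 1.0 - np.maximum(0.0, rate_given - rate_without)

    failure0 = np.clip(failure0, _INIT_CLIP, 1.0 - _INIT_CLIP)
    leak0 = np.clip(leak0, _INIT_CLIP, 1.0 - _INIT_CLIP)

    failure = np.empty((s, d))
    leak = np.empty(s)
    traces: list[list[float]] = []
    total_iter = 0
    converged = True
    ll_init_total = 0.0
    for i in range(s):
        n1 = np.bincount(inv, weights=X[:, i], minlength=U.shape[0])
        n0 = group_sizes - n1
        theta0 = logit(np.concatenate([failure0[i], [leak0[i]]]))
        nll0, _ = _symptom_nll(theta0, U, n1, n0)
        ll_init_total += -nll0
        best = {"ll": -nll0, "theta": theta0}
        trace = [-nll0]

        def _record(theta, best=best, trace=trace, args=(U, n1, n0)):
            ll = -_symptom_nll(theta, *args)[0]
            if ll > best["ll"]:
                best["ll"] = ll
                best["theta"] = theta.copy()
                trace.append(ll)

        res = minimize(
            _symptom_nll,
            theta0,
            args=(U, n1, n0),
            jac=True,
            method="L-BFGS-B",
            callback=_record,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        _record(res.x)
        theta = best["theta"]
        failure[i] = clamp(expit(theta[:-1]))
        leak[i] = clamp(expit(theta[-1]))
        traces.append(trace)
        total_iter = max(total_iter, int(res.nit))
        if not res.success and int(res.nit) >= max_iter:
            converged = False

    model = NoisyOrModel(
        disease_ids=matrix.disease_ids,
        symptom_ids=matrix.symptom_ids,
        failure=failure,
        leak=leak,
        initial_log_likelihood=ll_init_total,
        n_iter=total_iter,
        converged=converged,
        ll_traces=traces,
    )
    model.log_likelihood = noisy_or_log_likelihood(model, matrix)
    return model


# -- serialization ---------------------------------------------------------


def model_to_dict(model) -> dict:
    """JSON-serializable parameter dump with diagnostics."""
    if isinstance(model, LogisticModel):
        return {
            "kind": "logistic",
            "disease_id": model.disease_id,
            "symptom_ids": model.symptom_ids,
            "weights": [float(w) for w in model.weights],
            "intercept": model.intercept,
            "l1_strength": model.l1_strength,
        }
    if isinstance(model, NaiveBayesModel):
        return {
            "kind": "naive_bayes",
            "disease_id": model.disease_id,
            "symptom_ids": model.symptom_ids,
            "p_present": [float(p) for p in model.p_present],
            "p_absent": [float(p) for p in model.p_absent],
            "pseudocount": model.pseudocount,
            "class_prior": model.class_prior,
        }
    if isinstance(model, NoisyOrModel):
        return {
            "kind": "noisy_or",
            "disease_ids": model.disease_ids,
            "symptom_ids": model.symptom_ids,
            "failure": model.failure.tolist(),
            "leak": model.leak.tolist(),
            "log_likelihood": model.log_likelihood,
            "initial_log_likelihood": model.initial_log_likelihood,
            "n_iter": model.n_iter,
            "converged": model.converged,
        }
    raise TypeError(f"unknown model type {type(model)!r}")


def model_from_dict(doc: dict):
    kind = doc["kind"]
    if kind == "logistic":
        return LogisticModel(
            disease_id=doc["disease_id"],
            symptom_ids=list(doc["symptom_ids"]),
            weights=np.asarray(doc["weights"], dtype=float),
            intercept=float(doc["intercept"]),
            l1_strength=float(doc["l1_strength"]),
        )
    if kind == "naive_bayes":
        return NaiveBayesModel(
            disease_id=doc["disease_id"],
            symptom_ids=list(doc["symptom_ids"]),
            p_present=np.asarray(doc["p_present"], dtype=float),
            p_absent=np.asarray(doc["p_absent"], dtype=float),
            pseudocount=float(doc["pseudocount"]),
            class_prior=float(doc["class_prior"]),
        )
    if kind == "noisy_or":
        return NoisyOrModel(
            disease_ids=list(doc["disease_ids"]),
            symptom_ids=list(doc["symptom_ids"]),
            failure=np.asarray(doc["failure"], dtype=float),
            leak=np.asarray(doc["leak"], dtype=float),
            log_likelihood=float(doc.get("log_likelihood", float("nan"))),
            initial_log_likelihood=float(
                doc.get("initial_log_likelihood", float("nan"))
            ),
            n_iter=int(doc.get("n_iter", 0)),
            converged=bool(doc.get("converged", False)),
        )
    raise ValueError(f"unknown model kind {kind!r}")
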