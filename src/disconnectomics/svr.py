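"""Multivariate SVR-based connectome lesion-symptom mapping (SVR-CLSM).

The behavioural score (compound CoC) is regressed on the patients x links
disconnection matrix with an epsilon-insensitive linear-kernel support vector
regression. Because the kernel is linear, the dual solution back-projects to
a primal weight vector w = sum_i alpha_i x_i over the support vectors — one
beta weight per link, the model's estimate of how strongly disconnection of
that link drives the score.

The regularisation parameter C is chosen by grid search over powers of two
(2^-30 ... 2^30 by default, 61 candidates) under repeated k-fold
cross-validation, maximising the sum of prediction accuracy (Pearson r
between out-of-fold predictions and observed scores) and reproducibility
(mean pairwise Pearson r between weight vectors fitted on different training
folds). Link-wise significance is then assessed by permutation: behavioural
scores are shuffled, the model refitted with the same C, and each link's
observed weight compared against its permutation distribution, with the
add-one estimator p = (1 + #{w_perm >= w_obs}) / (1 + n_perm) and Bonferroni
control over the tested links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .errors import ConfigurationError, DataContractError


@dataclass
class SvrConfig:
    """Tunable parameters of the SVR-CLSM analysis.

    c_exponent_range : (lo, hi, step)
        The C grid is ``2**e`` for e = lo, lo+step, ..., hi. Default
        (-30, 30, 1), i.e. 61 candidates.
    epsilon : width of the insensitivity tube of the SVR loss.
    n_folds, n_repeats : repeated k-fold CV layout for the C search.
    n_permutations : permutations of the behavioural scores for link p-values.
    alpha : familywise significance level before Bonferroni division.
    tail : ``positive`` tests the directed hypothesis that more disconnection
        raises the score (weights in the upper tail); ``two_sided`` uses |w|.
    normalize_features : ``none`` (raw disconnection counts) or
        ``unit_norm_per_patient`` (each patient's link vector scaled to unit
        L2 norm), provided for sensitivity analyses.
    """

    c_exponent_range: tuple[int, int, int] = (-30, 30, 1)
    epsilon: float = 0.1
    n_folds: int = 5
    n_repeats: int = 5
    n_permutations: int = 10_000
    alpha: float = 0.05
    tail: str = "positive"
    normalize_features: str = "none"
    tradeoff_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    max_iter: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.tail not in ("positive", "two_sided"):
            raise ConfigurationError(f"unknown tail {self.tail!r}")
        if self.normalize_features not in ("none", "unit_norm_per_patient"):
            raise ConfigurationError(
                f"unknown normalize_features {self.normalize_features!r}"
            )

    def c_grid(self) -> np.ndarray:
        lo, hi, step = self.c_exponent_range
        if step < 1 or hi < lo:
            raise ConfigurationError("bad c_exponent_range")
        return 2.0 ** np.arange(lo, hi + 1, step, dtype=float)


@dataclass
class CvResult:
    """Grid-search record: one row per C candidate, plus the chosen C."""

    table: pd.DataFrame  # columns: C, accuracy, reproducibility
    chosen_C: float

    def save_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ClsmResult:
    """Per-link beta weights, permutation p-values and Bonferroni flags."""

    beta: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    chosen_C: float
    n_permutations: int
    alpha: float
    link_index: list[tuple[int, int]] | None = None

    @property
    def n_links(self) -> int:
        return len(self.beta)

    def to_dataframe(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "beta": self.beta,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )
        if self.link_index is not None:
            df.insert(0, "roi_a", [a for a, _ in self.link_index])
            df.insert(1, "roi_b", [b for _, b in self.link_index])
            if names:
                df.insert(2, "name_a", [names[a] for a, _ in self.link_index])
                df.insert(3, "name_b", [names[b] for _, b in self.link_index])
        return df

    def save_csv(self, path: str | Path, names: dict[int, str] | None = None) -> None:
        self.to_dataframe(names).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_X_y(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DataContractError("X must be 2-D (patients x links)")
    if len(y) != X.shape[0]:
        raise DataContractError("X and y disagree on the number of patients")
    if X.shape[0] < 2:
        raise DataContractError("need at least 2 patients")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataContractError("non-finite values in X or y")
    return X, y


def normalize_features(X: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return X
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def fit_linear_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float = 0.1,
    max_iter: int = 1_000_000,
) -> tuple[np.ndarray, float]:
    """Fit an epsilon-insensitive linear SVR; return (weights, intercept).

    Weights are the primal feature-space weight vector obtained by
    back-projecting the dual solution, so ``X @ w + b`` reproduces the
    model's predictions exactly.
    """
    X, y = _check_X_y(X, y)
    model = SVR(kernel="linear", C=C, epsilon=epsilon, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # libsvm max_iter warnings
        model.fit(X, y)
    w = np.zeros(X.shape[1]) if model.dual_coef_.size == 0 else (
        model.dual_coef_ @ X[model.support_]
    ).ravel()
    return w, float(model.intercept_[0])


def _fit_gram(
    G_train: np.ndarray,
    X_train: np.ndarray,
    y_train: np.ndarray,
    C: float,
    epsilon: float,
    max_iter: int,
) -> tuple[np.ndarray, float, SVR]:
    """Fit on a precomputed Gram matrix; back-project to primal weights.

    The Gram matrix of a linear kernel is data-independent of y, so repeated
    fits (CV folds, permutations) reuse it instead of recomputing X X^T.
    """
    model = SVR(kernel="precomputed", C=C, epsilon=epsilon, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(G_train, y_train)
    if model.dual_coef_.size == 0:
        w = np.zeros(X_train.shape[1])
    else:
        w = (model.dual_coef_ @ X_train[model.support_]).ravel()
    return w, float(model.intercept_[0]), model


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0.0 when either side has zero variance."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b)[0])


def _fold_indices(
    n: int, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded shuffled k-fold split (no stratification beyond the shuffle)."""
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, n_folds)]


def optimize_C(X: np.ndarray, y: np.ndarray, config: SvrConfig) -> CvResult:
    """Choose C on a powers-of-two grid by repeated k-fold cross-validation.

    For every C, ``n_repeats`` rounds of ``n_folds``-fold CV are run on
    identical fold splits (so candidates face the same resampling).
    Accuracy is the mean over repeats of the Pearson r between pooled
    out-of-fold predictions and the observed scores; reproducibility is the
    mean pairwise Pearson r between all training-fold weight vectors. The
    chosen C maximises the (by default equally) weighted sum; ties resolve to
    the smallest C.
    """
    X, y = _check_X_y(X, y)
    X = normalize_features(X, config.normalize_features)
    n = len(y)
    if n < 2 * config.n_folds:
        raise ConfigurationError(
            f"need at least {2 * config.n_folds} patients for {config.n_folds}-fold CV"
        )
    grid = config.c_grid()
    rng = np.random.default_rng(config.seed)
    splits = [
        _fold_indices(n, config.n_folds, rng) for _ in range(config.n_repeats)
    ]
    G = X @ X.T
    wa, wr = config.tradeoff_weights
    rows = []
    for C in grid:
        accs = []
        weight_vectors = []
        for folds in splits:
            oof = np.zeros(n)
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                w, b, _ = _fit_gram(
                    G[np.ix_(train_idx, train_idx)],
                    X[train_idx],
                    y[train_idx],
                    C,
                    config.epsilon,
                    config.max_iter,
                )
                oof[test_idx] = X[test_idx] @ w + b
                weight_vectors.append(w)
            accs.append(_pearson(oof, y))
        W = np.stack(weight_vectors)
        m = len(W)
        pair_r = [
            _pearson(W[i], W[j]) for i in range(m) for j in range(i + 1, m)
        ]
        rows.append(
            {
                "C": C,
                "accuracy": float(np.mean(accs)),
                "reproducibility": float(np.mean(pair_r)) if pair_r else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    objective = wa * table["accuracy"] + wr * table["reproducibility"]
    chosen = float(table["C"].iloc[int(np.argmax(objective.to_numpy()))])
    return CvResult(table=table, chosen_C=chosen)


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    chosen_C: float,
    config: SvrConfig,
    link_index: list[tuple[int, int]] | None = None,
) -> ClsmResult:
    """Link-wise permutation test of the SVR beta weights.

    The observed model is fitted on (X, y); each permutation shuffles y,
    refits with the identical C and epsilon, and records the permuted weight
    vector. Per link, the add-one p-value counts permuted weights at least as
    extreme as the observed one (upper tail for ``positive``, absolute value
    for ``two_sided``); significance applies Bonferroni over the tested links.
    """
    X, y = _check_X_y(X, y)
    X = normalize_features(X, config.normalize_features)
    n_links = X.shape[1]
    n_perm = config.n_permutations
    bonferroni = config.alpha / n_links
    if 1.0 / (n_perm + 1) >= bonferroni:
        warnings.warn(
            f"with {n_perm} permutations the smallest attainable p-value "
            f"{1.0 / (n_perm + 1):.2e} cannot fall below the Bonferroni "
            f"threshold {bonferroni:.2e}; no link can reach significance",
            stacklevel=2,
        )
    G = X @ X.T
    w_obs, _, _ = _fit_gram(G, X, y, chosen_C, config.epsilon, config.max_iter)
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(n_links, dtype=np.int64)
    obs_stat = w_obs if config.tail == "positive" else np.abs(w_obs)
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        w_perm, _, _ = _fit_gram(G, X, y_perm, chosen_C, config.epsilon, config.max_iter)
        stat = w_perm if config.tail == "positive" else np.abs(w_perm)
        exceed += stat >= obs_stat
    p = (1.0 + exceed) / (1.0 + n_perm)
    significant = p < bonferroni
    return ClsmResult(
        beta=w_obs,
        p_value=p,
        significant=significant,
        chosen_C=float(chosen_C),
        n_permutations=n_perm,
        alpha=config.alpha,
        link_index=link_index,
    )
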