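"""Metrics, phenotype standardization and (nested) cross-validation.

Model accuracy is scored by the Pearson correlation between observed
and predicted trait values (the field's standard accuracy measure for
genomic estimated breeding values) together with the mean squared
error, averaged over the folds of a replicated k-fold cross-validation.
Hyperparameter tuning minimizes an inner cross-validated MSE with the
SABO optimizer, nested inside each outer training partition so the
held-out fold never informs the tuned model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .data import (GenotypeMatrix, PhenotypeVector, as_genotype_matrix,
                   as_phenotype_vector)
from .model import ILSTSVR, ILSTSVRHyperparams, TwinRegressionResults
from .sabo import SABOConfig, SearchBounds, optimize

__all__ = [
    "pearson", "mse", "standardize_phenotype", "kfold_indices",
    "FoldAssignment", "CVReport", "cross_validate", "default_bounds",
    "tune_and_evaluate",
]


def pearson(y, y_hat) -> float:
    """Pearson correlation coefficient cov(y, y_hat) / (sd_y sd_yhat)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError(f"length mismatch: {y.size} vs {y_hat.size}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(y, y_hat).statistic)


def mse(y, y_hat) -> float:
    """Mean squared error (1/n) sum (y_i - yhat_i)^2."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError(f"length mismatch: {y.size} vs {y_hat.size}")
    return float(np.mean((y - y_hat) ** 2))


def standardize_phenotype(y):
    """Center and scale to unit sample variance (n-1 denominator).

    Returns ``(z, mean, sd)`` so callers can invert the transform.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 observations to standardize")
    mu = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant phenotype")
    return (y - mu) / sd, mu, sd


@dataclass
class FoldAssignment:
    """A partition of samples 0..n-1 into k near-equal folds."""

    fold_of_sample: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)


def kfold_indices(n: int, k: int, seed: int) -> FoldAssignment:
    """Seeded random partition into k folds whose sizes differ by <= 1."""
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of_sample = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_of_sample[chunk] = f
    return FoldAssignment(fold_of_sample, k, seed)


@dataclass
class CVReport:
    """Per-fold and aggregated cross-validation metrics."""

    per_fold_pcc: np.ndarray
    per_fold_mse: np.ndarray
    k: int
    replicates: int
    seed: int
    tuned_hyperparams: list = None
    replicate_reports: list = field(default=None, repr=False)

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.per_fold_pcc))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.per_fold_mse))

    def to_dict(self) -> dict:
        out = {
            "k": self.k,
            "replicates": self.replicates,
            "seed": self.seed,
            "mean_pcc": self.mean_pcc,
            "mean_mse": self.mean_mse,
            "per_fold_pcc": [float(v) for v in self.per_fold_pcc],
            "per_fold_mse": [float(v) for v in self.per_fold_mse],
        }
        if self.tuned_hyperparams is not None:
            out["tuned_hyperparams"] = [
                {"C1": hp.C1, "C3": hp.C3, "eps1": hp.eps1, "eps2": hp.eps2,
                 "kernel": hp.kernel, "sigma": hp.sigma}
                for hp in self.tuned_hyperparams
            ]
        return out

    def summary(self) -> str:
        lines = [
            "Cross-validation report",
            "=" * 40,
            f"{'folds x replicates:':<24}{self.k} x {self.replicates}",
            f"{'mean PCC:':<24}{self.mean_pcc:.4f}",
            f"{'mean MSE:':<24}{self.mean_mse:.4f}",
            "=" * 40,
        ]
        return "\n".join(lines)


def _prepare_y(y_train, y_test, mode: str):
    """Standardize per the chosen mode; returns transformed train/test."""
    if mode == "off":
        return y_train, y_test
    if mode in ("fold", "global"):
        # 'global' standardization is applied once by the caller; inside a
        # fold both modes scale with the training statistics
        z, mu, sd = standardize_phenotype(y_train)
        return z, (y_test - mu) / sd
    raise ValueError(f"unknown standardization mode {mode!r}")


def cross_validate(X, Y, hyperparams: ILSTSVRHyperparams, k: int = 10,
                   replicates: int = 1, seed: int = 0,
                   standardize: str = "fold", max_iter: int = 50,
                   tol: float = 1e-4) -> CVReport:
    """Replicated k-fold cross-validation at fixed hyperparameters.

    Replicate r re-partitions the samples with ``seed + r``; each sample
    is predicted exactly once per replicate and the report aggregates
    the k*replicates fold-level PCC/MSE values by arithmetic mean.
    """
    X = as_genotype_matrix(X)
    Y = as_phenotype_vector(Y)
    n = X.n_samples
    if n // k < 2:
        raise ValueError(f"folds of {n}//{k} < 2 samples")
    y_all = Y.values
    if standardize == "global":
        y_all, _, _ = standardize_phenotype(y_all)
    pccs, mses = [], []
    for r in range(replicates):
        folds = kfold_indices(n, k, seed + r)
        for f in range(k):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            y_tr, y_te = _prepare_y(
                y_all[tr], y_all[te],
                "off" if standardize == "global" else standardize)
            res = ILSTSVR(y_tr, X.values[tr], hyperparams).fit(
                max_iter=max_iter, tol=tol)
            pred = res.predict(X.values[te])
            pccs.append(pearson(y_te, pred))
            mses.append(mse(y_te, pred))
    return CVReport(np.array(pccs), np.array(mses), k, replicates, seed)


def default_bounds(n_markers: int, kernel: str = "rbf") -> SearchBounds:
    """Default log-scaled search box over (C1, C3[, sigma]).

    The sigma range tracks sqrt(m), the typical scale of Euclidean
    distances between dosage vectors over m markers.
    """
    root_m = float(np.sqrt(n_markers))
    if kernel == "rbf":
        return SearchBounds(
            lower=[1e-3, 1e-4, 1e-2 * root_m],
            upper=[1e3, 1e2, 1e2 * root_m],
            scale=["log10", "log10", "log10"],
        )
    return SearchBounds(lower=[1e-3, 1e-4], upper=[1e3, 1e2],
                        scale=["log10", "log10"])


def _position_to_hyperparams(pos, kernel: str, eps1: float,
                             eps2: float) -> ILSTSVRHyperparams:
    if kernel == "rbf":
        C1, C3, sigma = pos
    else:
        C1, C3 = pos
        sigma = None
    return ILSTSVRHyperparams(C1=float(C1), C3=float(C3), eps1=eps1,
                              eps2=eps2, kernel=kernel, sigma=sigma)


def _inner_cv_mse(Xtr, ytr, hp, inner: str, inner_k: int, seed: int,
                  max_iter: int, tol: float) -> float:
    n = Xtr.shape[0]
    if inner == "holdout":
        folds = kfold_indices(n, 4, seed)        # 25% holdout
        splits = [(folds.train_indices(0), folds.test_indices(0))]
    else:
        folds = kfold_indices(n, inner_k, seed)
        splits = [(folds.train_indices(f), folds.test_indices(f))
                  for f in range(inner_k)]
    errs = []
    for tr, te in splits:
        res = ILSTSVR(ytr[tr], Xtr[tr], hp).fit(max_iter=max_iter, tol=tol)
        errs.append(mse(ytr[te], res.predict(Xtr[te])))
    return float(np.mean(errs))


def tune_and_evaluate(X, Y, bounds: SearchBounds | None = None,
                      sabo_config: SABOConfig | None = None, k: int = 10,
                      replicates: int = 1, seed: int = 0,
                      kernel: str = "rbf", eps1: float = 0.05,
                      eps2: float = 0.05, inner: str = "kfold",
                      inner_k: int = 5, standardize: str = "fold",
                      max_iter: int = 50, tol: float = 1e-4) -> CVReport:
    """SABO-tuned nested cross-validation.

    Within each outer training partition, SABO minimizes the inner
    cross-validated MSE over (C1, C3[, sigma]) with C2=C1 and C4=C3
    tied; the best hyperparameters are then refit on the full outer
    training partition and scored on the held-out fold.  ``inner`` may
    be ``'kfold'`` (default, ``inner_k`` folds) or ``'holdout'`` (a
    single 75/25 split, faster).
    """
    X = as_genotype_matrix(X)
    Y = as_phenotype_vector(Y)
    if bounds is None:
        bounds = default_bounds(X.n_markers, kernel)
    if sabo_config is None:
        sabo_config = SABOConfig(seed=seed)
    n = X.n_samples
    y_all = Y.values
    if standardize == "global":
        y_all, _, _ = standardize_phenotype(y_all)
    pccs, mses_, tuned = [], [], []
    for r in range(replicates):
        folds = kfold_indices(n, k, seed + r)
        for f in range(k):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            y_tr, y_te = _prepare_y(
                y_all[tr], y_all[te],
                "off" if standardize == "global" else standardize)
            Xtr = X.values[tr]
            inner_seed = (seed + 7919 * r + 104729 * f) % (2 ** 31)

            def fitness(pos):
                hp = _position_to_hyperparams(pos, kernel, eps1, eps2)
                return _inner_cv_mse(Xtr, y_tr, hp, inner, inner_k,
                                     inner_seed, max_iter, tol)

            cfg = SABOConfig(n_agents=sabo_config.n_agents,
                             n_iterations=sabo_config.n_iterations,
                             seed=inner_seed,
                             v_choices=sabo_config.v_choices,
                             v_continuous=sabo_config.v_continuous)
            best_pos, _, _ = optimize(fitness, bounds, cfg)
            hp = _position_to_hyperparams(best_pos, kernel, eps1, eps2)
            res = ILSTSVR(y_tr, Xtr, hp).fit(max_iter=max_iter, tol=tol)
            pred = res.predict(X.values[te])
            pccs.append(pearson(y_te, pred))
            mses_.append(mse(y_te, pred))
            tuned.append(hp)
    return CVReport(np.array(pccs), np.array(mses_), k, replicates, seed,
                    tuned_hyperparams=tuned)
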