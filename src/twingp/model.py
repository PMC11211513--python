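"""Least-squares twin support vector regression with iterative L1 reweighting.

The regressor is the average of two epsilon-offset bound functions

    f1(x) = w1' phi(x) + b1      (down-bound)
    f2(x) = w2' phi(x) + b2      (up-bound)
    f(x)  = (f1(x) + f2(x)) / 2

where phi is the identity (linear) or the RBF feature map evaluated
against the training samples (kernel form).  Each side minimizes an
unconstrained quadratic: a squared residual shifted by -eps (down) or
+eps (up), a penalty C on the opposite-shifted residual, and optionally
a Lasso term on the weights.  The L1 penalty ||w||_1 is handled by the
standard reweighting identity ||w||_1 = ||alpha * w||_2^2 with
alpha_i = 1/|w_i|, which turns each side into a ridge-like linear
system re-solved as alpha is updated; with the Lasso weight set to zero
the model reduces to plain LSTSVR and a single solve per side is exact.

The public surface is both functional (``solve_twin_side``,
``fit_ilstsvr``, ``predict``) and object-oriented in the statsmodels
style (``ILSTSVR(y, X, ...).fit()`` returning a results object).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .data import (GenotypeMatrix, PhenotypeVector, as_genotype_matrix,
                   as_phenotype_vector)
from .kernels import build_feature_matrix

ALPHA_FLOOR = 1e-8

__all__ = [
    "ILSTSVRHyperparams", "TwinSystem", "solve_twin_side", "update_alpha",
    "twin_objective", "ILSTSVR", "LSTSVR", "TwinRegressionResults",
    "fit_ilstsvr", "fit_lstsvr", "predict",
]


@dataclass(frozen=True)
class ILSTSVRHyperparams:
    """Hyperparameters of the twin regressor.

    C1 is the residual penalty (tied: C2 = C1); C3 the Lasso penalty
    (tied: C4 = C3, zero recovers LSTSVR); eps1/eps2 the down/up bound
    offsets; sigma the RBF width (used iff kernel='rbf').
    """

    C1: float = 1.0
    C3: float = 0.0
    eps1: float = 0.05
    eps2: float = 0.05
    kernel: str = "linear"
    sigma: float | None = None

    def __post_init__(self):
        if self.C1 <= 0:
            raise ValueError(f"C1 must be positive, got {self.C1}")
        if self.C3 < 0:
            raise ValueError(f"C3 must be nonnegative, got {self.C3}")
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValueError("eps1 and eps2 must be nonnegative")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "rbf" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("rbf kernel requires sigma > 0")

    # the two penalties of the up-side are tied to the down-side
    @property
    def C2(self) -> float:
        return self.C1

    @property
    def C4(self) -> float:
        return self.C3


@dataclass
class TwinSystem:
    """One side's assembled (p+1)x(p+1) normal equations."""

    lhs: np.ndarray
    rhs: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.lhs).all() or not np.isfinite(self.rhs).all():
            raise ValueError("non-finite entries in assembled twin system")
        asym = np.abs(self.lhs - self.lhs.T).max()
        scale = max(np.abs(self.lhs).max(), 1.0)
        if asym > 1e-10 * scale:
            raise ValueError(f"twin system lhs not symmetric (max dev {asym:g})")


def _eps_sign(side: str, C: float) -> float:
    # down-bound: the eps column of the rhs carries (C-1); up-bound: (1-C)
    if side == "down":
        return C - 1.0
    if side == "up":
        return 1.0 - C
    raise ValueError(f"side must be 'down' or 'up', got {side!r}")


def assemble_twin_system(H, Y, C, C_reg, eps, alpha, side) -> TwinSystem:
    """Build the linear system whose solution is one side's (w, b).

    The bias carries the same Lasso penalty C_reg as the weights, so the
    bottom-right entry is (1+C) n + C_reg.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    n, p = H.shape
    if alpha.size != p:
        raise ValueError(f"alpha has length {alpha.size}, expected {p}")
    if np.any(alpha <= 0):
        raise ValueError("alpha entries must be strictly positive")
    s = _eps_sign(side, C)
    h = H.sum(axis=0)
    lhs = np.empty((p + 1, p + 1))
    lhs[:p, :p] = (1.0 + C) * (H.T @ H)
    lhs[np.arange(p), np.arange(p)] += C_reg * alpha * alpha
    lhs[:p, p] = (1.0 + C) * h
    lhs[p, :p] = (1.0 + C) * h
    lhs[p, p] = (1.0 + C) * n + C_reg
    rhs = np.empty(p + 1)
    rhs[:p] = (1.0 + C) * (H.T @ Y) + s * eps * h
    rhs[p] = (1.0 + C) * Y.sum() + s * eps * n
    return TwinSystem(lhs, rhs)


def _solve_spd(lhs: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Cholesky solve with one ridge-jitter retry for near-singular systems."""
    try:
        c, low = scipy.linalg.cho_factor(lhs, check_finite=False)
        return scipy.linalg.cho_solve((c, low), rhs, check_finite=False)
    except scipy.linalg.LinAlgError:
        pass
    dim = lhs.shape[0]
    jitter = 1e-10 * (np.trace(lhs) / dim)
    lhs = lhs + jitter * np.eye(dim)
    try:
        c, low = scipy.linalg.cho_factor(lhs, check_finite=False)
        return scipy.linalg.cho_solve((c, low), rhs, check_finite=False)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"twin system singular even after ridge jitter {jitter:g} "
            f"(dim {dim}, trace {np.trace(lhs):g})"
        ) from err


def solve_twin_side(H, Y, C, C_reg, eps, alpha, side):
    """Exact minimizer (w, b) of one side's quadratic objective at fixed alpha.

    Parameters
    ----------
    H : (n, p) array
        Feature matrix (markers, or kernel evaluations against training
        samples).
    Y : (n,) array
    C : float
        Positive residual penalty.
    C_reg : float
        Nonnegative Lasso-surrogate penalty on weights and bias.
    eps : float
        Bound offset (nonnegative).
    alpha : (p,) array
        Strictly positive reweighting vector; the effective ridge is
        ``C_reg * diag(alpha)^2``.
    side : {'down', 'up'}

    Returns
    -------
    w : (p,) ndarray
    b : float
    """
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if C_reg < 0 or eps < 0:
        raise ValueError("C_reg and eps must be nonnegative")
    Y = np.asarray(Y, dtype=float).ravel()
    if not np.isfinite(Y).all():
        raise ValueError("non-finite phenotype values")
    sys = assemble_twin_system(H, Y, C, C_reg, eps, alpha, side)
    sol = _solve_spd(sys.lhs, sys.rhs)
    return sol[:-1], float(sol[-1])


def twin_objective(H, Y, C, C_reg, eps, alpha, side, w, b) -> float:
    """Value of one side's objective at (w, b); used for verification."""
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    r = Y - H @ w - b
    e = np.ones_like(r)
    if side == "down":
        main = 0.5 * np.sum((r - eps * e) ** 2) + 0.5 * C * np.sum((r + eps * e) ** 2)
    elif side == "up":
        main = 0.5 * np.sum((r + eps * e) ** 2) + 0.5 * C * np.sum((r - eps * e) ** 2)
    else:
        raise ValueError(f"side must be 'down' or 'up', got {side!r}")
    reg = 0.5 * C_reg * (np.sum((alpha * w) ** 2) + b * b)
    return float(main + reg)


def update_alpha(w, floor: float = ALPHA_FLOOR) -> np.ndarray:
    """Reweighting update alpha_i = 1 / max(|w_i|, floor)."""
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    w = np.asarray(w, dtype=float).ravel()
    return 1.0 / np.maximum(np.abs(w), floor)


def _init_alpha(p: int, how: str, rng: np.random.Generator | None) -> np.ndarray:
    if how == "ones":
        return np.ones(p)
    if how == "random":
        if rng is None:
            rng = np.random.default_rng()
        return rng.uniform(0.5, 1.5, size=p)
    raise ValueError(f"unknown alpha initialization {how!r}")


class ILSTSVR:
    """Lasso-regularized least-squares twin support vector regressor.

    Parameters
    ----------
    endog : array or PhenotypeVector
        Trait values, length n.
    exog : array or GenotypeMatrix
        Marker dosages, n x m.
    hyperparams : ILSTSVRHyperparams, optional
        May instead be given piecewise via keyword arguments
        (``C1, C3, eps1, eps2, kernel, sigma``).

    Examples
    --------
    >>> res = ILSTSVR(y, X, C1=1.0, C3=0.5, kernel='linear').fit()
    >>> res.predict(X_new)
    """

    def __init__(self, endog, exog, hyperparams: ILSTSVRHyperparams | None = None,
                 **kwargs):
        self.exog = as_genotype_matrix(exog)
        self.endog = as_phenotype_vector(endog)
        if self.endog.n_samples != self.exog.n_samples:
            raise ValueError(
                f"{self.endog.n_samples} phenotypes for "
                f"{self.exog.n_samples} genotype rows"
            )
        if hyperparams is None:
            hyperparams = ILSTSVRHyperparams(**kwargs)
        elif kwargs:
            hyperparams = replace(hyperparams, **kwargs)
        self.hyperparams = hyperparams

    @classmethod
    def from_dataframe(cls, genotypes, phenotypes, trait=None, **kwargs):
        """Build from pandas DataFrames (samples as index, markers/traits as
        columns); rows are inner-joined on the index."""
        import pandas as pd

        common = genotypes.index.intersection(phenotypes.index)
        if len(common) == 0:
            raise ValueError("no shared sample ids between the two frames")
        g = genotypes.loc[common]
        col = phenotypes[trait] if trait is not None else phenotypes.iloc[:, 0]
        X = GenotypeMatrix(g.to_numpy(dtype=float), list(g.index),
                           [str(c) for c in g.columns])
        Y = PhenotypeVector(col.loc[common].to_numpy(dtype=float), list(common),
                            trait or str(phenotypes.columns[0]))
        return cls(Y, X, **kwargs)

    def _features(self) -> np.ndarray:
        hp = self.hyperparams
        return build_feature_matrix(self.exog, self.exog, hp.kernel, hp.sigma)

    def fit(self, max_iter: int = 50, tol: float = 1e-4,
            alpha_init: str = "ones", seed: int | None = None
            ) -> "TwinRegressionResults":
        """Run the alternating reweighting loop until the alphas settle.

        Each iteration solves the two twin systems exactly at the current
        alphas, then refreshes ``alpha_i = 1/max(|w_i|, 1e-8)``; the loop
        stops when the largest relative alpha change drops below ``tol``
        or after ``max_iter`` iterations.  ``alpha_init='random'`` draws
        the starting alphas from Uniform(0.5, 1.5) with ``seed``.
        """
        hp = self.hyperparams
        H = self._features()
        Y = self.endog.values
        p = H.shape[1]
        rng = np.random.default_rng(seed) if seed is not None else None
        alpha1 = _init_alpha(p, alpha_init, rng)
        alpha2 = _init_alpha(p, alpha_init, rng)

        # precompute the alpha-independent parts of both systems
        n = H.shape[0]
        G = (1.0 + hp.C1) * (H.T @ H)
        h = H.sum(axis=0)
        HtY = H.T @ Y
        base = np.empty((p + 1, p + 1))
        base[:p, :p] = G
        base[:p, p] = (1.0 + hp.C1) * h
        base[p, :p] = (1.0 + hp.C1) * h
        base[p, p] = (1.0 + hp.C1) * n + hp.C3
        diag_idx = np.arange(p)
        rhs1 = np.empty(p + 1)
        rhs1[:p] = (1.0 + hp.C1) * HtY + (hp.C1 - 1.0) * hp.eps1 * h
        rhs1[p] = (1.0 + hp.C1) * Y.sum() + (hp.C1 - 1.0) * hp.eps1 * n
        rhs2 = np.empty(p + 1)
        rhs2[:p] = (1.0 + hp.C2) * HtY + (1.0 - hp.C2) * hp.eps2 * h
        rhs2[p] = (1.0 + hp.C2) * Y.sum() + (1.0 - hp.C2) * hp.eps2 * n

        def solve(alpha_vec, rhs):
            lhs = base.copy()
            if hp.C3 > 0:
                lhs[diag_idx, diag_idx] += hp.C3 * alpha_vec * alpha_vec
            sol = _solve_spd(lhs, rhs)
            return sol[:-1], float(sol[-1])

        converged = False
        n_iter = 0
        w1 = w2 = None
        b1 = b2 = 0.0
        for n_iter in range(1, max_iter + 1):
            w1, b1 = solve(alpha1, rhs1)
            w2, b2 = solve(alpha2, rhs2)
            if hp.C3 == 0.0:
                # the Lasso block vanishes: one exact solve, no iteration
                converged = True
                break
            new1 = update_alpha(w1)
            new2 = update_alpha(w2)
            delta = max(
                np.max(np.abs(new1 - alpha1) / (1.0 + np.abs(alpha1))),
                np.max(np.abs(new2 - alpha2) / (1.0 + np.abs(alpha2))),
            )
            alpha1, alpha2 = new1, new2
            if delta < tol:
                converged = True
                break

        return TwinRegressionResults(
            model=self, w1=w1, b1=b1, w2=w2, b2=b2,
            alpha1=alpha1, alpha2=alpha2,
            n_iterations=n_iter, converged=converged,
        )


class LSTSVR(ILSTSVR):
    """Plain least-squares twin SVR (no Lasso term): the C3=0 special case,
    fitted by a single exact solve per side."""

    def __init__(self, endog, exog, hyperparams: ILSTSVRHyperparams | None = None,
                 **kwargs):
        if hyperparams is not None:
            hyperparams = replace(hyperparams, C3=0.0)
        else:
            kwargs.pop("C3", None)
            kwargs["C3"] = 0.0
        super().__init__(endog, exog, hyperparams, **kwargs)


@dataclass
class TwinRegressionResults:
    """Fitted twin regressor: the two bound functions plus diagnostics.

    ``w1``/``w2`` have one entry per marker (linear) or per training
    sample (rbf); predictions average the two bounds.
    """

    model: ILSTSVR
    w1: np.ndarray
    b1: float
    w2: np.ndarray
    b2: float
    alpha1: np.ndarray
    alpha2: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def hyperparams(self) -> ILSTSVRHyperparams:
        return self.model.hyperparams

    @property
    def train_X(self) -> GenotypeMatrix | None:
        """Training genotypes (kept for kernel prediction)."""
        if self.hyperparams.kernel == "rbf":
            return self.model.exog
        return None

    @property
    def params(self) -> np.ndarray:
        """Averaged coefficients 0.5*(w1+w2) followed by the averaged bias."""
        return np.concatenate([0.5 * (self.w1 + self.w2),
                               [0.5 * (self.b1 + self.b2)]])

    def predict(self, X_new) -> np.ndarray:
        """f(x) = 0.5 * phi(x) (w1+w2) + 0.5 (b1+b2)."""
        from .kernels import _values

        hp = self.hyperparams
        if hp.kernel == "rbf" and self.train_X is None:
            raise ValueError("kernel model lost its training genotypes")
        ref = self.train_X if hp.kernel == "rbf" else X_new
        if hp.kernel == "linear" and _values(X_new).shape[1] != self.w1.size:
            raise ValueError(
                f"model was trained on {self.w1.size} markers, "
                f"got {_values(X_new).shape[1]}"
            )
        Phi = build_feature_matrix(X_new, ref, hp.kernel, hp.sigma)
        return 0.5 * (Phi @ (self.w1 + self.w2)) + 0.5 * (self.b1 + self.b2)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog.values - self.fittedvalues

    def summary(self) -> str:
        hp = self.hyperparams
        n, m = self.model.exog.values.shape
        resid = self.resid
        lines = [
            "Twin Support Vector Regression Results",
            "=" * 46,
            f"{'No. samples:':<26}{n}",
            f"{'No. markers:':<26}{m}",
            f"{'Kernel:':<26}{hp.kernel}",
            f"{'C1 (=C2):':<26}{hp.C1:.6g}",
            f"{'C3 (=C4, Lasso):':<26}{hp.C3:.6g}",
            f"{'eps1 / eps2:':<26}{hp.eps1:.6g} / {hp.eps2:.6g}",
        ]
        if hp.kernel == "rbf":
            lines.append(f"{'sigma:':<26}{hp.sigma:.6g}")
        lines += [
            f"{'Iterations:':<26}{self.n_iterations}"
            f" ({'converged' if self.converged else 'not converged'})",
            f"{'b1 / b2:':<26}{self.b1:.6g} / {self.b2:.6g}",
            f"{'Training MSE:':<26}{np.mean(resid ** 2):.6g}",
            f"{'Nonzero |w| (>1e-6):':<26}"
            f"{int(np.sum(np.abs(0.5 * (self.w1 + self.w2)) > 1e-6))}",
            "=" * 46,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_ilstsvr(X, Y, hyperparams: ILSTSVRHyperparams, max_iter: int = 50,
                tol: float = 1e-4, seed: int | None = None,
                alpha_init: str = "ones") -> TwinRegressionResults:
    """Fit an ILSTSVR model (see :class:`ILSTSVR` for the object interface)."""
    return ILSTSVR(Y, X, hyperparams).fit(max_iter=max_iter, tol=tol,
                                          alpha_init=alpha_init, seed=seed)


def fit_lstsvr(X, Y, hyperparams: ILSTSVRHyperparams) -> TwinRegressionResults:
    """Fit the plain LSTSVR model (C3 forced to zero; single solve)."""
    return LSTSVR(Y, X, hyperparams).fit()


def predict(model: TwinRegressionResults, X_new) -> np.ndarray:
    return model.predict(X_new)
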