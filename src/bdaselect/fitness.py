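"""PLS regression with k-fold cross-validation; RMSECV as the selection cost.

The optimizer's cost for a candidate wavelength mask is the root-mean-square
error of cross-validation (RMSECV) of a partial-least-squares calibration
built on the selected channels only: lower is better. PLS is fitted by
NIPALS with mean-centering (no scaling), kept deliberately lean because the
cost function sits in the optimizer's inner loop and is evaluated tens of
thousands of times per experiment; at full rank it coincides with ordinary
least squares.

The fold assignment lives in :class:`FitnessConfig` and is drawn once per
optimizer run, so every individual in the swarm is scored against the same
partition and costs are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import SpectraDataset, WavelengthMask

__all__ = [
    "FitnessConfig",
    "FitnessValue",
    "PLSModel",
    "make_folds",
    "pls_fit",
    "rmsecv",
    "r2_cv",
    "explained_variance_components",
]

#: Sentinel cost for an all-zero mask; large enough never to become the food
#: source while staying finite for bookkeeping.
EMPTY_MASK_COST = 1e10


def make_folds(n_samples: int, k_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random near-equal-size fold labels in ``{0, ..., k_folds-1}``."""
    if not 2 <= k_folds <= n_samples:
        raise ValueError(f"k_folds must be in [2, {n_samples}], got {k_folds}")
    sizes = np.full(k_folds, n_samples // k_folds)
    sizes[: n_samples % k_folds] += 1
    labels = np.repeat(np.arange(k_folds), sizes)
    return labels[rng.permutation(n_samples)]


@dataclass
class FitnessConfig:
    """Cross-validated PLS cost-function settings.

    ``n_latent`` is the number of PLS latent variables (default 2) and
    ``k_folds`` the number of CV folds (default 5). ``fold_assignment``
    maps each sample to its fold and is shared by every mask evaluation
    within one optimizer run.
    """

    fold_assignment: np.ndarray
    n_latent: int = 2
    k_folds: int = 5
    empty_mask_cost: float = EMPTY_MASK_COST

    def __post_init__(self) -> None:
        self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        n = self.fold_assignment.size
        if not 2 <= self.k_folds <= n:
            raise ValueError(f"k_folds must be in [2, {n}]")
        counts = np.bincount(self.fold_assignment, minlength=self.k_folds)
        if counts.size != self.k_folds or np.any(counts == 0):
            raise ValueError("every fold must be non-empty")

    @classmethod
    def for_dataset(
        cls,
        dataset: SpectraDataset,
        n_latent: int = 2,
        k_folds: int = 5,
        rng: np.random.Generator | int | None = None,
    ) -> "FitnessConfig":
        """Draw a fold assignment for ``dataset`` and build a config."""
        rng = np.random.default_rng(rng)
        return cls(
            fold_assignment=make_folds(dataset.n_samples, k_folds, rng),
            n_latent=n_latent,
            k_folds=k_folds,
        )

    def for_subset(self, rows: np.ndarray, rng: np.random.Generator) -> "FitnessConfig":
        """Fresh fold assignment sized to a sample subset (bootstrap use)."""
        return replace(
            self, fold_assignment=make_folds(len(rows), self.k_folds, rng)
        )


@dataclass
class FitnessValue:
    """RMSECV of one mask plus per-fold diagnostics."""

    rmsecv: float
    n_selected: int
    per_fold_rmse: np.ndarray

    @property
    def is_valid(self) -> bool:
        return self.n_selected > 0


@dataclass
class PLSModel:
    """Linear predictor ``y = X @ coef + intercept`` from a PLS fit."""

    coef: np.ndarray
    intercept: float
    n_latent: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def pls_fit(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSModel:
    """Fit a PLS1 regression by NIPALS (mean-centered, unscaled).

    Deflation stops early if the residual X'y covariance vanishes, so the
    returned model may use fewer latent variables than requested when the
    data are exhausted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_latent < 1:
        raise ValueError("n_latent must be >= 1")
    if n_latent > min(n - 1, p):
        raise ValueError(
            f"n_latent={n_latent} exceeds min(n_samples-1, n_features)="
            f"{min(n - 1, p)}"
        )
    if np.ptp(y) == 0:
        raise ValueError("zero-variance target")

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((p, n_latent))
    P = np.empty((p, n_latent))
    Q = np.empty(n_latent)
    a = 0
    for a in range(n_latent):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:  # X residual carries no covariance with y
            break
        w /= norm
        t = Xc @ w
        tt = t @ t
        p_load = Xc.T @ t / tt
        q = (yc @ t) / tt
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, p_load, q
        a += 1
    if a == 0:
        return PLSModel(coef=np.zeros(p), intercept=y_mean, n_latent=0)
    W, P, Q = W[:, :a], P[:, :a], Q[:a]
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PLSModel(coef=coef, intercept=y_mean - x_mean @ coef, n_latent=a)


def _mask_bool(mask: WavelengthMask | np.ndarray, n_channels: int) -> np.ndarray:
    bits = mask.bits if isinstance(mask, WavelengthMask) else np.asarray(mask)
    if bits.size != n_channels:
        raise ValueError(
            f"mask length {bits.size} does not match {n_channels} channels"
        )
    return bits.astype(bool)


def _cv_predictions(
    dataset: SpectraDataset,
    mask: WavelengthMask | np.ndarray,
    config: FitnessConfig,
) -> tuple[np.ndarray, int]:
    """Pooled held-out predictions for all samples; returns (y_hat, n_selected)."""
    sel = _mask_bool(mask, dataset.n_channels)
    n_sel = int(sel.sum())
    if n_sel == 0:
        return np.array([]), 0
    X = dataset.absorbance[:, sel]
    y = dataset.target
    folds = config.fold_assignment
    if folds.size != dataset.n_samples:
        raise ValueError("fold assignment does not match dataset size")
    y_hat = np.empty_like(y)
    for k in range(config.k_folds):
        test = folds == k
        train = ~test
        n_train = int(train.sum())
        if n_train < 2:
            raise ValueError(f"fold {k} leaves fewer than 2 training samples")
        # clamp latent variables to what the selected block can support
        n_lat = min(config.n_latent, n_sel, n_train - 1)
        model = pls_fit(X[train], y[train], n_lat)
        y_hat[test] = model.predict(X[test])
    return y_hat, n_sel


def rmsecv(
    dataset: SpectraDataset,
    mask: WavelengthMask | np.ndarray,
    config: FitnessConfig,
) -> FitnessValue:
    """Cross-validated RMSE of the PLS model on the masked channels.

    Each fold is predicted by a model trained on the other folds;
    ``rmsecv = sqrt(mean over all n samples of squared held-out residual)``.
    An empty mask gets the sentinel ``config.empty_mask_cost``.
    """
    y_hat, n_sel = _cv_predictions(dataset, mask, config)
    if n_sel == 0:
        return FitnessValue(
            rmsecv=config.empty_mask_cost,
            n_selected=0,
            per_fold_rmse=np.full(config.k_folds, config.empty_mask_cost),
        )
    resid2 = (dataset.target - y_hat) ** 2
    per_fold = np.array(
        [
            np.sqrt(resid2[config.fold_assignment == k].mean())
            for k in range(config.k_folds)
        ]
    )
    return FitnessValue(
        rmsecv=float(np.sqrt(resid2.mean())),
        n_selected=n_sel,
        per_fold_rmse=per_fold,
    )


def r2_cv(
    dataset: SpectraDataset,
    mask: WavelengthMask | np.ndarray,
    config: FitnessConfig,
) -> float:
    """Coefficient of determination of the pooled cross-validated predictions."""
    y_hat, n_sel = _cv_predictions(dataset, mask, config)
    if n_sel == 0:
        raise ValueError("cannot compute R2 for an empty mask")
    y = dataset.target
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero-variance target")
    return 1.0 - ss_res / ss_tot


def explained_variance_components(dataset: SpectraDataset) -> np.ndarray:
    """Cumulative PCA explained-variance fractions of the absorbance matrix.

    A sanity check for the latent-variable default on new data: if the first
    two principal components already carry most of the spectral variance,
    two PLS latent variables are a reasonable starting point.
    """
    from sklearn.decomposition import PCA

    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    n_comp = min(dataset.n_samples - 1, dataset.n_channels)
    pca = PCA(n_components=n_comp)
    pca.fit(dataset.absorbance)
    return np.cumsum(pca.explained_variance_ratio_)
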