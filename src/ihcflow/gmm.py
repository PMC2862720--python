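"""Gaussian mixture color models and Bayesian pixel classification.

An IHC micrograph is segmented into three pixel classes by color: the
staining part of the cells (SP, the brown DAB reaction product), the
non-staining cell part (NSP, blue hematoxylin counterstain), and the
background (BG). Each class's RGB color distribution is modeled as a
Gaussian mixture

    f(x; lambda) = sum_j p_j N(x; mu_j, Sigma_j),   sum_j p_j = 1,

fit by expectation-maximization, and a pixel is assigned to the class
with the highest posterior probability (class prior times mixture
likelihood). The default component counts are 5 for SP, 10 for NSP and
2 for BG, reflecting the multi-modal color distributions of stained
tissue, counterstained nuclei/cytoplasm, and near-white background.

All densities are evaluated in log space: with 3x3 covariances on byte
data, linear-space likelihood products underflow immediately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DegenerateInputError

# Label codes used in every mask in the package.
BG, NSP, SP = 0, 1, 2
CLASS_NAMES = ("sp", "nsp", "bg")  # fixed tie-break order: SP > NSP > BG
#: label code emitted for each position in CLASS_NAMES order
_CLASS_CODES = np.array([SP, NSP, BG])

DEFAULT_COMPONENT_COUNTS = {"sp": 5, "nsp": 10, "bg": 2}


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: weight, RGB mean and 3x3 covariance."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if not (0.0 < self.weight < 1.0 or np.isclose(self.weight, 1.0)):
            raise ConfigurationError(f"component weight must lie in (0, 1]: {self.weight}")
        if cov.shape != (mean.size, mean.size):
            raise ConfigurationError("covariance shape does not match mean dimension")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ConfigurationError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ConfigurationError("covariance must be positive definite")


class MixtureModel:
    """A convex combination of Gaussian densities over RGB space."""

    def __init__(self, components: Sequence[GaussianComponent]):
        if len(components) < 1:
            raise ConfigurationError("a mixture needs at least one component")
        self.components = list(components)
        weights = np.array([c.weight for c in self.components])
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mixture weights must sum to 1 (got {weights.sum():.12f})"
            )
        self._weights = weights
        self._means = np.stack([c.mean for c in self.components])
        self._covs = np.stack([c.cov for c in self.components])
        # Pre-factor the covariances once; used by every density evaluation.
        self._chol = []
        for i, cov in enumerate(self._covs):
            try:
                self._chol.append(np.linalg.cholesky(cov))
            except np.linalg.LinAlgError as exc:
                raise DegenerateInputError(
                    f"singular covariance in component {i}"
                ) from exc

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self._means.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return self._weights.copy()

    @property
    def means(self) -> np.ndarray:
        return self._means.copy()

    @property
    def covs(self) -> np.ndarray:
        return self._covs.copy()

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Log mixture density at each row of ``x`` (shape (n, d) or (d,))."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n, d = x.shape
        if d != self.dim:
            raise ConfigurationError(f"expected {self.dim}-vectors, got dimension {d}")
        log_terms = np.empty((n, self.n_components))
        cst = -0.5 * d * np.log(2.0 * np.pi)
        for j, L in enumerate(self._chol):
            diff = x - self._means[j]
            z = np.linalg.solve(L, diff.T)  # whitened residuals, shape (d, n)
            maha = np.sum(z * z, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            log_terms[:, j] = np.log(self._weights[j]) + cst - 0.5 * (logdet + maha)
        return logsumexp(log_terms, axis=1)

    def density(self, x: np.ndarray) -> np.ndarray | float:
        out = np.exp(self.log_density(x))
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    # ---- persistence -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "components": [
                {"weight": float(c.weight), "mean": c.mean.tolist(), "cov": c.cov.tolist()}
                for c in self.components
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        comps = [
            GaussianComponent(c["weight"], np.array(c["mean"]), np.array(c["cov"]))
            for c in d["components"]
        ]
        return cls(comps)


def mixture_density(x: np.ndarray, model: MixtureModel) -> float:
    """Mixture density f(x; lambda) = sum_j p_j N(x; mu_j, Sigma_j)."""
    return float(np.exp(model.log_density(np.asarray(x, dtype=float)))[0])


@dataclass
class FitReport:
    model: MixtureModel
    loglik_trace: list[float]
    n_iter: int
    converged: bool


def fit_em(
    samples: np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg_covar: float = 1e-3,
) -> FitReport:
    """Fit a Gaussian mixture to color samples by expectation-maximization.

    Initialization is k-means seeding with the given ``seed``; each M-step
    adds ``reg_covar`` * I to every covariance (1e-3 on the 0-255 scale) so
    quantized colors cannot produce singular fits. Iteration stops when the
    relative log-likelihood improvement drops below ``tol`` or after
    ``max_iter`` iterations; the log-likelihood is non-decreasing throughout.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("samples must be a 2-D array of vectors")
    n, d = X.shape
    if n_components < 1:
        raise ConfigurationError("need at least one component")
    if n < n_components:
        raise ConfigurationError(
            f"need at least {n_components} samples to fit {n_components} components, got {n}"
        )

    km = KMeans(n_clusters=n_components, n_init=3, random_state=seed)
    labels = km.fit_predict(X)
    weights = np.array([(labels == j).mean() for j in range(n_components)])
    weights = np.clip(weights, 1e-6, None)
    weights /= weights.sum()
    means = km.cluster_centers_.copy()
    covs = np.empty((n_components, d, d))
    for j in range(n_components):
        pts = X[labels == j]
        if len(pts) > 1:
            covs[j] = np.cov(pts, rowvar=False)
        else:
            covs[j] = np.zeros((d, d))
        covs[j] += reg_covar * np.eye(d)

    trace: list[float] = []
    converged = False
    cst = -0.5 * d * np.log(2.0 * np.pi)
    for it in range(max_iter):
        # E-step in log space
        log_r = np.empty((n, n_components))
        for j in range(n_components):
            try:
                L = np.linalg.cholesky(covs[j])
            except np.linalg.LinAlgError as exc:
                raise DegenerateInputError(
                    f"degenerate covariance in component {j} after regularization"
                ) from exc
            diff = X - means[j]
            z = np.linalg.solve(L, diff.T)
            maha = np.sum(z * z, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            log_r[:, j] = np.log(weights[j]) + cst - 0.5 * (logdet + maha)
        log_norm = logsumexp(log_r, axis=1)
        loglik = float(log_norm.sum())
        trace.append(loglik)
        if it > 0:
            prev = trace[-2]
            rel = abs(loglik - prev) / max(abs(prev), 1e-300)
            if rel < tol:
                converged = True
                break
        resp = np.exp(log_r - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for j in range(n_components):
            diff = X - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
            covs[j] += reg_covar * np.eye(d)

    comps = [
        GaussianComponent(float(w), m, c) for w, m, c in zip(weights, means, covs)
    ]
    return FitReport(
        model=MixtureModel(comps),
        loglik_trace=trace,
        n_iter=len(trace),
        converged=converged,
    )


class ClassModelSet:
    """One mixture model per pixel class plus class priors.

    Class priors default to uniform; they are configurable and recorded in
    the persisted JSON. Classification is invariant to rescaling all priors
    by a positive constant.
    """

    def __init__(
        self,
        sp: MixtureModel,
        nsp: MixtureModel,
        bg: MixtureModel,
        class_priors: Sequence[float] | None = None,
    ):
        self.sp, self.nsp, self.bg = sp, nsp, bg
        priors = np.full(3, 1.0 / 3.0) if class_priors is None else np.asarray(
            class_priors, dtype=float
        )
        if priors.shape != (3,) or np.any(priors <= 0):
            raise ConfigurationError("class priors must be 3 positive numbers")
        self.class_priors = priors / priors.sum()

    @property
    def models(self) -> tuple[MixtureModel, MixtureModel, MixtureModel]:
        return (self.sp, self.nsp, self.bg)  # CLASS_NAMES order

    # ---- persistence -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_priors": self.class_priors.tolist(),
            "classes": {
                name: model.to_dict()
                for name, model in zip(CLASS_NAMES, self.models)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassModelSet":
        payload = json.loads(Path(path).read_text())
        models = {
            name: MixtureModel.from_dict(payload["classes"][name])
            for name in CLASS_NAMES
        }
        return cls(
            sp=models["sp"],
            nsp=models["nsp"],
            bg=models["bg"],
            class_priors=payload["class_priors"],
        )


def train_class_models(
    pixels_by_class: dict[str, np.ndarray],
    component_counts: dict[str, int] | None = None,
    seed: int = 0,
    class_priors: Sequence[float] | None = None,
    **em_kwargs,
) -> tuple[ClassModelSet, dict[str, FitReport]]:
    """Fit the SP/NSP/BG mixtures from per-class pixel samples."""
    counts = dict(DEFAULT_COMPONENT_COUNTS)
    if component_counts:
        counts.update(component_counts)
    reports: dict[str, FitReport] = {}
    for i, name in enumerate(CLASS_NAMES):
        if name not in pixels_by_class:
            raise ConfigurationError(f"missing pixel samples for class '{name}'")
        reports[name] = fit_em(
            pixels_by_class[name], counts[name], seed=seed + i, **em_kwargs
        )
    model_set = ClassModelSet(
        sp=reports["sp"].model,
        nsp=reports["nsp"].model,
        bg=reports["bg"].model,
        class_priors=class_priors,
    )
    return model_set, reports


def class_log_posteriors(x: np.ndarray, model_set: ClassModelSet) -> np.ndarray:
    """Unnormalized-then-normalized log posteriors over (SP, NSP, BG)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    log_post = np.empty((x.shape[0], 3))
    for c, model in enumerate(model_set.models):
        log_post[:, c] = np.log(model_set.class_priors[c]) + model.log_density(x)
    if not np.all(np.isfinite(logsumexp(log_post, axis=1))):
        raise DegenerateInputError("all class likelihoods are zero for some input")
    return log_post - logsumexp(log_post, axis=1)[:, None]


def class_posteriors(x: np.ndarray, model_set: ClassModelSet) -> np.ndarray:
    """Posterior P(class | color) over (SP, NSP, BG); sums to 1."""
    out = np.exp(class_log_posteriors(x, model_set))
    out /= out.sum(axis=1, keepdims=True)  # absorb residual float error
    return out[0] if np.asarray(x).ndim == 1 else out


def classify_pixels(image: np.ndarray, model_set: ClassModelSet) -> np.ndarray:
    """Per-pixel maximum-posterior label mask (codes 0=BG, 1=NSP, 2=SP).

    Ties break by the fixed class order SP > NSP > BG, biasing toward
    detection of staining.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ConfigurationError("expected a non-empty H x W x 3 RGB image")
    h, w = img.shape[:2]
    flat = img.reshape(-1, 3).astype(float)
    log_post = class_log_posteriors(flat, model_set)
    # argmax over CLASS_NAMES order (SP first) → first maximum wins ties
    winner = np.argmax(log_post, axis=1)
    return _CLASS_CODES[winner].reshape(h, w)
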