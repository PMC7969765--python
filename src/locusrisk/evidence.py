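"""Multi-omics evidence integration.

Continuous features are decorrelated by the Hotelling transform (projection
onto the eigenvectors of their covariance), each retained component is made
approximately Gaussian by a Box-Cox power transform, converted to an
upper-tail normal p-value, and finally combined with the gene's raw p-value
features by Fisher's combined probability test. The per-gene evidence score
is -ln of the combined p-value, a non-negative quantity that grows with the
strength of the multi-omics support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import P_FLOOR, EvidenceScores, FeatureBundle, ValidationError

__all__ = [
    "HotellingModel",
    "BoxCoxFit",
    "hotelling_transform",
    "boxcox_fit",
    "boxcox_apply",
    "gaussian_pvalues",
    "fisher_combine",
    "fisher_combined_pvalue",
    "compute_evidence",
    "DegenerateDataError",
]

_AUTO_EIGENVALUE_RTOL = 1e-10  # "auto" keeps components with lambda_k > rtol * lambda_1


class DegenerateDataError(ValueError):
    """Data carries no usable variation for the requested operation."""


@dataclass
class HotellingModel:
    """Fitted decorrelating projection.

    Attributes
    ----------
    means : column means M of the input matrix.
    eigenvalues : covariance eigenvalues, non-increasing.
    eigenvectors : matrix whose rows v_k are the unit eigenvectors matching
        ``eigenvalues``.
    n_components : retained count n <= m.
    """

    means: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_components: int

    @property
    def projection(self) -> np.ndarray:
        """U: the top-n eigenvector rows."""
        return self.eigenvectors[: self.n_components]


@dataclass(frozen=True)
class BoxCoxFit:
    """Shift constant and fitted exponent for one component."""

    shift: float
    beta: float


def hotelling_transform(
    P: np.ndarray, n_components: int | str = "auto"
) -> tuple[HotellingModel, np.ndarray]:
    """Project a g x m feature matrix onto its covariance eigenvectors.

    Returns the fitted model and the g x n component matrix U (P - M)^T,
    transposed back to g x n. Components are mutually uncorrelated. With
    ``n_components="auto"`` numerically null directions are dropped
    (eigenvalue below 1e-10 times the leading one). Each retained component
    is sign-oriented so that its largest-magnitude loading is positive
    (eigenvector signs are otherwise arbitrary).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValidationError("feature matrix must be 2-D")
    g, m = P.shape
    if g < 2 or m < 1:
        raise ValidationError(f"need >= 2 genes and >= 1 feature, got {P.shape}")
    if not np.isfinite(P).all():
        raise ValidationError("feature matrix has non-finite entries")

    means = P.mean(axis=0)
    centered = P - means
    cov = np.cov(centered, rowvar=False, ddof=1).reshape(m, m)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are eigenvectors

    # orient: largest-|loading| entry positive
    for k in range(m):
        j = np.argmax(np.abs(evecs[k]))
        if evecs[k, j] < 0:
            evecs[k] = -evecs[k]

    rank = int(np.sum(evals > _AUTO_EIGENVALUE_RTOL * max(evals[0], np.finfo(float).tiny)))
    if n_components == "auto":
        n = max(rank, 1)
    else:
        n = int(n_components)
        if n < 1 or n > m:
            raise ValidationError(f"n_components must be in [1, {m}], got {n}")
        if n > max(rank, 1):
            raise ValidationError(
                f"requested {n} components but covariance rank is {rank}"
            )
    model = HotellingModel(means=means, eigenvalues=evals, eigenvectors=evecs, n_components=n)
    transformed = centered @ model.projection.T
    return model, transformed


def boxcox_fit(
    x: np.ndarray, interval: tuple[float, float] = (-5.0, 5.0), tol: float = 1e-5
) -> BoxCoxFit:
    """Fit a Box-Cox exponent by profile maximum likelihood.

    The data are first shifted to be strictly positive (c = 0 if min(x) > 0,
    else 1 - min(x)); the exponent maximizing the profile log-likelihood is
    found by golden-section search over ``interval``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValidationError("boxcox_fit needs a 1-D vector of length >= 10")
    if not np.isfinite(x).all():
        raise ValidationError("boxcox_fit input has non-finite entries")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant vector: Box-Cox likelihood is flat")
    mn = float(x.min())
    shift = 0.0 if mn > 0 else 1.0 - mn
    shifted = x + shift

    def nll(beta: float) -> float:
        return -float(stats.boxcox_llf(beta, shifted))

    beta = _golden_section(nll, interval[0], interval[1], tol)
    return BoxCoxFit(shift=shift, beta=float(beta))


def _golden_section(f, a: float, b: float, tol: float) -> float:
    """Minimize a unimodal function on [a, b] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def boxcox_apply(x: np.ndarray, fit: BoxCoxFit) -> np.ndarray:
    """Apply a fitted Box-Cox transform: ((x+c)^beta - 1)/beta, log at beta=0."""
    x = np.asarray(x, dtype=float)
    shifted = x + fit.shift
    if np.any(shifted <= 0):
        raise ValidationError("shifted values must be strictly positive")
    if abs(fit.beta) < 1e-8:
        return np.log(shifted)
    return (shifted**fit.beta - 1.0) / fit.beta


def gaussian_pvalues(y: np.ndarray, tail: str = "upper") -> np.ndarray:
    """Standardize a component and convert to normal p-values.

    z = (y - mean)/sd with the sample sd (denominator g-1); p is the
    upper-tail standard-normal probability (or the two-sided one if
    ``tail="two_sided"``), clamped into [1e-300, 1].
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValidationError("need >= 2 values")
    sd = y.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("constant component: cannot standardize")
    z = (y - y.mean()) / sd
    if tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "two_sided":
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return np.clip(p, P_FLOOR, 1.0)


def fisher_combined_pvalue(pvalues: np.ndarray) -> float:
    """Fisher's combined probability: chi-square survival of -2 sum(ln p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    T = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(T, df=2 * p.size))


def fisher_combine(transformed_row: np.ndarray, raw_row: np.ndarray) -> float:
    """Per-gene evidence: -ln of the Fisher-combined p over both categories."""
    p = np.concatenate([np.atleast_1d(transformed_row), np.atleast_1d(raw_row)])
    combined = fisher_combined_pvalue(p)
    return float(-np.log(max(combined, P_FLOOR)))


def compute_evidence(
    bundle: FeatureBundle,
    n_components: int | str = "auto",
    tail: str = "upper",
    boxcox_interval: tuple[float, float] = (-5.0, 5.0),
) -> EvidenceScores:
    """Run the full evidence pipeline over a feature bundle.

    Continuous features -> Hotelling components -> per-component Box-Cox ->
    Gaussian p-values; then Fisher-combine with the gene's raw p-value
    features. Deterministic given the bundle and settings.
    """
    n_raw = bundle.n_pvalue_features
    m = bundle.n_continuous_features
    if n_raw == 0 and m == 0:
        raise ValidationError("feature bundle has no features at all")

    comp_pvals = np.empty((len(bundle.genes), 0))
    if m > 0:
        _, components = hotelling_transform(bundle.continuous.to_numpy(), n_components)
        cols = []
        for k in range(components.shape[1]):
            col = components[:, k]
            if np.ptp(col) == 0:
                continue  # numerically dead direction; contributes nothing
            fit = boxcox_fit(col, interval=boxcox_interval)
            cols.append(gaussian_pvalues(boxcox_apply(col, fit), tail=tail))
        if cols:
            comp_pvals = np.column_stack(cols)

    raw = bundle.pvalues.to_numpy()
    scores = {
        gene: fisher_combine(comp_pvals[i], raw[i])
        for i, gene in enumerate(bundle.genes)
    }
    return EvidenceScores(scores=scores)
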