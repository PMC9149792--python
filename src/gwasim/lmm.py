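"""From-scratch linear mixed model association engine.

Model: y = Xβ + g + e with g ~ N(0, σ²_g K) and e ~ N(0, σ²_e I), where
K is the genomic relationship matrix (GRM) built from standardized
genotypes.  Following the FaST-LMM construction, K is eigendecomposed
once; y, X and the genotypes are rotated onto the spectral axis, where
the covariance is diagonal and the restricted likelihood profile over
δ = σ²_e/σ²_g reduces to a cheap one-dimensional optimization.

Per-variant tests hold δ fixed at the null-model optimum ("population
parameters previously determined", the EMMAX/FaST-LMM approximation) and
compute a Wald 1-d.f. statistic by generalized least squares in the
rotated space; p-values come from the asymptotic χ²(1) null.  The tested
variant is *not* excluded from the GRM (proximal contamination), which
mirrors passing the same marker set to the association and the
similarity matrix and costs a small amount of power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

from .population import GenotypePanel
from .traits import standardized_genotypes

logger = logging.getLogger(__name__)

_LOG_DELTA_RANGE = (-10.0, 10.0)  # natural log of delta
_DELTA_XATOL = 1e-6
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Symmetric PSD sample × sample genetic relationship matrix."""

    matrix: np.ndarray
    sample_ids: list[str]

    def validate(self, tol: float = 1e-6) -> None:
        K = self.matrix
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.sample_ids):
            raise ValueError("kinship matrix shape mismatch")
        if not np.isfinite(K).all():
            raise ValueError("kinship matrix contains non-finite entries")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        w = linalg.eigvalsh(K)
        if w.min() < -tol * max(1.0, w.max()):
            raise ValueError("kinship matrix is not positive semi-definite")


@dataclass
class NullModelFit:
    """REML variance components of the no-marker (null) mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    h2_est: float
    eigenvalues: np.ndarray = field(repr=False, default=None)
    rotation: np.ndarray = field(repr=False, default=None)
    rotated_y: np.ndarray = field(repr=False, default=None)
    rotated_X: np.ndarray = field(repr=False, default=None)
    boundary: bool = False


@dataclass
class AssociationResult:
    """Per-variant mixed-model test statistics and p-values."""

    statistics: np.ndarray
    p_values: np.ndarray
    null_fit: NullModelFit
    variants: pd.DataFrame
    collinear: np.ndarray = field(repr=False, default=None)

    def to_frame(self, sort: bool = True) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.variants["chrom"].to_numpy(),
            "pos": self.variants["pos"].to_numpy(),
            "variant_index": np.arange(len(self.statistics)),
            "statistic": self.statistics,
            "p_value": self.p_values,
        })
        return df.sort_values("p_value", kind="stable",
                              ignore_index=True) if sort else df


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def compute_grm(panel: GenotypePanel) -> KinshipMatrix:
    """K = W Wᵀ / m with W the standardized (mean-imputed) genotypes.

    The panel must be filtered first: a monomorphic variant raises.
    The mean of the diagonal is ≈ 1 by construction.
    """
    if panel.n_variants < 2:
        raise ValueError("need at least 2 variants to build a GRM")
    W = standardized_genotypes(panel)
    K = (W @ W.T) / panel.n_variants
    return KinshipMatrix(matrix=K, sample_ids=list(panel.sample_ids))


# ---------------------------------------------------------------------------
# Restricted likelihood on the spectral axis
# ---------------------------------------------------------------------------


def reml_loglik(delta: float, eigenvalues: np.ndarray,
                rotated_y: np.ndarray, rotated_X: np.ndarray) -> float:
    """Profiled restricted log-likelihood at variance ratio ``delta``.

    σ²_g is profiled out analytically; the value equals the dense-matrix
    restricted likelihood of y ~ N(Xβ, σ²_g(K + δI)) at its σ̂²_g, β̂.
    """
    lam = eigenvalues
    w = 1.0 / (lam + delta)
    X = rotated_X
    n, p = X.shape
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * rotated_y)
    beta = linalg.solve(XtWX, XtWy, assume_a="pos")
    rss = float(w @ rotated_y**2 - XtWy @ beta)
    dof = n - p
    sigma_g2 = rss / dof
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (dof * np.log(2.0 * np.pi * sigma_g2)
                   + float(np.sum(np.log(lam + delta)))
                   + logdet_xwx - logdet_xx + dof)


def _fit_delta(eigenvalues: np.ndarray, rotated_y: np.ndarray,
               rotated_X: np.ndarray):
    """Maximize the restricted likelihood over log δ (grid + Brent)."""
    lo, hi = _LOG_DELTA_RANGE

    def negll(x: float) -> float:
        return -reml_loglik(np.exp(x), eigenvalues, rotated_y, rotated_X)

    grid = np.linspace(lo, hi, 41)
    vals = np.array([negll(x) for x in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(negll, bounds=(a, b), method="bounded",
                                   options={"xatol": _DELTA_XATOL})
    x_opt, ll = (res.x, -res.fun) if res.fun <= vals[i] \
        else (grid[i], -vals[i])
    boundary = x_opt <= lo + 1e-3 or x_opt >= hi - 1e-3
    return float(x_opt), float(ll), boundary


def _null_fit_from_rotated(eigenvalues, U, rotated_y,
                           rotated_X) -> NullModelFit:
    x_opt, ll, boundary = _fit_delta(eigenvalues, rotated_y, rotated_X)
    delta = float(np.exp(x_opt))
    n, p = rotated_X.shape
    w = 1.0 / (eigenvalues + delta)
    XtWX = rotated_X.T @ (w[:, None] * rotated_X)
    XtWy = rotated_X.T @ (w * rotated_y)
    beta = linalg.solve(XtWX, XtWy, assume_a="pos")
    rss = float(w @ rotated_y**2 - XtWy @ beta)
    sigma_g2 = rss / (n - p)
    sigma_e2 = delta * sigma_g2
    h2 = float(np.clip(1.0 / (1.0 + delta), 0.0, 1.0))
    if boundary:
        logger.debug("REML optimum at the delta boundary (log delta=%.2f);"
                     " h2 estimate clamped to %.3g", x_opt, h2)
    return NullModelFit(sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
                        reml_loglik=ll, h2_est=h2,
                        eigenvalues=eigenvalues, rotation=U,
                        rotated_y=rotated_y, rotated_X=rotated_X,
                        boundary=boundary)


def fit_null_reml(phenotype: np.ndarray, kinship: KinshipMatrix,
                  covariates: np.ndarray | None = None) -> NullModelFit:
    """Fit the null mixed model by REML via one spectral decomposition.

    ``covariates`` defaults to an intercept-only design.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    K = kinship.matrix if isinstance(kinship, KinshipMatrix) else \
        np.asarray(kinship, dtype=np.float64)
    lam, U = linalg.eigh(K)
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    X = np.ones((n, 1)) if covariates is None else \
        np.asarray(covariates, dtype=np.float64).reshape(n, -1)
    return _null_fit_from_rotated(lam, U, U.T @ y, U.T @ X)


def estimate_h2(null_fit: NullModelFit) -> float:
    """Genome-wide heritability: σ²_g / (σ²_g + σ²_e)."""
    total = null_fit.sigma_g2 + null_fit.sigma_e2
    if total <= 0:
        raise ValueError("both variance components are zero; heritability "
                         "undefined")
    return float(null_fit.sigma_g2 / total)


# ---------------------------------------------------------------------------
# Association engine
# ---------------------------------------------------------------------------


class AssociationEngine:
    """Cached spectral machinery for repeated scans on one panel.

    Eigendecomposes the GRM once and keeps the rotated genotype matrix,
    so that each additional phenotype (or permutation) costs one matrix-
    vector product per variant.
    """

    def __init__(self, panel: GenotypePanel,
                 kinship: KinshipMatrix | None = None):
        self.panel = panel
        if kinship is None:
            kinship = compute_grm(panel)
        if isinstance(kinship, KinshipMatrix):
            K = kinship.matrix
        else:
            K = np.asarray(kinship, dtype=np.float64)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        lam, U = linalg.eigh(K)
        if lam.min() < -1e-6 * max(1.0, lam.max()):
            raise ValueError("kinship matrix is not positive semi-definite")
        self.eigenvalues = np.clip(lam, 0.0, None)
        self.rotation = U
        G = _mean_imputed_calls(panel)
        self.rotated_G = U.T @ G
        self._rotated_G_sq = self.rotated_G**2
        self.rotated_intercept = U.T @ np.ones(panel.n_samples)

    @property
    def n_samples(self) -> int:
        return self.panel.n_samples

    def fit_null(self, phenotype: np.ndarray) -> NullModelFit:
        y = np.asarray(phenotype, dtype=np.float64)
        if np.var(y) == 0:
            raise ValueError("phenotype has zero variance")
        return _null_fit_from_rotated(
            self.eigenvalues, self.rotation, self.rotation.T @ y,
            self.rotated_intercept[:, None])

    # -- scan ---------------------------------------------------------------

    def scan_statistics(self, phenotypes: np.ndarray,
                        delta: float) -> np.ndarray:
        """Wald χ²(1) statistics, variants × phenotype-columns.

        ``phenotypes`` is (n,) or (n, r); δ is held fixed.  A variant
        collinear with the intercept in the rotated space gets 0.
        """
        Y = np.asarray(phenotypes, dtype=np.float64)
        squeeze = Y.ndim == 1
        Y = Y.reshape(self.n_samples, -1)
        n = self.n_samples
        w = np.ones(n) if np.isinf(delta) else \
            1.0 / (self.eigenvalues + delta)
        u = self.rotated_intercept
        RY = self.rotation.T @ Y
        WY = w[:, None] * RY
        suu = float(w @ u**2)
        sug = self.rotated_G.T @ (w * u)              # (m,)
        sgg = self._rotated_G_sq.T @ w                # (m,)
        suy = u @ WY                                  # (r,)
        syy = np.einsum("ir,ir->r", RY, WY)           # (r,)
        sgy = self.rotated_G.T @ WY                   # (m, r)

        D = suu * sgg - sug**2
        bad = D <= 1e-12 * np.maximum(suu * sgg, 1e-300)
        Dsafe = np.where(bad, 1.0, D)
        b = (suu * sgy - sug[:, None] * suy[None, :]) / Dsafe[:, None]
        beta0 = (sgg[:, None] * suy[None, :]
                 - sug[:, None] * sgy) / Dsafe[:, None]
        rss = syy[None, :] - beta0 * suy[None, :] - b * sgy
        # relative floor: cancellation can drive rss slightly negative
        sigma2 = np.maximum(rss, 1e-12 * syy[None, :]) / (n - 2)
        stat = b**2 * Dsafe[:, None] / (suu * sigma2)
        stat[bad, :] = 0.0
        stat = np.clip(stat, 0.0, None)
        return stat[:, 0] if squeeze else stat

    def scan(self, phenotype: np.ndarray,
             null_fit: NullModelFit | None = None,
             delta: float | None = None) -> AssociationResult:
        if delta is None:
            if null_fit is None:
                null_fit = self.fit_null(phenotype)
            delta = null_fit.delta
        stats = self.scan_statistics(phenotype, delta)
        pvals = np.maximum(chi2.sf(stats, df=1), _P_FLOOR)
        collinear = stats == 0.0  # degenerate fits carry p = 1 and a flag
        return AssociationResult(statistics=stats, p_values=pvals,
                                 null_fit=null_fit,
                                 variants=self.panel.variants,
                                 collinear=collinear)


def _mean_imputed_calls(panel: GenotypePanel) -> np.ndarray:
    from .population import MISSING
    X = panel.calls.astype(np.float64)
    missing = panel.calls == MISSING
    if missing.any():
        n_obs = (~missing).sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError("variant with no observed calls")
        mean = np.where(missing, 0.0, X).sum(axis=0) / n_obs
        X = np.where(missing, mean[None, :], X)
    return X


def association_scan(panel: GenotypePanel, phenotype: np.ndarray,
                     kinship: KinshipMatrix | None = None,
                     null_fit: NullModelFit | None = None
                     ) -> AssociationResult:
    """One-shot mixed-model scan: GRM → REML null fit → per-variant test.

    For repeated scans on the same panel, build an
    :class:`AssociationEngine` once and reuse it.
    """
    engine = AssociationEngine(panel, kinship)
    return engine.scan(np.asarray(phenotype, dtype=np.float64),
                       null_fit=null_fit)


def write_association(result: AssociationResult, path: str) -> None:
    """Verbose per-variant results table plus a null-model summary block."""
    nf = result.null_fit
    with open(path, "w") as fh:
        fh.write(f"# sigma_g2 = {nf.sigma_g2:.6g}\n"
                 f"# sigma_e2 = {nf.sigma_e2:.6g}\n"
                 f"# h2_est = {nf.h2_est:.6g}\n")
        result.to_frame().to_csv(fh, sep="\t", index=False)
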