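"""EMMA-style linear mixed-model association for inbred populations.

The model is ``y = mu + x beta + u + e`` with ``Var(u) = sigma_g^2 K`` and
``Var(e) = sigma_e^2 I``; with one phenotype record per inbred line the
incidence matrix is the identity.  Variance components are estimated once on
the null model (no marker) by REML over the variance ratio
``delta = sigma_e^2 / sigma_g^2`` using the spectral decomposition of the
kinship matrix; each marker is then tested by generalized least squares with
the ratio held fixed (the EMMAX approximation).  Samples missing a marker's
genotype are excluded from that marker's test, with the reduced-covariance
Cholesky factor cached per missingness pattern.

Genome-wide thresholds come from Bonferroni correction and from permutation
tests: the phenotype vector is permuted against the sample labels (which
preserves marker LD), the genome-wide minimum p-value recorded per
permutation, and the threshold set at the lower alpha-quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from varsync.encoder import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_bn(
    gm: GenotypeMatrix | np.ndarray, flavor: str = "bn"
) -> pd.DataFrame:
    """Kinship matrix from a SNP genotype matrix.

    ``bn`` is the Balding-Nichols allele-frequency-standardized estimator
    K[i,j] = mean_l (g_il - p_l)(g_jl - p_l) / (p_l (1 - p_l)) over markers
    where both samples are called, adjusted to be positive semidefinite.
    ``ibs`` is the identity-by-state fraction and ``identity`` the identity
    matrix (no structure correction).
    """
    if isinstance(gm, GenotypeMatrix):
        samples = list(gm.samples)
        vals = gm.values.astype(float)
    else:
        vals = np.asarray(gm, dtype=float)
        samples = [f"s{i}" for i in range(vals.shape[0])]
    n = vals.shape[0]
    if n < 2:
        raise ValueError("kinship needs at least two samples")
    if flavor == "identity":
        return pd.DataFrame(np.eye(n), index=samples, columns=samples)
    mask = vals != MISSING
    x = np.where(mask, vals, np.nan)
    if flavor == "ibs":
        m = mask.astype(float)
        same = np.zeros((n, n))
        tot = m @ m.T
        filled = np.where(mask, vals, -9)
        for i in range(n):
            same[i] = ((filled == filled[i]) & mask & mask[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(tot > 0, same / np.maximum(tot, 1), 0.0)
        np.fill_diagonal(k, 1.0)
        return pd.DataFrame(k, index=samples, columns=samples)
    if flavor != "bn":
        raise ValueError(f"unknown kinship flavor {flavor!r}")
    p = np.nanmean(x, axis=0)
    ok = (p > 0) & (p < 1)
    if not ok.any():
        raise ValueError("no polymorphic markers for kinship estimation")
    x = x[:, ok]
    p = p[ok]
    z = (x - p) / np.sqrt(p * (1.0 - p))
    z0 = np.nan_to_num(z)
    m = (~np.isnan(z)).astype(float)
    num = z0 @ z0.T
    den = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    k = (k + k.T) / 2.0
    w = np.linalg.eigvalsh(k)
    if w[0] < 0:
        k += (abs(w[0]) + 1e-9) * np.eye(n)
    return pd.DataFrame(k, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


@dataclass
class EmmaNullResults:
    """Variance components of the null mixed model plus a spectral cache."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    reml: bool
    n: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    y: np.ndarray
    X: np.ndarray
    K: np.ndarray

    @property
    def heritability(self) -> float:
        """Proportion of variance attributed to the random genetic effect."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    def summary(self) -> str:
        lines = [
            "EMMA null model (REML)" if self.reml else "EMMA null model (ML)",
            f"  n                : {self.n}",
            f"  sigma_g^2        : {self.sigma_g2:.6g}",
            f"  sigma_e^2        : {self.sigma_e2:.6g}",
            f"  delta (e/g)      : {self.delta:.6g}",
            f"  pseudo-h^2       : {self.heritability:.4f}",
            f"  log-likelihood   : {self.loglik:.6g}",
        ]
        return "\n".join(lines)


class EmmaNull:
    """Null mixed model ``y = X b + u + e`` with ``Var(u) = sigma_g^2 K``.

    ``fit`` profiles the ratio ``delta = sigma_e^2/sigma_g^2`` on a log grid
    (100 points over ln delta in [-10, 10]) refined by bounded minimisation,
    by default under REML.
    """

    def __init__(self, y: np.ndarray, K: np.ndarray | pd.DataFrame, X: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float)
        self.K = np.asarray(K, dtype=float)
        n = len(self.y)
        if n < 3:
            raise ValueError("need at least 3 samples")
        if self.K.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if np.ptp(self.y) == 0:
            raise ValueError("phenotype has zero variance")
        self.X = np.column_stack([np.ones(n)] + ([] if X is None else [np.asarray(X, float)]))

    def _neg_ll(self, log_delta: float, w: np.ndarray, yt: np.ndarray, Xt: np.ndarray, reml: bool):
        delta = np.exp(log_delta)
        v = w + delta
        n, q = Xt.shape
        XtW = Xt / v[:, None]
        xtx = XtW.T @ Xt
        beta = np.linalg.solve(xtx, XtW.T @ yt)
        resid = yt - Xt @ beta
        rss = float(resid @ (resid / v))
        if reml:
            df = n - q
            sig = rss / df
            _, ld1 = np.linalg.slogdet(xtx)
            _, ld0 = np.linalg.slogdet(Xt.T @ Xt)
            ll = -0.5 * (df * np.log(2 * np.pi * sig) + np.log(v).sum() + df + ld1 - ld0)
        else:
            sig = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * sig) + np.log(v).sum() + n)
        return -ll, sig, beta

    def fit(self, reml: bool = True, ngrid: int = 100) -> EmmaNullResults:
        w, U = np.linalg.eigh(self.K)
        w = np.clip(w, 0.0, None)
        yt = U.T @ self.y
        Xt = U.T @ self.X
        grid = np.linspace(-10.0, 10.0, ngrid)
        nll = np.array([self._neg_ll(g, w, yt, Xt, reml)[0] for g in grid])
        k = int(np.argmin(nll))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, ngrid - 1)]
        res = optimize.minimize_scalar(
            lambda g: self._neg_ll(g, w, yt, Xt, reml)[0],
            bounds=(lo, hi),
            method="bounded",
        )
        log_delta = float(res.x) if res.fun <= nll[k] else float(grid[k])
        neg, sig_g2, _ = self._neg_ll(log_delta, w, yt, Xt, reml)
        delta = float(np.exp(log_delta))
        return EmmaNullResults(
            sigma_g2=float(sig_g2),
            sigma_e2=float(sig_g2 * delta),
            delta=delta,
            loglik=-neg,
            reml=reml,
            n=len(self.y),
            eigenvalues=w,
            eigenvectors=U,
            y=self.y,
            X=self.X,
            K=self.K,
        )


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSet:
    bonferroni_p: float
    permutation_p: float
    n_tests: int
    n_permutations: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "bonferroni_p": self.bonferroni_p,
            "permutation_p": self.permutation_p,
            "n_tests": self.n_tests,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
        }


@dataclass
class AssociationResults:
    """Per-marker mixed-model association results for one variant class."""

    table: pd.DataFrame  # marker, kind, n_used, beta, se, statistic, p
    null: EmmaNullResults
    model: "AssociationScan"
    thresholds_: ThresholdSet | None = None

    def summary(self, top: int = 10) -> str:
        t = self.table.dropna(subset=["p"]).sort_values("p")
        lines = [
            "Mixed-model association scan",
            f"  markers tested   : {int(self.table.p.notna().sum())} of {len(self.table)}",
            f"  delta (null)     : {self.null.delta:.4g}",
        ]
        if self.thresholds_ is not None:
            lines.append(f"  bonferroni p     : {self.thresholds_.bonferroni_p:.3g}")
            lines.append(f"  permutation p    : {self.thresholds_.permutation_p:.3g}")
        lines.append("  top associations:")
        for r in t.head(top).itertuples():
            lines.append(
                f"    {r.marker:<24} beta={r.beta:+.4f} se={r.se:.4f} p={r.p:.3g}"
            )
        return "\n".join(lines)

    def thresholds(
        self,
        alpha: float = 0.05,
        n_perm: int = 1000,
        seed: int | None = None,
        n_tests: int | None = None,
    ) -> ThresholdSet:
        ts = self.model.permutation_thresholds(alpha, n_perm, seed, n_tests)
        self.thresholds_ = ts
        return ts


class AssociationScan:
    """Single-marker mixed-model scan over one genotype matrix.

    Parameters
    ----------
    y : phenotype vector (one value per sample in ``samples``).
    genotypes : GenotypeMatrix or samples x markers array with -1 missing.
    K : kinship matrix aligned with the samples.
    covariates : optional fixed-effect columns (no intercept).
    """

    def __init__(
        self,
        y: np.ndarray | pd.Series,
        genotypes: GenotypeMatrix | np.ndarray,
        K: np.ndarray | pd.DataFrame,
        covariates: np.ndarray | None = None,
        marker_names: list[str] | None = None,
        marker_kinds: list[str] | None = None,
    ):
        if isinstance(genotypes, GenotypeMatrix):
            self.G = genotypes.values.astype(float)
            if marker_names is None:
                marker_names = [
                    f"{r.chrom}:{r.pos}:{r.kind}:{r.length}"
                    for r in genotypes.markers.itertuples()
                ]
            if marker_kinds is None:
                marker_kinds = list(genotypes.markers.kind)
            self.samples = list(genotypes.samples)
        else:
            self.G = np.asarray(genotypes, dtype=float)
            self.samples = [f"s{i}" for i in range(self.G.shape[0])]
        if isinstance(y, pd.Series):
            y = y.reindex(self.samples).values
        self.y = np.asarray(y, dtype=float)
        self.K = np.asarray(K, dtype=float)
        self.covariates = None if covariates is None else np.asarray(covariates, float)
        n, L = self.G.shape
        self.marker_names = marker_names or [f"m{j}" for j in range(L)]
        self.marker_kinds = marker_kinds or ["marker"] * L
        if len(self.y) != n or self.K.shape != (n, n):
            raise ValueError("inconsistent shapes between y, genotypes and K")
        self._chol_cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    # -- helpers ------------------------------------------------------------

    def _base_X(self, idx: np.ndarray) -> np.ndarray:
        cols = [np.ones(idx.sum())]
        if self.covariates is not None:
            cov = self.covariates[idx]
            if cov.ndim == 1:
                cov = cov[:, None]
            cols.append(cov)
        return np.column_stack(cols)

    def _chol_for_pattern(self, idx: np.ndarray, delta: float):
        key = idx.tobytes()
        hit = self._chol_cache.get(key)
        if hit is None:
            V = self.K[np.ix_(idx, idx)] + delta * np.eye(int(idx.sum()))
            c, low = linalg.cho_factor(V, lower=True)
            hit = (c, low)
            self._chol_cache[key] = hit
        return hit

    def _gls_t_test(self, g: np.ndarray, idx: np.ndarray, delta: float):
        """GLS t-test of the marker coefficient on the non-missing subset."""
        c = self._chol_for_pattern(idx, delta)
        X = np.column_stack([self._base_X(idx), g])
        yv = self.y[idx]
        Xs = linalg.cho_solve(c, X)
        ys = linalg.cho_solve(c, yv)
        xtx = X.T @ Xs
        xty = X.T @ ys
        beta = np.linalg.solve(xtx, xty)
        resid = yv - X @ beta
        rss = float(resid @ linalg.cho_solve(c, resid))
        nu, q = X.shape
        df = nu - q
        if df <= 0:
            return np.nan, np.nan, np.nan, np.nan
        sigma2 = rss / df
        cov = sigma2 * np.linalg.inv(xtx)
        se = float(np.sqrt(cov[-1, -1]))
        b = float(beta[-1])
        tstat = b / se if se > 0 else np.nan
        p = float(2.0 * stats.t.sf(abs(tstat), df)) if np.isfinite(tstat) else np.nan
        return b, se, tstat, p

    # -- fitting ------------------------------------------------------------

    def fit(self, reml: bool = True) -> AssociationResults:
        """Estimate null variance components, then test every marker."""
        null = EmmaNull(self.y, self.K, X=self.covariates).fit(reml=reml)
        self.null_ = null
        delta = null.delta
        rows = []
        for j in range(self.G.shape[1]):
            g = self.G[:, j]
            idx = g != MISSING
            gv = g[idx]
            n_used = int(idx.sum())
            if n_used < 3 or np.ptp(gv) == 0:
                rows.append(
                    (self.marker_names[j], self.marker_kinds[j], n_used,
                     np.nan, np.nan, np.nan, np.nan)
                )
                continue
            b, se, tstat, p = self._gls_t_test(gv, idx, delta)
            rows.append(
                (self.marker_names[j], self.marker_kinds[j], n_used, b, se, tstat, p)
            )
        table = pd.DataFrame(
            rows, columns=["marker", "kind", "n_used", "beta", "se", "statistic", "p"]
        )
        return AssociationResults(table, null, self)

    # -- permutation thresholds ---------------------------------------------

    def _fast_min_p(self, y_perm: np.ndarray, U, w, delta, G_imp, keep) -> float:
        """Minimum p over complete (mean-imputed) markers for one phenotype,
        via closed-form weighted regression in the rotated basis."""
        v = 1.0 / (w + delta)
        yt = U.T @ y_perm
        ones_t = self._ones_t
        a = float((ones_t * ones_t * v).sum())
        d = float((ones_t * yt * v).sum())
        f = float((yt * yt * v).sum())
        Gt = G_imp
        b = (Gt * (ones_t * v)[:, None]).sum(axis=0)
        c = (Gt * Gt * v[:, None]).sum(axis=0)
        e = (Gt * (yt * v)[:, None]).sum(axis=0)
        denom = a * c - b * b
        ok = keep & (denom > 1e-12)
        beta1 = np.where(ok, (a * e - b * d) / np.where(ok, denom, 1.0), 0.0)
        beta0 = (d - b * beta1) / a
        rss = f - beta0 * d - beta1 * e
        n = len(y_perm)
        df = n - 2
        sigma2 = np.maximum(rss, 1e-300) / df
        var1 = sigma2 * a / np.where(ok, denom, 1.0)
        tstat = np.where(ok, np.abs(beta1) / np.sqrt(np.maximum(var1, 1e-300)), 0.0)
        tmax = float(tstat.max()) if len(tstat) else 0.0
        return float(2.0 * stats.t.sf(tmax, df))

    def permutation_thresholds(
        self,
        alpha: float = 0.05,
        n_perm: int = 1000,
        seed: int | None = None,
        n_tests: int | None = None,
    ) -> ThresholdSet:
        """Bonferroni plus permutation genome-wide thresholds.

        For the permutation scan, missing genotypes are mean-imputed so all
        markers can be screened with one rotated weighted regression per
        permutation; the reported per-marker tests are unaffected.
        """
        if n_perm < 20:
            import warnings

            warnings.warn("fewer than 20 permutations gives a crude threshold")
        if not hasattr(self, "null_"):
            self.fit()
        null = self.null_
        delta = null.delta
        U, w = null.eigenvectors, null.eigenvalues
        G = self.G.copy()
        missing = G == MISSING
        keep = np.ptp(np.where(missing, np.nan, G), axis=0) > 0
        keep &= ~np.all(missing, axis=0)
        col_mean = np.nanmean(np.where(missing, np.nan, G), axis=0)
        G[missing] = np.take(col_mean, np.nonzero(missing)[1])
        Gt = U.T @ G
        self._ones_t = U.T @ np.ones(len(self.y))
        if n_tests is None:
            n_tests = int(keep.sum())
        rng = np.random.default_rng(seed)
        minp = np.empty(n_perm)
        for r in range(n_perm):
            yp = rng.permutation(self.y)
            minp[r] = self._fast_min_p(yp, U, w, delta, Gt, keep)
        perm_p = float(np.quantile(minp, alpha))
        return ThresholdSet(
            bonferroni_p=alpha / max(n_tests, 1),
            permutation_p=perm_p,
            n_tests=n_tests,
            n_permutations=n_perm,
            alpha=alpha,
        )
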