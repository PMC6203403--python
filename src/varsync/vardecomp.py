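"""Phenotypic variance decomposition across variant classes.

Genome-wide significant SNPs are added as fixed effects to the mixed model
first; significant INDELs and then ORFS markers follow, so the extra
variance each class explains on top of the previous ones can be read off:

    h2_S   = 1 - sum (y - yhat_S)^2   / sum (y - ybar)^2
    h2_S+I = 1 - sum (y - yhat_S+I)^2 / sum (y - ybar)^2
    h2_I   = h2_S+I - h2_S            (extra variance from INDELs)
    h2_O   = h2_S+I+O - h2_S+I        (extra variance from ORFS burden)

with the fixed-effect coefficients estimated by generalized least squares
under the null-model variance components, and the fitted values excluding
the random effect.  Because significant markers are often correlated, each
candidate enters only if a marginal F-test on the residual sums of squares
of the nested fixed-effect models (in the rotated, whitened basis) gives
p < 1e-4; candidates are offered within each class in ascending association
p-value, and perfectly collinear columns are skipped outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from varsync.encoder import MISSING
from varsync.lmm import EmmaNull, EmmaNullResults

CLASS_ORDER = ("snp", "indel", "orfs")


def h2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Proportion of phenotypic variance explained by fitted values."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    denom = float(((y - y.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("phenotype has zero variance")
    return 1.0 - float(((y - yhat) ** 2).sum()) / denom


def fitted_fixed(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    null: EmmaNullResults | None = None,
) -> np.ndarray:
    """Fixed-effect fitted values ``mu + X beta`` under the mixed model.

    beta is the GLS estimate with covariance sigma_g^2 (K + delta I); the
    random effect is excluded from the fit, as the decomposition requires.
    """
    y = np.asarray(y, float)
    n = len(y)
    if null is None:
        null = EmmaNull(y, K).fit()
    X = np.ones((n, 1)) if covariates is None or covariates.size == 0 else np.column_stack(
        [np.ones(n), covariates]
    )
    w, U = null.eigenvalues, null.eigenvectors
    v = w + null.delta
    Xt = U.T @ X
    yt = U.T @ y
    XtW = Xt / v[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    return X @ beta


@dataclass
class SelectedCovariate:
    name: str
    var_class: str
    assoc_p: float
    f_p: float


@dataclass
class DecompositionResults:
    """Variance shares per variant class with the selected covariates."""

    h2_S: float
    h2_SI: float
    h2_SIO: float
    h2_I: float
    h2_O: float
    selected: list[SelectedCovariate]
    null: EmmaNullResults
    n: int

    def to_dict(self) -> dict:
        return {
            "h2_S": self.h2_S,
            "h2_SI": self.h2_SI,
            "h2_SIO": self.h2_SIO,
            "h2_I": self.h2_I,
            "h2_O": self.h2_O,
            "n_selected": len(self.selected),
        }

    def selected_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.var_class, s.assoc_p, s.f_p) for s in self.selected],
            columns=["marker", "class", "assoc_p", "marginal_f_p"],
        )

    def summary(self) -> str:
        lines = [
            "Variance decomposition (marginal F-test selection)",
            f"  n                      : {self.n}",
            f"  h2 (SNP)               : {self.h2_S:.4f}",
            f"  h2 (SNP+INDEL)         : {self.h2_SI:.4f}",
            f"  h2 (SNP+INDEL+ORFS)    : {self.h2_SIO:.4f}",
            f"  extra from INDELs      : {self.h2_I:.4f}",
            f"  extra from ORFS burden : {self.h2_O:.4f}",
            f"  covariates selected    : {len(self.selected)}",
        ]
        for s in self.selected:
            lines.append(f"    [{s.var_class}] {s.name}  F-test p={s.f_p:.3g}")
        return "\n".join(lines)


class VarianceDecomposition:
    """Forward-selection variance decomposition over SNP -> INDEL -> ORFS.

    Parameters
    ----------
    y : phenotype vector.
    K : kinship matrix.
    candidates : mapping of variant class ('snp', 'indel', 'orfs') to a
        DataFrame with one row per genome-wide significant marker and
        columns ``name``, ``p`` (association p-value), plus the genotype
        columns supplied separately in ``genotype_arrays`` (n x m per class).
        Missing genotypes (-1) are mean-imputed for the fixed-effect fits.
    """

    def __init__(
        self,
        y: np.ndarray,
        K: np.ndarray | pd.DataFrame,
        candidates: dict[str, tuple[np.ndarray, pd.DataFrame]],
    ):
        self.y = np.asarray(y, float)
        self.K = np.asarray(K, float)
        self.candidates = {}
        n = len(self.y)
        for cls, (G, meta) in candidates.items():
            G = np.asarray(G, float)
            if G.ndim == 1:
                G = G[:, None]
            if G.shape[0] != n:
                raise ValueError(f"{cls}: genotype rows != len(y)")
            if len(meta) != G.shape[1]:
                raise ValueError(f"{cls}: metadata rows != genotype columns")
            G = G.copy()
            miss = G == MISSING
            if miss.any():
                col_mean = np.where(
                    miss.all(axis=0), 0.0, np.nanmean(np.where(miss, np.nan, G), axis=0)
                )
                G[miss] = np.take(col_mean, np.nonzero(miss)[1])
            self.candidates[cls] = (G, meta.reset_index(drop=True))

    def _rotated_rss(self, Xt: np.ndarray, yt: np.ndarray, v: np.ndarray) -> float:
        XtW = Xt / v[:, None]
        beta = np.linalg.lstsq(XtW.T @ Xt, XtW.T @ yt, rcond=None)[0]
        resid = yt - Xt @ beta
        return float(resid @ (resid / v))

    def fit(self, p_threshold: float = 1e-4, reml: bool = True) -> DecompositionResults:
        y = self.y
        n = len(y)
        null = EmmaNull(y, self.K).fit(reml=reml)
        w, U = null.eigenvalues, null.eigenvectors
        v = w + null.delta
        yt = U.T @ y

        X_cols: list[np.ndarray] = []  # raw-space selected covariate columns
        selected: list[SelectedCovariate] = []
        h2_by_stage: dict[str, float] = {}

        def current_h2() -> float:
            cov = np.column_stack(X_cols) if X_cols else None
            yhat = fitted_fixed(y, cov, self.K, null=null)
            return h2(y, yhat)

        for cls in CLASS_ORDER:
            if cls in self.candidates:
                G, meta = self.candidates[cls]
                order = np.argsort(meta.p.values, kind="stable")
                for j in order:
                    g = G[:, j]
                    if np.ptp(g) == 0:
                        continue
                    # perfect collinearity with an already-selected covariate
                    redundant = False
                    for col in X_cols:
                        if np.ptp(col) == 0:
                            continue
                        r = np.corrcoef(col, g)[0, 1]
                        if abs(r) > 1.0 - 1e-12:
                            redundant = True
                            break
                    if redundant:
                        continue
                    X0 = np.column_stack([np.ones(n)] + X_cols)
                    X1 = np.column_stack([X0, g])
                    X0t, X1t = U.T @ X0, U.T @ X1
                    rss0 = self._rotated_rss(X0t, yt, v)
                    rss1 = self._rotated_rss(X1t, yt, v)
                    df2 = n - X1.shape[1]
                    if df2 <= 0 or rss1 <= 0:
                        continue
                    fstat = (rss0 - rss1) / (rss1 / df2)
                    f_p = float(stats.f.sf(max(fstat, 0.0), 1, df2))
                    if f_p < p_threshold:
                        X_cols.append(g.astype(float))
                        label = (
                            str(meta["name"].iloc[j]) if "name" in meta.columns else str(j)
                        )
                        selected.append(
                            SelectedCovariate(label, cls, float(meta.p.values[j]), f_p)
                        )
            h2_by_stage[cls] = current_h2()

        h2_S = h2_by_stage["snp"]
        h2_SI = h2_by_stage["indel"]
        h2_SIO = h2_by_stage["orfs"]
        clamped = False
        if h2_S < 0:
            h2_S, clamped = 0.0, True
        if h2_SI < h2_S:
            h2_SI, clamped = h2_S, True
        if h2_SIO < h2_SI:
            h2_SIO, clamped = h2_SI, True
        if clamped:
            warnings.warn("negative variance share clamped to preserve nesting")
        return DecompositionResults(
            h2_S=h2_S,
            h2_SI=h2_SI,
            h2_SIO=h2_SIO,
            h2_I=h2_SI - h2_S,
            h2_O=h2_SIO - h2_SI,
            selected=selected,
            null=null,
            n=n,
        )
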