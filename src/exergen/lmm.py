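"""Maximum-likelihood linear mixed model with an additive-genetic random effect.

The model for the phenotype vector y is

    y ~ N(X beta,  sigma2_a * A + sigma2_e * I)

where A is the additive genetic relationship matrix, block-diagonal by
family. Because A is block-diagonal, each family block is eigendecomposed
once; rotating y and X by the block eigenvectors diagonalizes the covariance,
so the likelihood is profiled over the single variance ratio
lambda = sigma2_a / sigma2_e with O(N) cost per evaluation. beta and sigma2_e
have closed-form GLS/ML solutions given lambda; lambda is found by bounded
1-D search on the log scale, with the boundary sigma2_a = 0 checked
explicitly.

Inference: per-coefficient two-sided Wald tests ((beta/se)^2 vs chi-square
with 1 df) and likelihood-ratio tests for nested model comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .pedigree import Pedigree, relationship_blocks


class ModelError(ValueError):
    """Rank-deficient design, non-nested comparison, or mismatched samples."""


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    alpha_used: Optional[float] = None

    @property
    def significant(self) -> Optional[bool]:
        return None if self.alpha_used is None else self.p_value < self.alpha_used


@dataclass
class LMMFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_a: float
    sigma2_e: float
    loglik: float
    n_used: int
    converged: bool
    sample_key: int = 0  # hash of the complete-case sample, for nesting checks

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)

    def coef(self, name: str) -> tuple[float, float]:
        if name not in self.names:
            raise ModelError(f"coefficient {name!r} not in model {self.names}")
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame({
            "coef": self.names,
            "estimate": self.beta,
            "se": self.se,
            "wald_chi2": z ** 2,
            "p_value": stats.chi2.sf(z ** 2, df=1),
        })


class KinshipTransform:
    """Block eigendecomposition of a relationship matrix.

    Stores the orthogonal block-diagonal eigenvector matrix (sparse) and the
    concatenated eigenvalues; ``rotate`` maps vectors into the basis in which
    the covariance sigma2_e * (lambda * A + I) is diagonal with weights
    lambda * d + 1.
    """

    def __init__(self, blocks: Sequence[tuple[np.ndarray, np.ndarray]], n: int):
        rows, cols, vals = [], [], []
        d = np.empty(n)
        offset = 0
        cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
        covered = 0
        for positions, A in blocks:
            k = len(positions)
            key = np.round(A, 10).tobytes()
            if key not in cache:
                cache[key] = np.linalg.eigh(A)
            w, U = cache[key]
            d[offset:offset + k] = np.clip(w, 0.0, None)
            rows.append(np.repeat(positions, k))
            cols.append(np.tile(np.arange(offset, offset + k), k))
            vals.append(U.ravel())
            offset += k
            covered += k
        if covered != n:
            raise ModelError("relationship blocks do not cover the sample")
        self.n = n
        self.d = d
        self._U = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self._Ut = self._U.T.tocsr()

    @classmethod
    def from_pedigree(cls, pedigree: Pedigree, ids: Sequence[str]) -> "KinshipTransform":
        return cls(relationship_blocks(pedigree, ids), len(ids))

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self._Ut @ v


def _profile(lam: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profiled ML pieces at a fixed variance ratio lambda."""
    n, p = Xt.shape
    iw = 1.0 / (1.0 + lam * d)
    Xw = Xt * iw[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    try:
        np.linalg.cholesky(XtWX)  # SPD check: fails on rank-deficient designs
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise ModelError("design matrix is rank deficient") from exc
    resid = yt - Xt @ beta
    rss = float(resid @ (resid * iw))
    sigma2_e = rss / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_e) + n
                     - np.log(iw).sum())
    return loglik, beta, sigma2_e, XtWX


def fit_rotated(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray,
                names: Optional[Sequence[str]] = None,
                sample_key: int = 0,
                lam_bounds: tuple[float, float] = (1e-8, 1e4),
                xatol: float = 1e-8) -> LMMFit:
    """ML fit on already-rotated data (see :class:`KinshipTransform`)."""
    n, p = Xt.shape
    if n < p + 2:
        raise ModelError(f"{n} complete cases cannot support {p} fixed effects")

    def neg_ll(t: float) -> float:
        return -_profile(np.exp(t), yt, Xt, d)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(np.log(lam_bounds[0]), np.log(lam_bounds[1])),
        method="bounded", options={"xatol": xatol},
    )
    lam = float(np.exp(res.x))
    ll_hat = -float(res.fun)
    ll0 = _profile(0.0, yt, Xt, d)[0]
    # prefer the boundary sigma2_a = 0 whenever it is not distinguishably
    # worse (the ratio is unidentified when A = I, where loglik is flat)
    if ll0 >= ll_hat - 1e-9 * (1.0 + abs(ll_hat)):
        lam, ll_hat = 0.0, ll0
    loglik, beta, sigma2_e, XtWX = _profile(lam, yt, Xt, d)
    cov = sigma2_e * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    return LMMFit(
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        beta=beta, se=se,
        sigma2_a=lam * sigma2_e, sigma2_e=sigma2_e,
        loglik=float(loglik), n_used=n,
        converged=bool(res.success or lam == 0.0),
        sample_key=sample_key,
    )


def fit_lmm(y: np.ndarray, X: np.ndarray,
            transform: KinshipTransform,
            names: Optional[Sequence[str]] = None,
            sample_key: int = 0) -> LMMFit:
    """ML fit of y ~ N(X beta, sigma2_a A + sigma2_e I) via the rotated form."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != transform.n or X.shape[0] != transform.n:
        raise ModelError("data length does not match the kinship transform")
    return fit_rotated(transform.rotate(y), transform.rotate(X), transform.d,
                       names=names, sample_key=sample_key)


def fit(data: pd.DataFrame, pedigree: Pedigree,
        variants: Sequence[str] = (),
        covariates: Sequence[str] = ("sex", "age_z", "sex_x_age"),
        response: str = "weekly_met_hours",
        id_column: str = "individual_id") -> LMMFit:
    """Fit the association mixed model from an analysis table.

    Builds the fixed-effect design (intercept, covariates, variant codes) on
    the complete-case sample, derives ``age_z`` (z-scored age) and
    ``sex_x_age`` on that sample when requested and not supplied, and uses
    the additive relationship matrix of the pedigree restricted to the used
    individuals as the random-effect structure. Sex must be coded 0 = male,
    1 = female.
    """
    df = data.copy()
    base_needed = {response, *variants}
    for c in covariates:
        if c in ("age_z", "sex_x_age"):
            base_needed.add("age_z" if "age_z" in df.columns else "age")
            if c == "sex_x_age":
                base_needed.add("sex")
        else:
            base_needed.add(c)
    missing_cols = sorted(c for c in base_needed | {id_column} if c not in df.columns)
    if missing_cols:
        raise ModelError(f"analysis table lacks columns: {missing_cols}")
    df = df.dropna(subset=sorted(base_needed))
    if "age_z" in covariates and "age_z" not in df.columns:
        df["age_z"] = standardize_age(df["age"].to_numpy())
    if "sex_x_age" in covariates and "sex_x_age" not in df.columns:
        df["sex_x_age"] = df["sex"].to_numpy() * df["age_z"].to_numpy()
    names = ["intercept", *covariates, *variants]
    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(dtype=float) for c in (*covariates, *variants)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("design matrix is rank deficient after complete-case filtering")
    ids = df[id_column].tolist()
    transform = KinshipTransform.from_pedigree(pedigree, ids)
    key = hash(tuple(ids))
    return fit_lmm(df[response].to_numpy(dtype=float), X, transform,
                   names=names, sample_key=key)


def test_variant(fit_result: LMMFit, coefficient: str,
                 alpha: Optional[float] = None) -> TestResult:
    """Two-sided Wald test of one fixed-effect coefficient (chi-square, 1 df)."""
    b, se = fit_result.coef(coefficient)
    w = (b / se) ** 2
    return TestResult(statistic=float(w), df=1,
                      p_value=float(stats.chi2.sf(w, df=1)), alpha_used=alpha)


def joint_test(full_fit: LMMFit, null_fit: LMMFit,
               alpha: Optional[float] = None) -> TestResult:
    """Likelihood-ratio test of the terms added by the full model."""
    if not set(null_fit.names) <= set(full_fit.names):
        raise ModelError("null model is not nested in the full model")
    if full_fit.n_used != null_fit.n_used or full_fit.sample_key != null_fit.sample_key:
        raise ModelError("models were fitted on different complete-case samples")
    df_added = len(full_fit.names) - len(null_fit.names)
    stat = 2.0 * (full_fit.loglik - null_fit.loglik)
    if stat < -1e-6:
        raise ModelError("full-model likelihood below the null: optimizer failure")
    stat = max(stat, 0.0)
    if df_added == 0:  # degenerate comparison of a model with itself
        return TestResult(statistic=stat, df=0, p_value=1.0, alpha_used=alpha)
    return TestResult(statistic=float(stat), df=df_added,
                      p_value=float(stats.chi2.sf(stat, df=df_added)),
                      alpha_used=alpha)


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test alpha under Bonferroni correction for ``n_tests`` tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0.0 < family_alpha <= 1.0:
        raise ValueError("family_alpha must lie in (0, 1]")
    return family_alpha / n_tests


def standardize_age(ages: np.ndarray) -> np.ndarray:
    """Z-score ages on the analysis sample (n-1 denominator)."""
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages[~np.isnan(ages)]).size < 2:
        raise ValueError("age standardization requires >= 2 distinct ages")
    sd = np.nanstd(ages, ddof=1)
    return (ages - np.nanmean(ages)) / sd
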