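"""Per-feature linear modeling with empirical-Bayes variance moderation.

The experimental design is a 2 genotype (WT, KI) x 3 timepoint
(SED, T10, EXH) layout fit as a cell-means model: one indicator column
per genotype-timepoint combination, no intercept.  Per feature, the model
yields cell-mean estimates, a residual variance ``s^2`` and residual
degrees of freedom ``d``.  Residual variances are then shrunk toward a
common prior by empirical Bayes: assuming

    s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_d / d,
    1 / sigma_g^2 ~ chi^2_d0 / (d0 * s0^2),

the marginal distribution of ``s_g^2`` is a scaled F, and the prior
parameters ``(d0, s0^2)`` are recovered in closed form by matching the
first two moments of ``log s_g^2`` (trigamma inversion).  The posterior
variance is the precision-weighted blend

    s~^2 = (d0*s0^2 + d*s^2) / (d0 + d),

and the moderated t-statistic uses ``d0 + d`` degrees of freedom.
Optional per-sample quality weights down-weight noisy samples without
sacrificing degrees of freedom, and Benjamini-Hochberg adjustment is
applied separately to the exercise-vs-sedentary family of contrasts and
to all remaining contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import OmicsMatrix

GENOTYPES = ("WT", "KI")
TIMEPOINTS = ("SED", "T10", "EXH")
#: The six design cells, in canonical order.
DEFAULT_LEVELS = tuple(f"{g}.{t}" for g in GENOTYPES for t in TIMEPOINTS)

EXERCISE_FAMILY = "exercise_vs_sed"
OTHER_FAMILY = "other"


# ---------------------------------------------------------------------------
# design and contrasts


@dataclass
class DesignSpec:
    """Cell-means design: one indicator column per genotype x timepoint."""

    group_per_sample: pd.Series  # sample id -> level label
    levels: tuple[str, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        unknown = set(self.group_per_sample) - set(self.levels)
        if unknown:
            raise ValueError(f"samples mapped to unknown levels: {sorted(unknown)}")
        counts = self.group_per_sample.value_counts()
        empty = [lv for lv in self.levels if counts.get(lv, 0) == 0]
        if empty:
            raise ValueError(f"design levels with no samples: {empty}")

    @classmethod
    def from_matrix(cls, matrix: OmicsMatrix, levels: tuple[str, ...] = DEFAULT_LEVELS) -> "DesignSpec":
        return cls(matrix.group_labels(), levels)

    def matrix(self) -> pd.DataFrame:
        """Indicator design matrix (samples x levels), no intercept."""
        X = pd.DataFrame(
            0.0, index=self.group_per_sample.index, columns=list(self.levels)
        )
        for sample, level in self.group_per_sample.items():
            X.at[sample, level] = 1.0
        return X


@dataclass(frozen=True)
class ContrastSpec:
    """A named linear contrast over the design levels."""

    name: str
    coefficients: tuple[float, ...]
    family: str = OTHER_FAMILY

    def vector(self, levels: Sequence[str]) -> np.ndarray:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (len(levels),):
            raise ValueError(
                f"contrast {self.name!r} has {c.size} coefficients for {len(levels)} levels"
            )
        return c


def _coef(levels: Sequence[str], plus: list[str], minus: list[str]) -> tuple[float, ...]:
    c = np.zeros(len(levels))
    for lv in plus:
        c[list(levels).index(lv)] += 1.0
    for lv in minus:
        c[list(levels).index(lv)] -= 1.0
    return tuple(c)


def default_contrasts(levels: Sequence[str] = DEFAULT_LEVELS) -> list[ContrastSpec]:
    """The study's named contrasts with their FDR family tags."""
    return [
        ContrastSpec("KI.SED-WT.SED", _coef(levels, ["KI.SED"], ["WT.SED"]), OTHER_FAMILY),
        ContrastSpec("KI.T10-KI.SED", _coef(levels, ["KI.T10"], ["KI.SED"]), EXERCISE_FAMILY),
        ContrastSpec("WT.T10-WT.SED", _coef(levels, ["WT.T10"], ["WT.SED"]), EXERCISE_FAMILY),
        ContrastSpec("KI.EXH-KI.SED", _coef(levels, ["KI.EXH"], ["KI.SED"]), EXERCISE_FAMILY),
        ContrastSpec("WT.EXH-WT.SED", _coef(levels, ["WT.EXH"], ["WT.SED"]), EXERCISE_FAMILY),
        ContrastSpec(
            "(KI.EXH-KI.SED)-(WT.EXH-WT.SED)",
            tuple(
                np.array(_coef(levels, ["KI.EXH"], ["KI.SED"]))
                - np.array(_coef(levels, ["WT.EXH"], ["WT.SED"]))
            ),
            OTHER_FAMILY,
        ),
    ]


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class FitResult:
    """Per-feature weighted least-squares fit of the cell-means model."""

    beta: pd.DataFrame          # features x levels
    sigma2: pd.Series           # residual variance s^2 per feature
    df_residual: int            # d = n_samples - n_levels
    cov_unscaled: np.ndarray    # (X' W X)^-1, shared across features
    amean: pd.Series            # mean abundance per feature
    levels: tuple[str, ...]
    weights: pd.Series          # per-sample weights used in the fit


def fit_cell_means(
    matrix: OmicsMatrix,
    design: DesignSpec | None = None,
    weights: pd.Series | Mapping[str, float] | None = None,
) -> FitResult:
    """Fit the cell-means model to every feature by (weighted) least squares.

    With uniform weights each coefficient is simply that cell's sample
    mean; with weights the fit is per-feature weighted least squares with
    a design-shared hat structure (the design has no feature-specific
    covariates, so ``(X'WX)^{-1}`` is common to all features).
    """
    if matrix.has_missing():
        raise ValueError("fit requires a complete matrix")
    if design is None:
        design = DesignSpec.from_matrix(matrix)
    X = design.matrix().loc[matrix.sample_ids].to_numpy()  # n x p
    Y = matrix.values.to_numpy()                           # G x n
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} samples cannot estimate {p} cell means with residual df")

    if weights is None:
        w = np.ones(n)
    else:
        w = pd.Series(weights).loc[matrix.sample_ids].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("sample weights must be positive")

    XtWX = (X * w[:, None]).T @ X
    cov_unscaled = np.linalg.inv(XtWX)
    beta = Y @ (w[:, None] * X) @ cov_unscaled.T          # G x p
    resid = Y - beta @ X.T
    rss = (resid**2 * w).sum(axis=1)
    df_residual = n - p
    sigma2 = rss / df_residual

    return FitResult(
        beta=pd.DataFrame(beta, index=matrix.feature_ids, columns=list(design.levels)),
        sigma2=pd.Series(sigma2, index=matrix.feature_ids, name="sigma2"),
        df_residual=df_residual,
        cov_unscaled=cov_unscaled,
        amean=pd.Series(Y.mean(axis=1), index=matrix.feature_ids, name="amean"),
        levels=tuple(design.levels),
        weights=pd.Series(w, index=matrix.sample_ids, name="weight"),
    )


def estimate_sample_weights(
    matrix: OmicsMatrix,
    design: DesignSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> pd.Series:
    """Estimate per-sample quality weights (geometric mean 1).

    Iterates: (i) weighted cell-means fit, (ii) per-sample mean squared
    standardized residual ``m_j`` (residuals scaled by the feature's
    residual standard deviation and the leverage correction
    ``1 - h_jj``), (iii) ``w_j <- 1/m_j`` renormalized to geometric mean
    one, until the weights stabilize.  Samples whose residuals run
    systematically hot receive proportionally smaller weights, shrinking
    their influence on the fit without dropping them.
    """
    if design is None:
        design = DesignSpec.from_matrix(matrix)
    X = design.matrix().loc[matrix.sample_ids].to_numpy()
    n, p = X.shape
    if matrix.n_features < p:
        raise ValueError("need at least as many features as design columns")
    Y = matrix.values.to_numpy()
    w = np.ones(n)
    for _ in range(max_iter):
        XtWX = (X * w[:, None]).T @ X
        cov = np.linalg.inv(XtWX)
        beta = Y @ (w[:, None] * X) @ cov.T
        resid = Y - beta @ X.T
        # leverage of sample j in the weighted fit
        h = w * np.einsum("ij,jk,ik->i", X, cov, X)
        h = np.clip(h, None, 1 - 1e-8)
        rss = (resid**2 * w).sum(axis=1)
        s2 = rss / (n - p)
        ok = s2 > 0
        if not ok.any():
            raise ValueError("all features have zero residual variance")
        std2 = (resid[ok] ** 2) / s2[ok][:, None] / (1.0 - h)[None, :]
        m = np.clip(std2.mean(axis=0), 1e-12, None)
        w_new = 1.0 / m
        w_new /= np.exp(np.mean(np.log(w_new)))
        if np.max(np.abs(w_new - w) / w) < tol:
            w = w_new
            break
        w = w_new
    return pd.Series(w, index=matrix.sample_ids, name="weight")


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma_inverse(x: float, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


@dataclass
class ModeratedResult:
    """Empirical-Bayes shrunk variances and the prior they shrink toward."""

    d0: float                      # prior degrees of freedom (may be inf)
    s0_squared: pd.Series          # prior variance (constant or per-feature trend)
    sigma2_post: pd.Series         # posterior variances s~^2
    df_total: pd.Series            # d0 + d per feature (capped at 1e9 when d0=inf)


def moderate_variances(
    fit: FitResult,
    trend: bool = False,
    robust: bool = True,
    robust_mad_threshold: float = 4.0,
    d0_override: float | None = None,
) -> ModeratedResult:
    """Shrink residual variances toward a common (or trended) prior.

    ``(d0, s0^2)`` are estimated by closed-form moment matching on
    ``log s^2`` (trigamma inversion of the excess variance).  With
    ``robust=True``, features whose ``log s^2`` lies more than
    ``robust_mad_threshold`` MAD-standardized units from the median are
    excluded from the moment matching, so a handful of outlying features
    cannot inflate or deflate the prior.  With ``trend=True`` the prior
    variance becomes a lowess-smoothed function of mean abundance.
    ``d0_override`` bypasses the estimator (0 gives the unmoderated fit,
    ``inf`` full shrinkage to the prior).

    When the log-variances carry no excess spread beyond sampling noise
    the prior df is infinite and the prior variance is the geometric
    mean of the observed variances, so a constant variance vector is a
    fixed point of the shrinkage.
    """
    s2 = fit.sigma2.to_numpy(dtype=float)
    d = float(fit.df_residual)
    if s2.size < 2:
        raise ValueError("need at least 2 features to estimate the prior")
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all residual variances are zero")

    z = np.log(s2[positive])
    e = z - special.digamma(d / 2) + np.log(d / 2)

    etrend = None
    if trend:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        a = fit.amean.to_numpy(dtype=float)[positive]
        fitted = lowess(e, a, frac=0.5, return_sorted=False)
        etrend_all = np.interp(fit.amean.to_numpy(dtype=float), *_sorted_xy(a, fitted))
        etrend = fitted
        e_centered = e - fitted
    else:
        e_centered = e

    use = np.ones(e_centered.size, dtype=bool)
    if robust:
        med = np.median(e_centered)
        mad = 1.4826 * np.median(np.abs(e_centered - med))
        if mad > 0:
            use = np.abs(e_centered - med) <= robust_mad_threshold * mad

    emean = float(np.mean(e_centered[use]))
    evar = float(np.var(e_centered[use], ddof=1)) - float(special.polygamma(1, d / 2))

    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        offset = special.digamma(d0 / 2) - np.log(d0 / 2)
    else:
        # no excess spread: prior = geometric mean of the observed s^2
        d0 = np.inf
        offset = special.digamma(d / 2) - np.log(d / 2)

    if d0_override is not None:
        if d0_override < 0:
            raise ValueError("d0_override must be non-negative")
        d0 = float(d0_override)
        if np.isinf(d0):
            offset = special.digamma(d / 2) - np.log(d / 2)

    if trend:
        log_s0 = etrend_all + emean + offset
        s0_sq = pd.Series(np.exp(log_s0), index=fit.sigma2.index, name="s0_squared")
    else:
        s0_val = float(np.exp(emean + offset))
        s0_sq = pd.Series(s0_val, index=fit.sigma2.index, name="s0_squared")

    if np.isinf(d0):
        post = s0_sq.to_numpy(dtype=float).copy()
        df_total = np.full(s2.size, 1e9)
    else:
        post = (d0 * s0_sq.to_numpy(dtype=float) + d * s2) / (d0 + d)
        df_total = np.full(s2.size, d0 + d)

    return ModeratedResult(
        d0=d0,
        s0_squared=s0_sq,
        sigma2_post=pd.Series(post, index=fit.sigma2.index, name="sigma2_post"),
        df_total=pd.Series(df_total, index=fit.sigma2.index, name="df_total"),
    )


def _sorted_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x)
    return x[order], y[order]


# ---------------------------------------------------------------------------
# contrast testing and FDR


_P_FLOOR = np.nextafter(0.0, 1.0)


def test_contrast(
    mod: ModeratedResult, fit: FitResult, contrast: ContrastSpec
) -> pd.DataFrame:
    """Test one contrast per feature with the moderated t-statistic.

    Returns a table with columns ``feature, contrast, logFC, t, df, p,
    family``.  ``logFC = c'beta``; ``t = logFC / (u * s~)`` where ``u`` is
    the contrast's unscaled standard error ``sqrt(c'(X'WX)^{-1}c)``.
    """
    c = contrast.vector(fit.levels)
    logfc = fit.beta.to_numpy() @ c
    u2 = float(c @ fit.cov_unscaled @ c)
    s2_post = mod.sigma2_post.to_numpy(dtype=float)
    df_total = mod.df_total.to_numpy(dtype=float)

    if u2 == 0.0:
        # null contrast: no effect, no evidence
        t_stat = np.zeros_like(logfc)
        p = np.ones_like(logfc)
    else:
        se = np.sqrt(u2 * s2_post)
        if np.any((se == 0) & (logfc != 0)):
            raise ValueError("zero standard error with nonzero effect")
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p = np.clip(p, _P_FLOOR, 1.0)

    return pd.DataFrame(
        {
            "feature": fit.beta.index,
            "contrast": contrast.name,
            "logFC": logfc,
            "t": t_stat,
            "df": df_total,
            "p": p,
            "family": contrast.family,
        }
    ).reset_index(drop=True)


def adjust_bh_grouped(table: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment applied separately per family tag.

    All rows sharing a ``family`` value are pooled into one BH family
    (contrasts and features together), mirroring an FDR budget split
    between the exercise-response contrasts and everything else.
    """
    if "family" not in table.columns or table["family"].isna().any():
        raise ValueError("every row needs a family tag for grouped adjustment")
    from statsmodels.stats.multitest import multipletests

    out = table.copy()
    out["adj_p"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        p = out.loc[idx, "p"].to_numpy(dtype=float)
        p = np.clip(p, _P_FLOOR, 1.0)
        out.loc[idx, "adj_p"] = multipletests(p, method="fdr_bh")[1]
    return out


def run_differential(
    matrix: OmicsMatrix,
    contrasts: Iterable[ContrastSpec] | None = None,
    use_sample_weights: bool = False,
    trend: bool = False,
    robust: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: fit, moderate, test all contrasts, adjust.

    ``use_sample_weights`` mirrors the study convention of enabling
    quality weights for global proteomics only.
    """
    design = DesignSpec.from_matrix(matrix)
    weights = estimate_sample_weights(matrix, design) if use_sample_weights else None
    fit = fit_cell_means(matrix, design, weights=weights)
    mod = moderate_variances(fit, trend=trend, robust=robust)
    if contrasts is None:
        contrasts = default_contrasts(design.levels)
    tables = [test_contrast(mod, fit, c) for c in contrasts]
    return adjust_bh_grouped(pd.concat(tables, ignore_index=True))
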