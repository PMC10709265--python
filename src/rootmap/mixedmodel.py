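"""Single-trait mixed linear model with genomic kinship.

The model is y = X b + u + e with u ~ N(0, sg2 * K) and e ~ N(0, se2 * I).
Variance components are estimated by REML, profiling the restricted
log-likelihood over the ratio lambda = se2 / sg2 after a one-time
eigendecomposition of K (the EMMA trick).  Marker scans reuse the null
lambda for every predictor (P3D, "population parameters previously
determined") unless asked to re-optimize per marker.  The full ML
log-likelihood at the optimum feeds the BIC used for covariate-model
selection, so models with different fixed effects stay comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: p-values below this are clipped before the -log10 transform; results
#: at the clip are flagged in the output.
P_FLOOR = 1e-300

GRID_LOG10 = np.linspace(-5.0, 5.0, 100)


def dummy_code(labels, drop_first: bool = True) -> np.ndarray:
    """0/1 indicator columns for a label vector.

    Levels are sorted; the alphabetically first level is dropped as the
    reference so the matrix stays full-rank next to an intercept.
    """
    lab = np.asarray(labels, dtype=object)
    levels = sorted(pd.unique(lab), key=str)
    use = levels[1:] if drop_first else levels
    return np.column_stack([(lab == lv).astype(float) for lv in use]) \
        if use else np.empty((lab.size, 0))


def build_design(n: int, labels=None) -> np.ndarray:
    """Intercept plus optional subpopulation dummies."""
    x = [np.ones((n, 1))]
    if labels is not None:
        x.append(dummy_code(labels))
    x = np.hstack(x)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    return x


@dataclass
class MixedModelSpec:
    """Response, fixed covariates, kinship, and the P3D switch."""

    y: np.ndarray
    x: np.ndarray  # n x p fixed-effect design incl. intercept
    kinship: np.ndarray
    p3d: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.x = np.asarray(self.x, dtype=float)
        n = self.y.size
        if self.x.shape[0] != n or self.kinship.shape != (n, n):
            raise ValueError("response, design and kinship sizes disagree")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    lambda_ratio: float  # se2 / sg2
    reml_loglik: float
    ml_loglik: float
    at_boundary: bool = False


@dataclass
class NullFit:
    """Null-model fit carrying everything a P3D scan needs."""

    vc: VarianceComponents
    eigvals: np.ndarray
    yt: np.ndarray  # U' y
    xt: np.ndarray  # U' X
    eigvecs: np.ndarray


def _check_kinship(k: np.ndarray, tol: float = 1e-8):
    if not np.allclose(k, k.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    w = np.linalg.eigvalsh(k)
    if w[0] < -tol * max(1.0, abs(w[-1])):
        raise ValueError(f"kinship not PSD (min eigenvalue {w[0]:.3g})")


def _profiled_logliks(lam, s, yt, xt):
    """REML and ML log-likelihoods profiled over the variance scale.

    For fixed lambda the GLS solution and the residual quadratic form q
    give sg2_REML = q/(n-p) and sg2_ML = q/n in closed form.
    """
    n, p = xt.shape
    w = 1.0 / (s + lam)
    xw = xt * w[:, None]
    xwx = xt.T @ xw
    beta = np.linalg.solve(xwx, xw.T @ yt)
    r = yt - xt @ beta
    q = float(np.sum(r * r * w))
    logdet_v = float(np.sum(np.log(s + lam)))
    sign, logdet_xwx = np.linalg.slogdet(xwx)
    _, logdet_xx = np.linalg.slogdet(xt.T @ xt)
    sg2_reml = q / (n - p)
    reml = -0.5 * (
        (n - p) * np.log(2 * np.pi * sg2_reml)
        + logdet_v + logdet_xwx - logdet_xx + (n - p)
    )
    sg2_ml = q / n
    ml = -0.5 * (n * np.log(2 * np.pi * sg2_ml) + logdet_v + n)
    return reml, ml, sg2_reml, sg2_ml


def reml_loglik_dense(y, x, kinship, sigma_g2, sigma_e2):
    """Direct evaluation of the restricted log-likelihood.

    Density of error contrasts A'y where A is an orthonormal basis of the
    null space of X'; used as an independent check of the spectral path.
    """
    n, p = x.shape
    q, _ = np.linalg.qr(x, mode="complete")
    a = q[:, p:]
    v = sigma_g2 * kinship + sigma_e2 * np.eye(n)
    ava = a.T @ v @ a
    ay = a.T @ y
    sign, logdet = np.linalg.slogdet(ava)
    return float(
        -0.5 * ((n - p) * np.log(2 * np.pi) + logdet
                + ay @ np.linalg.solve(ava, ay))
    )


def fit_null(spec: MixedModelSpec) -> NullFit:
    """REML variance components via spectral profiling over lambda.

    The restricted log-likelihood is evaluated on a 100-point grid of
    log10(lambda) in [-5, 5] and the best grid cell is refined by
    bounded Brent search.  The full ML log-likelihood is evaluated at
    the REML-optimal lambda (it feeds the BIC).
    """
    _check_kinship(spec.kinship)
    s, u = np.linalg.eigh(spec.kinship)
    s = np.maximum(s, 0.0)
    yt = u.T @ spec.y
    xt = u.T @ spec.x

    grid_vals = np.array([
        _profiled_logliks(10.0 ** g, s, yt, xt)[0] for g in GRID_LOG10
    ])
    best = int(np.argmax(grid_vals))
    at_boundary = best in (0, len(GRID_LOG10) - 1)
    if at_boundary:
        logger.warning("REML optimizer at lambda grid boundary")
    lo = GRID_LOG10[max(best - 1, 0)]
    hi = GRID_LOG10[min(best + 1, len(GRID_LOG10) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profiled_logliks(10.0 ** g, s, yt, xt)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    g_opt = float(res.x)
    lam = 10.0 ** g_opt
    reml, ml, sg2_reml, _ = _profiled_logliks(lam, s, yt, xt)
    vc = VarianceComponents(
        sigma_g2=sg2_reml,
        sigma_e2=sg2_reml * lam,
        lambda_ratio=lam,
        reml_loglik=reml,
        ml_loglik=ml,
        at_boundary=at_boundary,
    )
    return NullFit(vc=vc, eigvals=s, yt=yt, xt=xt, eigvecs=u)


def marker_scan(
    spec: MixedModelSpec,
    predictors: np.ndarray,
    predictor_ids=None,
    null: NullFit | None = None,
) -> pd.DataFrame:
    """GLS association test of each predictor column.

    Under P3D the covariance shape (lambda) stays fixed at the null
    optimum; the residual scale is re-estimated per predictor, giving a
    t-test with n - p - 1 degrees of freedom.  With ``p3d=False`` the
    variance components are re-optimized for every predictor.
    Zero-variance predictors yield missing rows (NaN statistics), not
    errors.  Columns: predictor_id, beta, t, minus_log10_p, p, fdr_p,
    p_clipped.
    """
    m = np.asarray(predictors, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    n, p = spec.x.shape
    if m.shape[0] != n:
        raise ValueError("predictor rows do not match sample count")
    if predictor_ids is None:
        predictor_ids = [f"pred{i}" for i in range(m.shape[1])]

    const = np.nanstd(m, axis=0) == 0
    if const.any():
        logger.info("marker_scan: %d constant predictors skipped", const.sum())

    if spec.p3d:
        if null is None:
            null = fit_null(spec)
        lam = null.vc.lambda_ratio
        w = 1.0 / (null.eigvals + lam)
        sw = np.sqrt(w)
        aw = null.xt * sw[:, None]
        bw = null.yt * sw
        mt = (null.eigvecs.T @ m) * sw[:, None]
        qx, _ = np.linalg.qr(aw)
        b_res = bw - qx @ (qx.T @ bw)
        g_res = mt - qx @ (qx.T @ mt)
        mm = np.einsum("ij,ij->j", g_res, g_res)
        my = g_res.T @ b_res
        yy = float(b_res @ b_res)
        df = n - p - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = my / mm
            rss = yy - beta * my
            sigma2 = rss / df
            t = beta / np.sqrt(sigma2 / mm)
        bad = const | (mm <= 1e-12) | ~np.isfinite(t)
        t = np.where(bad, np.nan, t)
        beta = np.where(bad, np.nan, beta)
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        beta = np.full(m.shape[1], np.nan)
        t = np.full(m.shape[1], np.nan)
        pvals = np.full(m.shape[1], np.nan)
        for j in range(m.shape[1]):
            if const[j]:
                continue
            xj = np.hstack([spec.x, m[:, [j]]])
            sub = MixedModelSpec(y=spec.y, x=xj, kinship=spec.kinship, p3d=True)
            fit = fit_null(sub)
            lam = fit.vc.lambda_ratio
            w = 1.0 / (fit.eigvals + lam)
            xw = fit.xt * w[:, None]
            xwx = fit.xt.T @ xw
            bhat = np.linalg.solve(xwx, xw.T @ fit.yt)
            r = fit.yt - fit.xt @ bhat
            dfj = n - xj.shape[1]
            sigma2 = float(np.sum(r * r * w)) / dfj
            cov = sigma2 * np.linalg.inv(xwx)
            beta[j] = bhat[-1]
            t[j] = bhat[-1] / np.sqrt(cov[-1, -1])
            pvals[j] = 2.0 * stats.t.sf(abs(t[j]), dfj)

    clipped = np.zeros(len(pvals), dtype=bool)
    ok = np.isfinite(pvals)
    clipped[ok] = pvals[ok] < P_FLOOR
    pvals = np.where(ok, np.clip(pvals, P_FLOOR, 1.0), np.nan)
    fdr = np.full(len(pvals), np.nan)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return pd.DataFrame({
        "predictor_id": list(predictor_ids),
        "beta": beta,
        "t": t,
        "p": pvals,
        "minus_log10_p": -np.log10(pvals),
        "fdr_p": fdr,
        "p_clipped": clipped,
    })


def bic(spec: MixedModelSpec, null: NullFit | None = None) -> float:
    """BIC = -2 * (full ML log-likelihood at the optimum) + q log n,

    with q = fixed-effect coefficients + 2 variance components.
    """
    if null is None:
        null = fit_null(spec)
    n, p = spec.x.shape
    q = p + 2
    return float(-2.0 * null.vc.ml_loglik + q * np.log(n))


@dataclass
class ModelSelectionResult:
    bics: dict  # model name -> BIC
    n_params: dict  # model name -> q
    selected: str
    n: int
    fits: dict = field(default_factory=dict, repr=False)


def select_covariate_model(
    y, kinship, labels4=None, labels6=None
) -> ModelSelectionResult:
    """BIC comparison of subpopulation covariate models.

    Candidates: (i) intercept only, (ii) four-group dummies, (iii)
    six-group dummies (each only when labels are supplied).  The lowest
    BIC wins; ties break toward fewer parameters.
    """
    n = np.asarray(y).size
    candidates = {"none": None}
    if labels4 is not None:
        _check_labels(labels4)
        candidates["subpop4"] = labels4
    if labels6 is not None:
        _check_labels(labels6)
        candidates["subpop6"] = labels6
    bics, n_params, fits = {}, {}, {}
    for name, lab in candidates.items():
        x = build_design(n, lab)
        spec = MixedModelSpec(y=y, x=x, kinship=kinship)
        fit = fit_null(spec)
        bics[name] = bic(spec, fit)
        n_params[name] = x.shape[1] + 2
        fits[name] = fit
    # argmin with ties toward fewer parameters
    selected = min(bics, key=lambda k: (round(bics[k], 12), n_params[k]))
    return ModelSelectionResult(
        bics=bics, n_params=n_params, selected=selected, n=n, fits=fits
    )


def _check_labels(labels):
    lab = np.asarray(labels, dtype=object)
    counts = pd.Series(lab).value_counts()
    if (counts < 1).any() or counts.size < 2:
        raise ValueError("each subpopulation level needs at least one sample")


def anova_dosage_subpop(expression, dosage, labels) -> float:
    """Marginal (type-II) F-test p-value for the additive dosage term.

    Linear model: expression ~ dosage + subpopulation, no interaction,
    dosage coded numerically (additive), subpopulation as a factor.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    dosage = np.asarray(dosage, dtype=float)
    if np.nanstd(dosage) == 0:
        raise ValueError("dosage is constant; ANOVA undefined")
    df = pd.DataFrame({
        "expr": np.asarray(expression, dtype=float),
        "dosage": dosage,
        "subpop": np.asarray(labels, dtype=object),
    })
    fit = ols("expr ~ dosage + C(subpop)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    p = float(table.loc["dosage", "PR(>F)"])
    if not np.isfinite(p) or p < P_FLOOR:
        p = P_FLOOR
    return p
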