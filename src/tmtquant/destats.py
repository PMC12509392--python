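"""Moderated differential expression between cohorts with tail-area FDR.

Per protein, an ordinary least-squares regression of log2 expression on an
intercept, the cohort indicator (old = 1, young = 0) and the clinical
covariates (sex, hypertension) yields the log2 fold change (old relative
to young), the residual variance s^2 and its degrees of freedom d.  The
per-protein variances are then shrunk toward an assay-wide prior estimated
by empirical Bayes: if the true variances follow a scaled inverse
chi-square prior with d0 degrees of freedom and scale s0^2, the posterior
variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t-statistic t = logFC / sqrt(s~^2 * v) follows a
t-distribution with d + d0 degrees of freedom under the null (v is the
unscaled variance of the cohort coefficient).  The hyperparameters (d0,
s0^2) are estimated once across all testable proteins by moment matching
of log s^2 against its theoretical scaled log-chi-square distribution
(digamma/trigamma inversion).  P-values are adjusted with a tail-area
false discovery rate: Storey-type q-values (pi0-scaled Benjamini-Hochberg
with cumulative-minimum monotonization), with plain BH (pi0 = 1) as the
conservative option used by default for small protein counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, DataError, ProteinQuantMatrix

DEFAULT_COVARIATES = ("sex", "hypertension")


@dataclass(frozen=True)
class EBHyperparams:
    """Assay-wide variance prior: d0 degrees of freedom, scale s0^2.

    ``d0 = inf`` means the per-protein variances are indistinguishable
    from a common value and shrinkage is total.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ConfigurationError("prior df d0 must be positive")
        if not (self.s0_sq > 0 and math.isfinite(self.s0_sq)):
            raise ConfigurationError("prior variance s0_sq must be positive")


def build_design_matrix(
    design: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Regression design: intercept, old-cohort indicator, covariates.

    Treatment coding with the young cohort, female sex and absent
    hypertension as the reference levels.  Returns (matrix, column names,
    sample ids); the cohort indicator is always column 1.
    """
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(design)),
        "group_old": (design["group"] == "old").to_numpy(float),
    }
    for cov in covariates:
        if cov == "sex":
            cols["sex_male"] = (design["sex"] == "male").to_numpy(float)
        elif cov == "hypertension":
            cols["hypertension"] = design["hypertension"].to_numpy(float)
        else:
            if cov not in design.columns:
                raise DataError(f"covariate {cov!r} not in design table")
            cols[cov] = design[cov].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), list(design["sample_id"])


def fit_protein_lm(
    values: np.ndarray, X: np.ndarray, coef_index: int = 1
) -> tuple[float, float, float, float]:
    """OLS fit of one protein's log2 values on the design.

    ``values`` may contain NaN (unquantified samples); the fit uses the
    present subset only, consistent with never imputing.  Returns
    ``(coef, s_sq, df, unscaled_var)`` where ``unscaled_var`` is the
    diagonal element of (X'X)^-1 for the tested coefficient.

    Raises :class:`DataError` when the reduced design is rank-deficient
    or leaves no residual degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    present = ~np.isnan(y)
    Xs, ys = X[present], y[present]
    p = X.shape[1]
    if Xs.shape[0] < p + 1 or np.linalg.matrix_rank(Xs) < p:
        raise DataError(
            "rank-deficient or df-exhausted design on present samples"
        )
    xtx_inv = np.linalg.inv(Xs.T @ Xs)
    beta = xtx_inv @ Xs.T @ ys
    resid = ys - Xs @ beta
    df = Xs.shape[0] - p
    s_sq = float(resid @ resid / df)
    return float(beta[coef_index]), s_sq, float(df), float(xtx_inv[coef_index, coef_index])


def _fit_all(
    Y: np.ndarray, X: np.ndarray, coef_index: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-protein OLS, grouped by missingness pattern.

    Returns (coef, s_sq, df, unscaled_var, testable) arrays over proteins;
    untestable proteins (rank-deficient reduced design) carry NaN.
    """
    n_prot, n_samp = Y.shape
    p = X.shape[1]
    coef = np.full(n_prot, np.nan)
    s_sq = np.full(n_prot, np.nan)
    df = np.full(n_prot, np.nan)
    v = np.full(n_prot, np.nan)
    testable = np.zeros(n_prot, dtype=bool)

    present = ~np.isnan(Y)
    patterns = {}
    for i in range(n_prot):
        patterns.setdefault(present[i].tobytes(), []).append(i)

    for key, idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        Xs = X[mask]
        if Xs.shape[0] < p + 1 or np.linalg.matrix_rank(Xs) < p:
            continue
        xtx_inv = np.linalg.inv(Xs.T @ Xs)
        proj = xtx_inv @ Xs.T  # p x n_present
        rows = np.asarray(idx)
        Ys = Y[np.ix_(rows, np.flatnonzero(mask))]
        B = Ys @ proj.T  # proteins x p
        resid = Ys - B @ Xs.T
        d = Xs.shape[0] - p
        coef[rows] = B[:, coef_index]
        s_sq[rows] = (resid**2).sum(axis=1) / d
        df[rows] = d
        v[rows] = xtx_inv[coef_index, coef_index]
        testable[rows] = True
    return coef, s_sq, df, v, testable


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 80) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing shape of trigamma; returns inf for y at
    or below zero (no finite solution) and a series-based start point.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < tol:
            break
    return x


def estimate_eb_hyperparams(
    s_sq: np.ndarray, df: np.ndarray, min_proteins: int = 10
) -> EBHyperparams:
    """Moment-matching estimate of the assay-wide variance prior.

    With true variances scaled-inverse-chi-square(d0, s0^2), the
    log sample variances satisfy

        E[log s^2] = log s0^2 + [digamma(d/2) - log(d/2)]
                              - [digamma(d0/2) - log(d0/2)]
        Var[log s^2] = trigamma(d/2) + trigamma(d0/2)

    so d0 is recovered by inverting the trigamma function on the excess
    spread of log s^2 and s0^2 from the corrected mean.  d0 is infinite
    when the empirical spread does not exceed the theoretical chi-square
    floor (variances indistinguishable from equal).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    finite = np.isfinite(s_sq) & (s_sq >= 0) & np.isfinite(df) & (df > 0)
    ok = finite & (s_sq > 0)
    if ok.sum() < min_proteins:
        if finite.sum() >= min_proteins and np.all(s_sq[finite] == 0):
            # Degenerate noise-free data: every fit is exact.  Total
            # shrinkage to a vanishing prior keeps fold changes intact
            # while null statistics collapse to t = 0.
            return EBHyperparams(d0=math.inf, s0_sq=np.finfo(float).tiny)
        raise DataError(
            f"need >= {min_proteins} positive finite variances for "
            "empirical-Bayes estimation; fall back to ordinary t-tests"
        )
    s_sq, df = s_sq[ok], df[ok]
    if np.all(s_sq == s_sq[0]):
        # literally zero spread: the sampling model cannot hold, so take
        # the common value itself as the prior rather than applying the
        # chi-square log-bias correction
        return EBHyperparams(d0=math.inf, s0_sq=float(s_sq[0]))
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var <= 0:
        return EBHyperparams(d0=math.inf, s0_sq=float(math.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    if math.isinf(d0):
        return EBHyperparams(d0=math.inf, s0_sq=float(math.exp(e_mean)))
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    log_fc: np.ndarray | float,
    s_sq: np.ndarray | float,
    df: np.ndarray | float,
    unscaled_var: np.ndarray | float,
    hyper: EBHyperparams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t-statistic, total df, and two-sided p-value.

    The posterior variance pools the protein-specific s^2 with the prior:
    s~^2 = (d0 s0^2 + d s^2) / (d0 + d); with d0 infinite the statistic
    is Gaussian with variance s0^2.
    """
    log_fc = np.atleast_1d(np.asarray(log_fc, dtype=float))
    s_sq = np.atleast_1d(np.asarray(s_sq, dtype=float))
    df = np.atleast_1d(np.asarray(df, dtype=float))
    unscaled_var = np.atleast_1d(np.asarray(unscaled_var, dtype=float))
    if math.isinf(hyper.d0):
        s_post = np.full_like(s_sq, hyper.s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s_post = (hyper.d0 * hyper.s0_sq + df * s_sq) / (hyper.d0 + df)
        df_total = df + hyper.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / np.sqrt(s_post * unscaled_var)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    return t, df_total, p


def estimate_pi0(p_values: np.ndarray) -> float:
    """Null-proportion estimate: average of #{p > lambda} / ((1-lambda) m)
    over lambda in {0.2, ..., 0.8}, capped to (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    lambdas = np.arange(0.2, 0.81, 0.1)
    estimates = [(p > lam).sum() / ((1.0 - lam) * m) for lam in lambdas]
    return float(np.clip(np.mean(estimates), 0.0, 1.0))


def adjust_fdr(p_values: np.ndarray, method: str = "tail_area") -> np.ndarray:
    """Tail-area FDR adjustment of raw p-values.

    ``tail_area``: Storey-type q-values, q(i) = pi0 * m * p(i) / rank(i)
    monotonized by cumulative minimum from the largest p, with pi0 from
    :func:`estimate_pi0`.  ``bh``: the same with pi0 = 1
    (Benjamini-Hochberg).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    if method not in ("tail_area", "bh"):
        raise ConfigurationError(f"unknown FDR method {method!r}")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    pi0 = estimate_pi0(p)
    return np.minimum(pi0 * bh, 1.0)


def run_de(
    matrix: ProteinQuantMatrix,
    design: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    fdr_method: str = "auto",
) -> tuple[pd.DataFrame, dict]:
    """Full moderated differential-expression analysis, old vs young.

    Fits every protein's regression on its present samples, estimates the
    variance prior once assay-wide, computes moderated t-statistics and
    tail-area-adjusted p-values, and flags significance at
    ``p_adjusted < alpha``.  ``fdr_method='auto'`` uses plain BH below
    200 testable proteins (where pi0 estimation is unstable) and
    pi0-scaled q-values otherwise.

    Returns the result table (protein, log_fc, t, df_total, p_value,
    p_adjusted, neg_log10_p_adjusted, significant) and a report dict with
    untestable proteins, the hyperparameters, the FDR method used, and a
    design collinearity diagnostic.
    """
    if matrix.scale != "log2":
        raise ConfigurationError("run_de expects a log2-scale matrix")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    design = design.set_index("sample_id").loc[matrix.samples].reset_index()
    X, colnames, _ = build_design_matrix(design, covariates)

    Y = matrix.data.to_numpy(dtype=float)
    coef, s_sq, df, v, testable = _fit_all(Y, X)
    proteins = np.asarray(matrix.proteins)
    if not testable.any():
        raise DataError("no testable proteins (all designs rank-deficient)")

    hyper = estimate_eb_hyperparams(s_sq[testable], df[testable])
    t, df_total, p = moderated_t(
        coef[testable], s_sq[testable], df[testable], v[testable], hyper
    )
    m = int(testable.sum())
    method = fdr_method
    if method == "auto":
        method = "bh" if m < 200 else "tail_area"
    q = adjust_fdr(p, method=method)

    result = pd.DataFrame(
        {
            "protein": proteins[testable],
            "log_fc": coef[testable],
            "t_moderated": t,
            "df_total": df_total,
            "p_value": p,
            "p_adjusted": q,
        }
    )
    with np.errstate(divide="ignore"):
        result["neg_log10_p_adjusted"] = -np.log10(result["p_adjusted"])
    result["significant"] = result["p_adjusted"] < alpha

    sv = np.linalg.svd(X, compute_uv=False)
    report = {
        "n_testable": m,
        "untestable_proteins": list(proteins[~testable]),
        "hyperparams": hyper,
        "fdr_method": method,
        "alpha": alpha,
        "design_columns": colnames,
        "design_condition_number": float(sv[0] / sv[-1]),
    }
    return result, report
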