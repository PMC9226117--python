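"""Two-level permutation inference and mixed-model comparisons.

Subject level: the t-value of each focal regressor in an OLS fit is
compared against a null distribution obtained by shuffling the dependent
variable; the right-tail p (with add-one correction) is mapped to a
Z-score, preserving the sign of the effect.

Group level: per-subject Z-values (or any per-subject statistics) are
tested against zero with a one-sample t whose null comes from random
sign-flips; effect sizes are Hedges-corrected Cohen's d with noncentral-t
confidence intervals.  A permutation-based 2x2 repeated-measures ANOVA and
maximum-likelihood mixed-model comparisons via likelihood-ratio tests
complete the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .exceptions import DegeneratePredictorError, DesignValidationError

__all__ = [
    "SubjectModelResult",
    "GroupTestResult",
    "MixedModelComparison",
    "permutation_z",
    "group_signflip_test",
    "cohens_d_hedges",
    "permutation_rm_anova",
    "fit_mixed_and_lrt",
    "deviation_code",
]


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

@dataclass
class SubjectModelResult:
    """Per-predictor coefficients, t-values and permutation Z of one subject."""

    coef: dict[str, float]
    tvalues: dict[str, float]
    zvalues: dict[str, float]
    pvalues_right: dict[str, float]
    n_perm: int
    seed: int | None
    focal: tuple[str, ...]
    meta: dict = field(default_factory=dict)


def _ols_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t-values (k, m) and coefficients for OLS of each column of Y on X."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = pinv @ Y  # (k, m)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return t, beta


def _design_matrix(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"] + list(X.columns)
    mat = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in X.columns])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise DegeneratePredictorError("rank-deficient predictor matrix")
    return mat, names


def p_to_z(p_right: float | np.ndarray, n_perm: int | None = None) -> float | np.ndarray:
    """Sign-preserving right-tail p to Z: Z = Phi^-1(1 - p_right).

    When ``n_perm`` is given, p is clipped to the resolution attainable
    with that many resamples, [1/(n+1), n/(n+1)], so Z stays finite and
    symmetric: a maximally negative effect mirrors the cap of a maximally
    positive one.
    """
    if n_perm is not None:
        lo = 1.0 / (1.0 + n_perm)
        p_right = np.clip(p_right, lo, 1.0 - lo)
    return stats.norm.isf(p_right)


def permutation_z(
    y: np.ndarray,
    X: pd.DataFrame,
    focal: list[str] | tuple[str, ...] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> SubjectModelResult:
    """Subject-level OLS with shuffle-the-outcome permutation Z-scores.

    The outcome ``y`` is regressed on the predictors in ``X`` (an intercept
    is added).  For each focal predictor the observed t is compared to a
    null built by refitting after randomly permuting ``y``; one shared
    permutation per iteration is used for all coefficients.  The right-tail
    p, p_r = (1 + #{t_null >= t_obs}) / (1 + n_perm), is converted to
    Z = Phi^-1(1 - p_r), so strong negative effects give negative Z.

    With ``exhaustive=True`` all n! permutations are enumerated (small n
    only) and p_r = #{t_null >= t_obs} / n! without the add-one term.
    """
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise DegeneratePredictorError("constant outcome: t undefined under permutation")
    mat, names = _design_matrix(X)
    if len(y) != mat.shape[0]:
        raise DesignValidationError("y and X row counts differ")
    focal = tuple(focal) if focal is not None else tuple(X.columns)
    meta: dict = {}
    if not exhaustive and n_perm < 100:
        meta["warning"] = f"n_perm={n_perm} is low; permutation p unstable"
        warnings.warn(meta["warning"], stacklevel=2)

    t_obs, beta_obs = _ols_t(mat, y[:, None])
    t_obs, beta_obs = t_obs[:, 0], beta_obs[:, 0]

    if exhaustive:
        from itertools import permutations

        perms = np.array(list(permutations(range(len(y)))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, len(y))), axis=1)
    t_null, _ = _ols_t(mat, y[perms].T)  # (k, n_perm_eff)

    idx = {name: i for i, name in enumerate(names)}
    p_right, zvals = {}, {}
    for name in focal:
        j = idx[name]
        if exhaustive:
            pr = float(np.mean(t_null[j] >= t_obs[j]))
        else:
            pr = (1.0 + np.sum(t_null[j] >= t_obs[j])) / (1.0 + len(perms))
        p_right[name] = float(pr)
        zvals[name] = float(p_to_z(pr, n_perm=len(perms)))
    return SubjectModelResult(
        coef={n: float(b) for n, b in zip(names, beta_obs)},
        tvalues={n: float(t) for n, t in zip(names, t_obs)},
        zvalues=zvals,
        pvalues_right=p_right,
        n_perm=len(perms),
        seed=seed,
        focal=focal,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def hedges_j(df: int | float) -> float:
    """Small-sample correction J(df) = 1 - 3 / (4*df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _nct_ci(t_obs: float, df: float, level: float = 0.95) -> tuple[float, float]:
    """CI for the noncentrality parameter of a t statistic (inversion)."""
    alpha = (1.0 - level) / 2.0
    if abs(t_obs) > 50:
        # the exact nct cdf underflows for extreme statistics; use the
        # asymptotic normal approximation of the noncentrality distribution
        zq = stats.norm.isf(alpha)
        half = zq * np.sqrt(1.0 + t_obs ** 2 / (2.0 * df))
        return t_obs - half, t_obs + half

    def upper(nc):  # P(T <= t_obs | nc) = alpha  -> nc is upper bound
        v = stats.nct.cdf(t_obs, df, nc)
        return (0.0 if nc > t_obs else 1.0) - alpha if np.isnan(v) else v - alpha

    def lower(nc):  # P(T >= t_obs | nc) = alpha
        v = stats.nct.sf(t_obs, df, nc)
        return (1.0 if nc > t_obs else 0.0) - alpha if np.isnan(v) else v - alpha

    def solve(f, direction):
        # expand the bracket outward from t_obs until the sign changes
        a, b, step = t_obs, t_obs + direction, 1.0
        fa = f(a)
        for _ in range(200):
            fb = f(b)
            if fa * fb <= 0:
                lo, hi = (a, b) if a < b else (b, a)
                return optimize.brentq(f, lo, hi, xtol=1e-8)
            a, fa = b, fb
            step *= 1.5
            b = b + direction * step
        raise RuntimeError("noncentrality bracket search failed")

    return solve(lower, -1.0), solve(upper, +1.0)


def cohens_d_hedges(
    values: np.ndarray,
    paired_with: np.ndarray | None = None,
    level: float = 0.95,
) -> dict[str, float]:
    """Hedges-corrected Cohen's d with a noncentral-t confidence interval.

    One-sample: d = mean/sd * J(n-1).  Paired: the test is on the
    differences, but d uses the pooled standard deviation of the two
    conditions, sqrt((sd_x^2 + sd_y^2)/2); the CI is obtained from the
    noncentral-t inversion of the paired t and rescaled to the pooled-SD
    metric.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise DesignValidationError("need n >= 3 for an effect size CI")
    if paired_with is not None:
        other = np.asarray(paired_with, dtype=float)
        diff = values - other
        sd_z = diff.std(ddof=1)
        pooled = np.sqrt((values.std(ddof=1) ** 2 + other.std(ddof=1) ** 2) / 2.0)
        denom = pooled
    else:
        diff = values
        sd_z = diff.std(ddof=1)
        denom = sd_z
    if sd_z == 0 or denom == 0:
        return {"d": float(np.inf) * np.sign(diff.mean()), "ci_low": np.nan,
                "ci_high": np.nan, "infinite": True}
    df = n - 1
    j = hedges_j(df)
    d = diff.mean() / denom * j
    t_obs = diff.mean() / (sd_z / np.sqrt(n))
    nc_lo, nc_hi = _nct_ci(t_obs, df, level)
    # delta (in sd-of-diff units) = nc/sqrt(n); rescale to the reported metric
    scale = (sd_z / denom) * j / np.sqrt(n)
    return {"d": float(d), "ci_low": float(nc_lo * scale),
            "ci_high": float(nc_hi * scale), "infinite": False}


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Observed statistic, permutation p, resampling metadata, effect size."""

    statistic: float
    p: float
    n_resamples: int
    effect_size: dict = field(default_factory=dict)
    tail: str = "two-sided"
    kind: str = "signflip-t"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def summary(self) -> str:
        es = self.effect_size
        s = (f"{self.kind}: stat={self.statistic:.3f}, p={self.p:.4g} "
             f"({self.tail}, {self.n_resamples} resamples)")
        if "d" in es:
            s += f", d={es['d']:.3f} [{es.get('ci_low', float('nan')):.3f}, " \
                 f"{es.get('ci_high', float('nan')):.3f}]"
        if "eta2_g" in es:
            s += f", generalized eta^2={es['eta2_g']:.3f}"
        return s


def _one_sample_t(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        # all-equal inputs: t is 0 for an all-zero vector, +/-inf otherwise
        return float(np.sign(x.mean()) * np.inf) if x.mean() != 0 else 0.0
    return float(x.mean() / (sd / np.sqrt(n)))


def group_signflip_test(
    values: np.ndarray,
    n_flips: int = 10_000,
    seed: int | None = None,
    paired_with: np.ndarray | None = None,
    exhaustive: bool = False,
) -> GroupTestResult:
    """One-sample (or paired) t-test against a random sign-flip null.

    Two-sided p = (1 + #{|t_flip| >= |t_obs|}) / (1 + n_flips); with
    ``exhaustive=True`` all 2^n sign patterns are enumerated and
    p = #{|t_flip| >= |t_obs|} / 2^n.
    """
    values = np.asarray(values, dtype=float)
    x = values - np.asarray(paired_with, float) if paired_with is not None else values
    n = len(x)
    if n < 2:
        raise DesignValidationError("need at least 2 subjects")
    t_obs = _one_sample_t(x)
    if t_obs == 0.0 and x.std(ddof=1) == 0:
        return GroupTestResult(statistic=0.0, p=1.0, n_resamples=0,
                               effect_size={"d": 0.0}, kind="signflip-t", seed=seed,
                               meta={"degenerate": "all-zero input"})

    if exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_flips, n)) * 2.0 - 1.0
    flipped = signs * x
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(sds == 0, np.sign(means) * np.inf, means / (sds / np.sqrt(n)))
        t_null = np.where((sds == 0) & (means == 0), 0.0, t_null)
    if exhaustive:
        p = float(np.mean(np.abs(t_null) >= abs(t_obs)))
    else:
        p = float((1.0 + np.sum(np.abs(t_null) >= abs(t_obs))) / (1.0 + len(signs)))
    try:
        if paired_with is not None:
            es = cohens_d_hedges(values, paired_with=np.asarray(paired_with, float))
        else:
            es = cohens_d_hedges(x)
    except DesignValidationError:  # n < 3: no CI
        es = {"d": np.nan, "note": "effect size needs n >= 3"}
    return GroupTestResult(
        statistic=t_obs, p=p, n_resamples=len(signs), effect_size=es,
        kind="signflip-t" if paired_with is None else "paired-signflip-t",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# permutation repeated-measures ANOVA (2x2 within design)
# ---------------------------------------------------------------------------

def _rm_anova_ss(cells: np.ndarray) -> dict[str, dict[str, float]]:
    """Classical 2x2 within-subject ANOVA from a (n, 2, 2) cell array."""
    n = cells.shape[0]
    grand = cells.mean()
    subj = cells.mean(axis=(1, 2))
    a_means = cells.mean(axis=(0, 2))
    b_means = cells.mean(axis=(0, 1))
    ss_subj = 4 * ((subj - grand) ** 2).sum()
    ss_a = 2 * n * ((a_means - grand) ** 2).sum()
    ss_b = 2 * n * ((b_means - grand) ** 2).sum()
    ab_means = cells.mean(axis=0)
    ss_ab = n * ((ab_means - a_means[:, None] - b_means[None, :] + grand) ** 2).sum()
    # error terms
    sa = cells.mean(axis=2)  # subject x A
    ss_as = 2 * ((sa - subj[:, None] - a_means[None, :] + grand) ** 2).sum()
    sb = cells.mean(axis=1)
    ss_bs = 2 * ((sb - subj[:, None] - b_means[None, :] + grand) ** 2).sum()
    ss_total = ((cells - grand) ** 2).sum()
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    dfe = n - 1
    res = {}
    denom_g = ss_subj + ss_as + ss_bs + ss_abs
    for name, ss_eff, ss_err in (
        ("A", ss_a, ss_as), ("B", ss_b, ss_bs), ("A:B", ss_ab, ss_abs),
    ):
        f = (ss_eff / 1.0) / (ss_err / dfe) if ss_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        res[name] = {
            "F": float(f),
            "df1": 1.0,
            "df2": float(dfe),
            "eta2_g": float(ss_eff / (ss_eff + denom_g)) if (ss_eff + denom_g) > 0 else 0.0,
        }
    return res


def permutation_rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str = "subject",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict[str, GroupTestResult]:
    """Permutation-based 2x2 repeated-measures ANOVA.

    For a two-level within-subject design every effect (two main effects
    and the interaction) reduces to a per-subject contrast, and the F test
    equals the squared paired t on that contrast.  The permutation null is
    built by randomly relabeling the factor levels within subjects, which
    for these contrasts amounts to per-subject sign-flips.  Generalized
    eta^2 is attached as effect size.
    """
    fa, fb = within
    levels_a = sorted(data[fa].unique())
    levels_b = sorted(data[fb].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise DesignValidationError("permutation_rm_anova supports 2x2 designs")
    subjects = sorted(data[subject].unique())
    cells = np.full((len(subjects), 2, 2), np.nan)
    for (s, a, b), grp in data.groupby([subject, fa, fb]):
        cells[subjects.index(s), levels_a.index(a), levels_b.index(b)] = grp[dv].mean()
    if np.isnan(cells).any():
        raise DesignValidationError("missing cells in the 2x2 within-subject design")

    obs = _rm_anova_ss(cells)
    n = len(subjects)
    contrasts = {
        "A": (cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1)),
        "B": (cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1)),
        "A:B": (cells[:, 0, 0] - cells[:, 0, 1] - cells[:, 1, 0] + cells[:, 1, 1]),
    }
    rng = np.random.default_rng(seed)
    out: dict[str, GroupTestResult] = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            if np.allclose(c, 0):
                out[name] = GroupTestResult(
                    statistic=0.0, p=1.0, n_resamples=n_perm,
                    effect_size={"eta2_g": obs[name]["eta2_g"]},
                    kind="perm-rm-anova-F", seed=seed,
                    meta={"df1": 1, "df2": n - 1, "degenerate": True},
                )
                continue
            raise DegeneratePredictorError("constant nonzero contrast")
        t_obs = c.mean() / (sd / np.sqrt(n))
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        flipped = signs * c
        t_null = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(n))
        f_obs, f_null = t_obs ** 2, t_null ** 2
        p = float((1.0 + np.sum(f_null >= f_obs)) / (1.0 + n_perm))
        out[name] = GroupTestResult(
            statistic=float(obs[name]["F"]), p=p, n_resamples=n_perm,
            effect_size={"eta2_g": obs[name]["eta2_g"]},
            kind="perm-rm-anova-F", seed=seed,
            meta={"df1": 1, "df2": n - 1},
        )
    # rename keys to the user's factor names
    return {
        f"{fa}": out["A"], f"{fb}": out["B"], f"{fa}:{fb}": out["A:B"],
    }


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def deviation_code(values: pd.Series | np.ndarray, levels: tuple | None = None) -> np.ndarray:
    """Deviation-code a two-level factor as +/-0.5."""
    arr = pd.Series(values)
    lv = list(levels) if levels is not None else sorted(arr.unique())
    if len(lv) != 2:
        raise DesignValidationError("deviation coding here supports two levels")
    return np.where(arr == lv[0], 0.5, -0.5)


@dataclass
class MixedModelComparison:
    """Likelihood-ratio comparison of a full vs nested reduced mixed model."""

    focal: str
    formula_full: str
    formula_reduced: str
    re_formula: str
    loglik_full: float
    loglik_reduced: float
    chi2: float
    df: int
    p: float
    fe_params: dict[str, float]
    converged: bool
    meta: dict = field(default_factory=dict)
    full_fit: object = field(default=None, repr=False)

    def summary(self) -> str:
        flag = "" if self.converged else "  [convergence flagged]"
        return (f"LRT {self.focal}: chi2({self.df}) = {self.chi2:.2f}, "
                f"p = {self.p:.4g}{flag}")


def _fit_ml(formula: str, data: pd.DataFrame, groups: str, re_formula: str):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        fit = None
        for method in (None, "powell", "cg"):
            try:
                cand = model.fit(reml=False, maxiter=500,
                                 **({} if method is None else {"method": method}))
            except Exception:
                continue
            if fit is None or (np.isfinite(cand.llf) and not np.isfinite(fit.llf)):
                fit = cand
            if bool(cand.converged) and np.isfinite(cand.llf):
                fit = cand
                break
    if fit is None:
        raise RuntimeError(f"mixed model fit failed outright: {formula}")
    converged = bool(fit.converged) and np.isfinite(fit.llf)
    singular = bool(np.any(np.linalg.eigvalsh(np.asarray(fit.cov_re)) < 1e-10))
    return fit, converged, singular


def fit_mixed_and_lrt(
    data: pd.DataFrame,
    formula_full: str,
    focal: str,
    groups: str = "subject",
    re_ladder: tuple[str, ...] | None = None,
) -> MixedModelComparison:
    """ML mixed-model fit with likelihood-ratio test of one fixed effect.

    The full model is compared against the nested model dropping ``focal``
    (identical random-effects structure): chi2 = 2 * delta logLik, df = 1.
    On convergence failure or a singular random-effects covariance, the
    random structure is simplified along ``re_ladder`` — every rung must
    retain the random slope of the focal effect.  If no rung converges the
    last fit is returned with ``converged=False`` (no silent fallback).
    """
    terms = [t.strip() for t in formula_full.split("~")[1].split("+")]
    if focal not in terms:
        raise DesignValidationError(f"focal term {focal!r} not in the full model")
    reduced_rhs = " + ".join(t for t in terms if t != focal) or "1"
    lhs = formula_full.split("~")[0].strip()
    formula_reduced = f"{lhs} ~ {reduced_rhs}"
    if re_ladder is None:
        re_ladder = (f"1 + {focal}", f"0 + {focal}")
    for rung in re_ladder:
        rung_terms = [t.strip() for t in rung.split("+")]
        if focal not in rung_terms:
            raise DesignValidationError(
                f"random-effects rung {rung!r} drops the focal slope {focal!r}"
            )

    candidates = []
    for rung in re_ladder:
        fit_full, conv_full, sing_full = _fit_ml(formula_full, data, groups, rung)
        fit_red, conv_red, sing_red = _fit_ml(formula_reduced, data, groups, rung)
        converged = conv_full and conv_red
        singular = sing_full or sing_red
        finite = np.isfinite(fit_full.llf) and np.isfinite(fit_red.llf)
        candidates.append((rung, fit_full, fit_red, converged, singular, finite))
        if converged and not singular:
            break
    # prefer a converged non-singular rung, then a converged one (boundary
    # variances near 0 are legitimate), then anything with finite likelihoods
    for want in ((True, False), (True, None), (None, None)):
        pick = next((c for c in candidates
                     if c[5]
                     and (want[0] is None or c[3] == want[0])
                     and (want[1] is None or c[4] == want[1])), None)
        if pick is not None:
            break
    if pick is None:
        pick = candidates[-1]
    rung, fit_full, fit_red, converged, singular, _ = pick
    chi2 = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
    p = float(stats.chi2.sf(chi2, 1))
    return MixedModelComparison(
        focal=focal,
        formula_full=formula_full,
        formula_reduced=formula_reduced,
        re_formula=rung,
        loglik_full=float(fit_full.llf),
        loglik_reduced=float(fit_red.llf),
        chi2=float(chi2),
        df=1,
        p=p,
        fe_params={k: float(v) for k, v in fit_full.fe_params.items()},
        converged=converged,
        meta={"singular": singular},
        full_fit=fit_full,
    )
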