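"""Cumulative-Gaussian psychometrics: thresholds, paired advice-split fits,
and the normalized shift (bias) statistic.

Choice proportions P(respond "left") as a function of signed disparity are
modelled as ``P(left | d) = Phi((d - mu) / sigma)``; ``sigma`` (the SD of
the underlying Gaussian) is the discrimination threshold and ``mu`` the
curve midpoint.  The social-influence bias of one observer is the signed
horizontal offset between the curves fitted to advice-left and advice-right
trials with a common slope; positive shift = displaced toward the advised
direction.

Fits are binomial maximum likelihood with a probit link (correct weighting
of unequal cell counts); a least-squares mode on proportions is retained
behind a flag.  No lapse-rate parameter is included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.special import ndtr

__all__ = [
    "BinomialPoint", "PsychometricFit", "normalize_disparities",
    "aggregate_points", "fit_cumulative_gaussian", "fit_paired_gaussians",
    "compare_one_vs_two_curves", "per_disparity_advice_test",
]

# sigma is bounded relative to the disparity scale of the data; hitting a
# bound marks the fit as unidentified rather than raising
_SIGMA_LO_FACTOR = 1e-3
_SIGMA_HI_FACTOR = 1e3


@dataclass(frozen=True)
class BinomialPoint:
    """Aggregated choices at one disparity: ``n_left`` of ``n_total``."""
    disparity: float
    n_left: int
    n_total: int

    def __post_init__(self):
        if not (0 <= self.n_left <= self.n_total) or self.n_total < 1:
            raise ValueError("require 0 <= n_left <= n_total and n_total >= 1")


@dataclass
class PsychometricFit:
    """Fitted cumulative-Gaussian parameters.

    ``mu``/``sigma`` are in the disparity units of the input.  For paired
    (advice-split) fits, ``mu`` holds the advice-left midpoint, ``mu_right``
    the advice-right one and ``shift = mu_right - mu_left`` (positive =
    toward the advised direction).
    """
    mu: float
    sigma: float
    shift: float | None = None
    mu_right: float | None = None
    adj_r2: float = float("nan")
    converged: bool = True
    ci: tuple[float, float] | None = None
    loglik: float = float("nan")
    n_params: int = 2
    method: str = "ml"


def normalize_disparities(disparities):
    """Scale disparities by the maximum absolute value to [-1, 1].

    Sign is preserved and zero maps to zero; an all-zero set has no scale
    and raises ValueError.
    """
    d = np.asarray(disparities, dtype=float)
    m = np.max(np.abs(d)) if d.size else 0.0
    if m == 0.0:
        raise ValueError("cannot normalize an all-zero disparity set")
    return d / m


def aggregate_points(trials: pd.DataFrame, disparity_col: str = "disparity_norm"
                     ) -> list[BinomialPoint]:
    """Collapse a trial table to per-disparity binomial counts."""
    g = trials.groupby(disparity_col, observed=True)["response"]
    return [BinomialPoint(float(d), int((r == "left").sum()), int(len(r)))
            for d, r in g]


def _points_to_arrays(points):
    d = np.array([p.disparity for p in points], dtype=float)
    k = np.array([p.n_left for p in points], dtype=float)
    n = np.array([p.n_total for p in points], dtype=float)
    return d, k, n


def _probit_irls(X, k, n, max_iter=60, tol=1e-10):
    """Newton/Fisher-scoring MLE for aggregated binomial probit data.

    Returns (beta, loglik, converged).  The linear predictor is clipped at
    +/-7.5, which acts as the slope/intercept bound under separation.
    """
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    # moment start: regress the clipped probit of proportions on X
    prop = np.clip(k / n, 0.01, 0.99)
    zq = stats.norm.ppf(prop)
    beta, *_ = np.linalg.lstsq(X, zq, rcond=None)
    ok = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -7.5, 7.5)
        mu = ndtr(eta)
        phi = np.exp(-0.5 * eta * eta) / math.sqrt(2 * math.pi)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        wgt = n * phi * phi / (mu * (1 - mu))
        score = X.T @ (phi * (k - n * mu) / (mu * (1 - mu)))
        info = (X * wgt[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p_dim), score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            ok = True
            break
    eta = np.clip(X @ beta, -7.5, 7.5)
    mu = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(k * np.log(mu) + (n - k) * np.log(1 - mu)))
    return beta, ll, ok


def _adj_r2(prop_obs, prop_fit, n_params):
    resid = np.sum((prop_obs - prop_fit) ** 2)
    tot = np.sum((prop_obs - np.mean(prop_obs)) ** 2)
    n_pts = len(prop_obs)
    if tot <= 0 or n_pts - n_params - 1 <= 0:
        return float("nan")
    r2 = 1.0 - resid / tot
    return 1.0 - (1.0 - r2) * (n_pts - 1) / (n_pts - n_params - 1)


def fit_cumulative_gaussian(points, method: str = "ml") -> PsychometricFit:
    """Fit P(left | d) = Phi((d - mu)/sigma) to binomial points.

    ``method='ml'`` is binomial maximum likelihood (probit); ``'ls'`` is
    unweighted least squares on proportions.  Degenerate data (flat at 50%,
    or perfectly separable) return a fit flagged ``converged=False`` with
    sigma pinned at the corresponding bound.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 disparity levels")
    d, k, n = _points_to_arrays(points)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct disparity levels")
    scale = np.max(np.abs(d))
    sig_lo, sig_hi = _SIGMA_LO_FACTOR * scale, _SIGMA_HI_FACTOR * scale

    if method == "ls":
        prop = k / n

        def f(x, mu, sigma):
            return ndtr((x - mu) / sigma)
        try:
            (mu, sigma), _ = curve_fit(f, d, prop, p0=[0.0, scale / 2],
                                       bounds=([-4 * scale, sig_lo], [4 * scale, sig_hi]),
                                       maxfev=10000)
            ok = sig_lo * 1.01 < sigma < sig_hi * 0.99
        except RuntimeError:
            mu, sigma, ok = 0.0, scale, False
        fit_prop = f(d, mu, sigma)
        ll = float("nan")
    else:
        X = np.column_stack([np.ones_like(d), d])
        beta, ll, ok = _probit_irls(X, k, n)
        b0, b1 = beta
        if b1 <= 1.0 / sig_hi:          # flat (or inverted): slope unidentified
            sigma = sig_hi
            mu = 0.0 if abs(b1) < 1e-300 else float(np.clip(-b0 / b1, d.min(), d.max()))
            ok = False
        elif b1 >= 1.0 / sig_lo:        # separable: slope at upper bound
            sigma = sig_lo
            mu = float(np.clip(-b0 / b1, d.min(), d.max()))
            ok = False
        else:
            sigma = 1.0 / b1
            mu = -b0 / b1
        fit_prop = ndtr((d - mu) / sigma)
    return PsychometricFit(mu=float(mu), sigma=float(sigma),
                           adj_r2=_adj_r2(k / n, fit_prop, 2),
                           converged=bool(ok), loglik=ll, n_params=2,
                           method=method)


def _paired_design(dL, dR):
    nL, nR = len(dL), len(dR)
    X = np.zeros((nL + nR, 3))
    X[:nL, 0] = 1.0
    X[nL:, 1] = 1.0
    X[:, 2] = np.concatenate([dL, dR])
    return X


def _fit_paired_ml(dL, kL, nL, dR, kR, nR):
    """Shared-slope paired probit fit; returns (mu_L, mu_R, sigma, ll, ok)."""
    X = _paired_design(dL, dR)
    k = np.concatenate([kL, kR])
    n = np.concatenate([nL, nR])
    beta, ll, ok = _probit_irls(X, k, n)
    cL, cR, b = beta
    scale = np.max(np.abs(X[:, 2]))
    if not (1.0 / (_SIGMA_HI_FACTOR * scale) < b < 1.0 / (_SIGMA_LO_FACTOR * scale)):
        b = np.clip(b, 1.0 / (_SIGMA_HI_FACTOR * scale), 1.0 / (_SIGMA_LO_FACTOR * scale))
        ok = False
    return -cL / b, -cR / b, 1.0 / b, ll, ok


def fit_paired_gaussians(points_adviceL, points_adviceR, shared_slope: bool = True,
                         n_boot: int = 1000, seed: int | None = None,
                         method: str = "ml") -> PsychometricFit:
    """Joint fit of advice-left / advice-right curves and the shift statistic.

    With ``shared_slope`` (the default, matching the definition of the bias
    statistic) both curves share sigma and differ only in their midpoints;
    ``shift = mu_right - mu_left`` is positive when responses are displaced
    toward the advised direction.  A seeded bootstrap (resampling trials
    within disparity x advice cells) supplies a percentile CI for the shift
    when ``n_boot > 0`` and a seed is given.
    """
    for name, pts in (("advice-left", points_adviceL), ("advice-right", points_adviceR)):
        if len(pts) < 3:
            raise ValueError(f"{name} condition needs >= 3 disparity levels")
    dL, kL, nL = _points_to_arrays(points_adviceL)
    dR, kR, nR = _points_to_arrays(points_adviceR)
    if np.any(nL < 1) or np.any(nR < 1):
        raise ValueError("empty advice cell")

    if not shared_slope:
        fL = fit_cumulative_gaussian(points_adviceL, method=method)
        fR = fit_cumulative_gaussian(points_adviceR, method=method)
        res = PsychometricFit(mu=fL.mu, sigma=fL.sigma, mu_right=fR.mu,
                              shift=fR.mu - fL.mu,
                              converged=fL.converged and fR.converged,
                              n_params=4, method=method)
        return res

    if method == "ls":
        prop = np.concatenate([kL / nL, kR / nR])
        X = _paired_design(dL, dR)

        def f(_, cL, cR, b):
            return ndtr(X @ np.array([cL, cR, b]))
        (cL, cR, b), _ = curve_fit(f, np.zeros(len(prop)), prop, p0=[0.0, 0.0, 2.0],
                                   maxfev=20000)
        muL, muR, sigma, ll, ok = -cL / b, -cR / b, 1.0 / b, float("nan"), True
    else:
        muL, muR, sigma, ll, ok = _fit_paired_ml(dL, kL, nL, dR, kR, nR)

    fit_prop = np.concatenate([ndtr((dL - muL) / sigma), ndtr((dR - muR) / sigma)])
    obs_prop = np.concatenate([kL / nL, kR / nR])
    ci = None
    if n_boot and seed is not None:
        rng = np.random.default_rng(seed)
        shifts = np.empty(n_boot)
        for b_i in range(n_boot):
            kLb = rng.binomial(nL.astype(int), kL / nL).astype(float)
            kRb = rng.binomial(nR.astype(int), kR / nR).astype(float)
            mL, mR, _, _, _ = _fit_paired_ml(dL, kLb, nL, dR, kRb, nR)
            shifts[b_i] = mR - mL
        ci = (float(np.percentile(shifts, 2.5)), float(np.percentile(shifts, 97.5)))
    return PsychometricFit(mu=float(muL), sigma=float(sigma), mu_right=float(muR),
                           shift=float(muR - muL),
                           adj_r2=_adj_r2(obs_prop, fit_prop, 3),
                           converged=bool(ok), ci=ci, loglik=ll, n_params=3,
                           method=method)


def compare_one_vs_two_curves(points_adviceL, points_adviceR,
                              n_perm: int = 2000, seed: int | None = 0) -> dict:
    """Does splitting by advice direction improve the psychometric fit?

    Compares a single curve on pooled data against the paired shared-slope
    model.  Returns adjusted R^2 of both models (computed on the advice-split
    proportions), an extra-sum-of-squares F-style p-value, and a permutation
    p-value obtained by permuting advice labels within disparity (the
    default inference: distribution-free).
    """
    dL, kL, nL = _points_to_arrays(points_adviceL)
    dR, kR, nR = _points_to_arrays(points_adviceR)
    muL, muR, sigma, ll2, _ = _fit_paired_ml(dL, kL, nL, dR, kR, nR)

    # one-curve fit on pooled counts at the union of disparities
    d_all = np.unique(np.concatenate([dL, dR]))
    k_pool = np.zeros_like(d_all)
    n_pool = np.zeros_like(d_all)
    for d_arr, k_arr, n_arr in ((dL, kL, nL), (dR, kR, nR)):
        for i, d in enumerate(d_all):
            m = d_arr == d
            k_pool[i] += k_arr[m].sum()
            n_pool[i] += n_arr[m].sum()
    X1 = np.column_stack([np.ones_like(d_all), d_all])
    beta1, _, _ = _probit_irls(X1, k_pool, n_pool)
    mu1, s1 = -beta1[0] / beta1[1], 1.0 / beta1[1]

    obs_prop = np.concatenate([kL / nL, kR / nR])
    fit1 = np.concatenate([ndtr((dL - mu1) / s1), ndtr((dR - mu1) / s1)])
    fit2 = np.concatenate([ndtr((dL - muL) / sigma), ndtr((dR - muR) / sigma)])
    rss1 = float(np.sum((obs_prop - fit1) ** 2))
    rss2 = float(np.sum((obs_prop - fit2) ** 2))
    n_pts = len(obs_prop)
    df2 = n_pts - 3
    if rss2 <= 1e-300 or df2 <= 0:
        p_f = float("nan")
    elif rss1 <= rss2:
        p_f = 1.0
    else:
        fstat = (rss1 - rss2) / (rss2 / df2)
        p_f = float(stats.f.sf(fstat, 1, df2))

    # permutation of advice labels within disparity (hypergeometric redraw of
    # the left-response split between the advice groups)
    p_perm = float("nan")
    if n_perm:
        rng = np.random.default_rng(seed)
        # align L and R cells on the common disparity grid
        common = d_all
        kLg = np.array([kL[dL == d].sum() for d in common])
        nLg = np.array([nL[dL == d].sum() for d in common])
        nRg = np.array([nR[dR == d].sum() for d in common])
        kTot = k_pool
        stat_obs = rss1 - rss2
        count = 0
        for _ in range(n_perm):
            kLp = rng.hypergeometric(kTot.astype(int),
                                     (n_pool - kTot).astype(int),
                                     nLg.astype(int)).astype(float)
            kRp = kTot - kLp
            mLp, mRp, sp, _, _ = _fit_paired_ml(common, kLp, nLg, common, kRp, nRg)
            f2p = np.concatenate([ndtr((common - mLp) / sp), ndtr((common - mRp) / sp)])
            obs_p = np.concatenate([kLp / nLg, kRp / nRg])
            f1p = np.concatenate([ndtr((common - mu1) / s1)] * 2)
            # refit one-curve: pooled counts unchanged under the permutation
            statp = float(np.sum((obs_p - f1p) ** 2) - np.sum((obs_p - f2p) ** 2))
            if statp >= stat_obs - 1e-15:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)

    # both adjusted R^2 use the two-curve parameter count so that identical
    # advice conditions score identically under either model
    return {
        "adj_r2_one": _adj_r2(obs_prop, fit1, 3),
        "adj_r2_two": _adj_r2(obs_prop, fit2, 3),
        "p_value": p_perm if n_perm else p_f,
        "p_permutation": p_perm,
        "p_f": p_f,
        "shift": muR - muL,
    }


def per_disparity_advice_test(trials: pd.DataFrame, alpha: float = 0.05,
                              disparity_col: str = "disparity_norm") -> pd.DataFrame:
    """Wilcoxon rank-sum test of advice-left vs advice-right responses,
    per disparity, across participants, Bonferroni-corrected.

    For each disparity level, each participant contributes their proportion
    of "left" responses under each advice direction; the two sets of
    proportions are compared with a two-sided rank-sum test.  Disparities
    with fewer than two participants in either condition are excluded (a
    warning row is retained with NaN p).
    """
    rows = []
    disps = sorted(trials[disparity_col].unique())
    n_tests = 0
    for d in disps:
        sub = trials[trials[disparity_col] == d]
        pL = sub[sub.advice == "left"].groupby("participant", observed=True)["response"] \
            .apply(lambda r: (r == "left").mean())
        pR = sub[sub.advice == "right"].groupby("participant", observed=True)["response"] \
            .apply(lambda r: (r == "left").mean())
        if len(pL) < 2 or len(pR) < 2:
            rows.append({"disparity": d, "n_left_adv": len(pL),
                         "n_right_adv": len(pR), "p_value": float("nan"),
                         "statistic": float("nan"), "excluded": True})
            continue
        stat, p = stats.ranksums(pL.to_numpy(), pR.to_numpy())
        rows.append({"disparity": d, "n_left_adv": len(pL), "n_right_adv": len(pR),
                     "p_value": float(p), "statistic": float(stat), "excluded": False})
        n_tests += 1
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_value"] * max(n_tests, 1), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
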