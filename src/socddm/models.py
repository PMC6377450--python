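"""Five-model diffusion comparison: which parameters vary with advice?

Group-level trial data are binned per condition cell (disparity x advice
direction) at the RT quantiles {.1,.3,.5,.7,.9} of each response boundary;
parameters are estimated by maximizing the multinomial likelihood of the
observed bin counts under the model's predicted bin probabilities, and
models are compared by BIC = k ln(n) - 2 lnL.

The model family (advice direction may affect...):

1. nothing;
2. the starting point z only;
3. the drift rate v only;
4. both v and z;
5. every parameter (unrestricted).

Drift always varies freely with disparity.  Under the default nuisance
tying, boundary separation, non-decision time and the three variability
parameters are shared across disparities (with seven disparities this
gives k = 13, 14, 20, 21, 26 for models 1-5); ``strict_disparity_tying``
frees them per disparity as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import _wfpt
from .config import QUAD_NODES, QUANTILE_PROBS, S_DEFAULT, SERIES_EPS
from .ddm import DiffusionParams

__all__ = [
    "ModelSpec", "FitOptions", "FitResult", "build_model", "fit_model",
    "fit_all_models", "bic", "compare_models", "split_by_conformity",
    "parameter_cis", "fit_diagnostics",
]

_NUISANCE = ("a", "ter", "eta", "sz", "st")

_DEFAULT_BOUNDS = {
    "v": (-2.0, 2.0),
    "z": (0.15, 0.85),
    "a": (0.05, 0.30),
    "ter": (0.05, 1.5),
    "eta": (0.0, 0.5),
    "sz": (0.0, 0.08),
    "st": (0.0, 0.6),
}

_MODEL_FREEDOMS = {
    1: (False, False, False),
    2: (False, True, False),
    3: (True, False, False),
    4: (True, True, False),
    5: (True, True, True),
}


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, k ln(n) - 2 lnL (lower = better)."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return k * math.log(n) - 2.0 * loglik


@dataclass(frozen=True)
class ModelSpec:
    """Parameter-tying map for one model variant.

    ``tying`` maps each diffusion parameter to the condition keys it varies
    with (subsets of {"disparity", "advice"}); ``k`` is the implied free-
    parameter count.
    """
    model_id: int
    disparity_levels: tuple
    v_by_advice: bool
    z_by_advice: bool
    nuisance_by_advice: bool
    strict_disparity_tying: bool = False

    @property
    def tying(self) -> dict:
        t = {"v": {"disparity"} | ({"advice"} if self.v_by_advice else set()),
             "z": {"advice"} if self.z_by_advice else set()}
        for p in _NUISANCE:
            keys = {"advice"} if self.nuisance_by_advice else set()
            if self.strict_disparity_tying:
                keys = keys | {"disparity"}
            t[p] = keys
        return t

    @property
    def k(self) -> int:
        nd = len(self.disparity_levels)
        k = nd * (2 if self.v_by_advice else 1)
        k += 2 if self.z_by_advice else 1
        per_n = 2 if self.nuisance_by_advice else 1
        if self.strict_disparity_tying:
            per_n *= nd
        return k + 5 * per_n


def build_model(model_id: int, disparity_levels,
                strict_disparity_tying: bool = False) -> ModelSpec:
    """ModelSpec for one of the five advice-effect variants."""
    if model_id not in _MODEL_FREEDOMS:
        raise ValueError(f"model_id must be 1..5, got {model_id}")
    levels = tuple(sorted(float(d) for d in np.unique(np.asarray(disparity_levels))))
    if len(levels) < 1:
        raise ValueError("need at least one disparity level")
    v_adv, z_adv, n_adv = _MODEL_FREEDOMS[model_id]
    return ModelSpec(model_id, levels, v_adv, z_adv, n_adv, strict_disparity_tying)


@dataclass
class FitOptions:
    quantile_probs: tuple = QUANTILE_PROBS
    n_restarts: int = 5
    seed: int = 0
    s: float = S_DEFAULT
    eps: float = SERIES_EPS
    maxfev: int = 20000
    ftol: float = 1e-7
    xtol: float = 1e-4
    full_bin_min: int = 10      # boundary counts below this collapse 6 -> 3 bins
    any_bin_min: int = 2        # below this the boundary is a single bin
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)  # e.g. {"sz": 0.0}
    init: np.ndarray | None = None


@dataclass
class FitResult:
    """Group-level fit of one model variant."""
    spec: ModelSpec
    theta: np.ndarray
    param_names: list
    estimates: pd.DataFrame
    loglik: float
    bic: float
    n: int
    k: int
    converged: bool
    restart_logliks: list
    warnings: list
    cells: pd.DataFrame
    options: FitOptions
    s: float = S_DEFAULT


# ---------------------------------------------------------------------------
# packing of the flat parameter vector
# ---------------------------------------------------------------------------

class _Packing:
    def __init__(self, spec: ModelSpec, bounds: dict, fixed: dict):
        self.spec = spec
        nd = len(spec.disparity_levels)
        self.nd = nd
        self.nva = 2 if spec.v_by_advice else 1
        self.nza = 2 if spec.z_by_advice else 1
        self.nna = 2 if spec.nuisance_by_advice else 1
        self.nnd = nd if spec.strict_disparity_tying else 1
        names, bl, bh = [], [], []
        b = dict(_DEFAULT_BOUNDS)
        b.update(bounds)
        self.offsets = {}
        pos = 0
        self.offsets["v"] = pos
        for i in range(nd):
            for a_i in range(self.nva):
                suffix = f"_{'LR'[a_i]}" if self.nva == 2 else ""
                names.append(f"v[d{i}]{suffix}")
                bl.append(b["v"][0]); bh.append(b["v"][1])
                pos += 1
        self.offsets["z"] = pos
        for a_i in range(self.nza):
            names.append(f"z_{'LR'[a_i]}" if self.nza == 2 else "z")
            bl.append(b["z"][0]); bh.append(b["z"][1])
            pos += 1
        for p in _NUISANCE:
            self.offsets[p] = pos
            for d_i in range(self.nnd):
                for a_i in range(self.nna):
                    nm = p + (f"[d{d_i}]" if self.nnd > 1 else "") + \
                        (f"_{'LR'[a_i]}" if self.nna == 2 else "")
                    names.append(nm)
                    if p in fixed:
                        bl.append(fixed[p]); bh.append(fixed[p])
                    else:
                        bl.append(b[p][0]); bh.append(b[p][1])
                    pos += 1
        self.names = names
        self.lo = np.array(bl)
        self.hi = np.array(bh)
        self.size = pos

    def v_index(self, d_idx, adv_idx):
        return self.offsets["v"] + d_idx * self.nva + (adv_idx if self.nva == 2 else 0)

    def z_index(self, adv_idx):
        return self.offsets["z"] + (adv_idx if self.nza == 2 else 0)

    def nuis_index(self, p, d_idx, adv_idx):
        d_i = d_idx if self.nnd > 1 else 0
        a_i = adv_idx if self.nna == 2 else 0
        return self.offsets[p] + d_i * self.nna + a_i

    def cell_params(self, theta, d_idx, adv_idx):
        g = lambda p: theta[self.nuis_index(p, d_idx, adv_idx)]
        return (theta[self.v_index(d_idx, adv_idx)], g("a"),
                theta[self.z_index(adv_idx)], g("ter"), g("eta"), g("sz"), g("st"))


# ---------------------------------------------------------------------------
# data preparation: observed quantile edges and bin counts per cell
# ---------------------------------------------------------------------------

@dataclass
class _Cell:
    d_idx: int
    adv_idx: int
    d_norm: float
    advice: str
    edges_up: np.ndarray
    edges_lo: np.ndarray
    counts: np.ndarray
    n: int


def _edges_counts(rts, probs, full_min, any_min):
    rts = np.sort(rts)
    m = len(rts)
    if m >= full_min:
        edges = np.quantile(rts, probs)
    elif m >= any_min:
        edges = np.quantile(rts, [0.3, 0.7])
    else:
        edges = np.empty(0)
    counts = np.diff(np.concatenate([[0], np.searchsorted(rts, edges, side="right"), [m]]))
    return np.asarray(edges, dtype=float), counts.astype(float)


def _prepare_cells(trials: pd.DataFrame, spec: ModelSpec, opts: FitOptions):
    cells = []
    warnings = []
    levels = list(spec.disparity_levels)
    for d_idx, d in enumerate(levels):
        for adv_idx, adv in enumerate(("left", "right")):
            sub = trials[(trials["disparity_norm"] == d) & (trials["advice"] == adv)]
            if "terminated" in sub.columns:
                sub = sub[sub["terminated"]]
            if len(sub) == 0:
                raise ValueError(f"empty condition cell: disparity {d}, advice {adv}")
            up = sub.loc[sub["response"] == "left", "rt_s"].to_numpy(dtype=float)
            lo = sub.loc[sub["response"] == "right", "rt_s"].to_numpy(dtype=float)
            e_up, c_up = _edges_counts(up, opts.quantile_probs, opts.full_bin_min,
                                       opts.any_bin_min)
            e_lo, c_lo = _edges_counts(lo, opts.quantile_probs, opts.full_bin_min,
                                       opts.any_bin_min)
            for nm, arr in (("left", up), ("right", lo)):
                if len(arr) < opts.full_bin_min:
                    warnings.append(
                        f"cell (d={d}, advice {adv}): only {len(arr)} '{nm}' "
                        "responses; RT bins collapsed")
            cells.append(_Cell(d_idx, adv_idx, float(d), adv, e_up, e_lo,
                               np.concatenate([c_up, c_lo]), len(up) + len(lo)))
    return cells, warnings


_GH = {}
_GL = {}


def _gh(n):
    if n not in _GH:
        _GH[n] = np.polynomial.hermite.hermgauss(n)
    return _GH[n]


def _gl(n):
    if n not in _GL:
        _GL[n] = np.polynomial.legendre.leggauss(n)
    return _GL[n]


_ONE = np.array([1.0])
_SQRT_PI = math.sqrt(math.pi)
_SQRT2 = math.sqrt(2.0)


def _cell_nll(v, a, z, ter, eta, sz, st, s, cell, eps):
    """Negative log-likelihood contribution of one cell (or None if the
    parameter combination is inconsistent)."""
    z_abs = z * a
    if z_abs - 0.5 * sz <= 1e-4 * a or z_abs + 0.5 * sz >= a * (1 - 1e-4) \
            or ter - 0.5 * st < 0.0:
        return None
    if eta > 1e-9:
        x, wt = _gh(QUAD_NODES)
        vp = (v + _SQRT2 * eta * x) / s
        vw = wt / _SQRT_PI
    else:
        vp = np.array([v / s])
        vw = _ONE
    if sz > 1e-9:
        u, wt = _gl(QUAD_NODES)
        wn = (z_abs + 0.5 * sz * u) / a
        ww = wt / 2.0
    else:
        wn = np.array([z])
        ww = _ONE
    if st > 1e-9:
        u, wt = _gl(QUAD_NODES)
        tn = ter + 0.5 * st * u
        tw = wt / 2.0
    else:
        tn = np.array([ter])
        tw = _ONE
    probs = _wfpt.cell_bin_probs(cell.edges_up, cell.edges_lo, vp, vw, wn, ww,
                                 tn, tw, a / s, eps)
    return -float(np.dot(cell.counts, np.log(np.maximum(probs, 1e-10))))


def _make_objective(cells, packing, opts):
    def nll(theta):
        total = 0.0
        for cell in cells:
            v, a, z, ter, eta, sz, st = packing.cell_params(theta, cell.d_idx,
                                                            cell.adv_idx)
            c = _cell_nll(v, a, z, ter, eta, sz, st, opts.s, cell, opts.eps)
            if c is None:
                return 1e10
            total += c
        return total
    return nll


def _heuristic_init(cells, packing, trials, opts):
    theta = np.empty(packing.size)
    rt = trials.loc[trials["terminated"], "rt_s"] if "terminated" in trials.columns \
        else trials["rt_s"]
    q10 = float(np.quantile(rt, 0.1))
    a0 = 0.12
    ter0 = float(np.clip(q10 - 0.08, packing.lo[packing.offsets["ter"]] + 1e-3,
                         packing.hi[packing.offsets["ter"]] - 1e-3))
    for p, val in (("a", a0), ("ter", ter0), ("eta", 0.08), ("sz", 0.01), ("st", 0.1)):
        for d_i in range(packing.nnd):
            for a_i in range(packing.nna):
                idx = packing.offsets[p] + d_i * packing.nna + a_i
                theta[idx] = np.clip(val, packing.lo[idx], packing.hi[idx])
    for a_i in range(packing.nza):
        theta[packing.z_index(a_i)] = 0.5
    # accumulate per-cell drift guesses from choice fractions
    acc = np.zeros(packing.size)
    cnt = np.zeros(packing.size)
    for cell in cells:
        n_up = cell.counts[:len(cell.counts) - (len(cell.edges_lo) + 1)].sum()
        p_up = np.clip(n_up / cell.n, 0.02, 0.98)
        v0 = opts.s ** 2 * math.log(p_up / (1 - p_up)) / a0
        i = packing.v_index(cell.d_idx, cell.adv_idx)
        acc[i] += v0
        cnt[i] += 1
    for i in range(packing.offsets["v"], packing.offsets["z"]):
        theta[i] = np.clip(acc[i] / max(cnt[i], 1), packing.lo[i] + 1e-6,
                           packing.hi[i] - 1e-6)
    return theta


def _embed_init(target: _Packing, source_fit: "FitResult"):
    """Initial vector for a richer model from a fitted nested model."""
    src_pack = _Packing(source_fit.spec, source_fit.options.bounds,
                        source_fit.options.fixed)
    theta = np.zeros(target.size)
    cnt = np.zeros(target.size)
    for d_idx in range(target.nd):
        for adv_idx in range(2):
            vals = src_pack.cell_params(source_fit.theta, d_idx, adv_idx)
            v, a, z, ter, eta, sz, st = vals
            for idx, val in [(target.v_index(d_idx, adv_idx), v),
                             (target.z_index(adv_idx), z),
                             (target.nuis_index("a", d_idx, adv_idx), a),
                             (target.nuis_index("ter", d_idx, adv_idx), ter),
                             (target.nuis_index("eta", d_idx, adv_idx), eta),
                             (target.nuis_index("sz", d_idx, adv_idx), sz),
                             (target.nuis_index("st", d_idx, adv_idx), st)]:
                theta[idx] += val
                cnt[idx] += 1
    theta = theta / np.maximum(cnt, 1)
    return np.clip(theta, target.lo, target.hi)


def fit_model(trials: pd.DataFrame, spec: ModelSpec,
              options: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of one model variant to group-level trials.

    Bounded derivative-free (Powell) optimization of the quantile-bin
    multinomial likelihood, from a choice-fraction heuristic start plus
    seeded random restarts; the spread of restart log-likelihoods is
    reported as a convergence diagnostic.
    """
    opts = options or FitOptions()
    packing = _Packing(spec, opts.bounds, opts.fixed)
    cells, warnings = _prepare_cells(trials, spec, opts)
    nll = _make_objective(cells, packing, opts)
    n = int(sum(c.n for c in cells))

    inits = []
    if opts.init is not None:
        inits.append(np.clip(np.asarray(opts.init, dtype=float), packing.lo, packing.hi))
    inits.append(_heuristic_init(cells, packing, trials, opts))
    rng = np.random.default_rng(opts.seed)
    while len(inits) < max(opts.n_restarts, 1):
        base = inits[0]
        pert = base + rng.normal(0.0, 0.12, packing.size) * (packing.hi - packing.lo)
        inits.append(np.clip(pert, packing.lo, packing.hi))

    free = packing.hi > packing.lo
    results = []
    for x0 in inits:
        res = optimize.minimize(
            nll, x0, method="Powell",
            bounds=optimize.Bounds(packing.lo, packing.hi),
            options={"maxfev": opts.maxfev, "ftol": opts.ftol, "xtol": opts.xtol})
        results.append(res)
    nlls = [float(r.fun) for r in results]
    best = results[int(np.argmin(nlls))]
    theta = np.clip(best.x, packing.lo, packing.hi)
    loglik = -float(best.fun)

    rows = []
    for cell in cells:
        v, a, z, ter, eta, sz, st = packing.cell_params(theta, cell.d_idx, cell.adv_idx)
        rows.append({"disparity_norm": cell.d_norm, "advice": cell.advice,
                     "v": v, "a": a, "z_rel": z, "ter": ter, "eta": eta,
                     "sz": sz, "st": st, "n": cell.n})
    est = pd.DataFrame(rows)
    cells_df = pd.DataFrame([{"disparity_norm": c.d_norm, "advice": c.advice,
                              "n": c.n, "n_bins": len(c.counts)} for c in cells])
    k = spec.k
    return FitResult(spec=spec, theta=theta, param_names=packing.names,
                     estimates=est, loglik=loglik, bic=bic(loglik, k, n), n=n,
                     k=k, converged=bool(best.success), restart_logliks=[-v for v in nlls],
                     warnings=warnings, cells=cells_df, options=opts, s=opts.s)


def fit_all_models(trials: pd.DataFrame, model_ids=(1, 2, 3, 4, 5),
                   options: FitOptions | None = None,
                   strict_disparity_tying: bool = False) -> dict:
    """Fit several model variants, warm-starting each richer model from its
    best fitted sub-model so that log-likelihoods respect the nesting order.
    """
    opts = options or FitOptions()
    levels = np.unique(trials["disparity_norm"])
    fits: dict[int, FitResult] = {}
    parents = {1: (), 2: (1,), 3: (1,), 4: (2, 3), 5: (4,)}
    for mid in sorted(model_ids):
        spec = build_model(mid, levels, strict_disparity_tying)
        o = replace(opts)
        avail = [fits[p] for p in parents[mid] if p in fits]
        if avail:
            src = max(avail, key=lambda f: f.loglik)
            o.init = _embed_init(_Packing(spec, opts.bounds, opts.fixed), src)
        fits[mid] = fit_model(trials, spec, o)
    return fits


def compare_models(fit_results) -> dict:
    """Rank fits of the same trial set by BIC; ties are reported, not broken.

    Accepts a dict {model_id: FitResult} or a list of FitResults.
    """
    if isinstance(fit_results, dict):
        fits = list(fit_results.values())
    else:
        fits = list(fit_results)
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are not on the same trial set: n = {sorted(ns)}")
    tab = pd.DataFrame([{"model": f.spec.model_id, "k": f.k,
                         "loglik": f.loglik, "bic": f.bic} for f in fits])
    tab = tab.sort_values("bic", kind="stable").reset_index(drop=True)
    tab["delta_bic"] = tab["bic"] - tab["bic"].iloc[0]
    best_bic = tab["bic"].iloc[0]
    tied = tab.loc[(tab["bic"] - best_bic).abs() < 1e-6, "model"].tolist()
    return {"table": tab, "selected": int(tied[0]) if len(tied) == 1 else None,
            "tied": tied}


def split_by_conformity(trials: pd.DataFrame) -> pd.DataFrame:
    """Annotate trials with their advice x conformity cell.

    Returns a copy with a ``cell`` column ("left_conform", "left_nonconform",
    "right_conform", "right_nonconform").  Empty cells are reported in
    ``.attrs['empty_cells']`` and ``.attrs['caveat']`` records that
    conditioning on the response biases parameter interpretation.
    """
    t = trials.copy()
    conf = t["conformed"].astype("boolean")
    t["cell"] = t["advice"].astype(str) + "_" + np.where(conf.fillna(False),
                                                         "conform", "nonconform")
    t.loc[conf.isna(), "cell"] = pd.NA
    all_cells = [f"{a}_{c}" for a in ("left", "right") for c in ("conform", "nonconform")]
    present = set(t["cell"].dropna().unique())
    t.attrs["empty_cells"] = sorted(set(all_cells) - present)
    t.attrs["caveat"] = ("cells condition on the response; parameter estimates "
                         "from response-conditioned data are descriptive only")
    return t


# ---------------------------------------------------------------------------
# bootstrap confidence intervals for the advice effects
# ---------------------------------------------------------------------------

def _coordinate_refit(cells, packing, theta0, opts, sweeps=2):
    """Cheap warm-started refit of drift and starting-point parameters with
    the nuisance parameters held fixed (profile refit)."""
    theta = theta0.copy()
    by_cell = {(c.d_idx, c.adv_idx): c for c in cells}

    def cell_obj(cell, th):
        v, a, z, ter, eta, sz, st = packing.cell_params(th, cell.d_idx, cell.adv_idx)
        c = _cell_nll(v, a, z, ter, eta, sz, st, opts.s, cell, opts.eps)
        return 1e10 if c is None else c

    for _ in range(sweeps):
        # drift parameters: each affects the cells sharing its index
        seen = {}
        for cell in cells:
            seen.setdefault(packing.v_index(cell.d_idx, cell.adv_idx), []).append(cell)
        for idx, cc in seen.items():
            def f(x):
                theta[idx] = x
                return sum(cell_obj(c, theta) for c in cc)
            res = optimize.minimize_scalar(
                f, bounds=(packing.lo[idx], packing.hi[idx]), method="bounded",
                options={"xatol": 1e-4})
            theta[idx] = res.x
        # starting point(s)
        zseen = {}
        for cell in cells:
            zseen.setdefault(packing.z_index(cell.adv_idx), []).append(cell)
        for idx, cc in zseen.items():
            def fz(x):
                theta[idx] = x
                return sum(cell_obj(c, theta) for c in cc)
            res = optimize.minimize_scalar(
                fz, bounds=(packing.lo[idx], packing.hi[idx]), method="bounded",
                options={"xatol": 1e-4})
            theta[idx] = res.x
    return theta


def _advice_stats(theta, packing, spec):
    """Per-disparity drift advice-differences and the starting-point
    displacement toward advice, from a parameter vector."""
    out = {}
    for d_idx, d in enumerate(spec.disparity_levels):
        if spec.v_by_advice:
            dv = theta[packing.v_index(d_idx, 0)] - theta[packing.v_index(d_idx, 1)]
        else:
            dv = 0.0
        out[f"dv[d={d:g}]"] = dv
    if spec.z_by_advice:
        out["z_displacement"] = 0.5 * (theta[packing.z_index(0)] - theta[packing.z_index(1)])
    else:
        out["z_displacement"] = theta[packing.z_index(0)] - 0.5
    out["dv_mean"] = float(np.mean([v for k, v in out.items() if k.startswith("dv[")]))
    return out


def parameter_cis(trials: pd.DataFrame, spec: ModelSpec, n_boot: int = 1000,
                  seed: int = 0, options: FitOptions | None = None,
                  alpha: float = 0.05, point_fit: FitResult | None = None,
                  sweeps: int = 2) -> pd.DataFrame:
    """Bootstrap intervals for the advice effects on drift and starting point.

    Trials are resampled with replacement within each disparity x advice
    cell; each replicate re-estimates drift and starting-point parameters by
    warm-started profile refits (nuisance parameters held at the point
    estimate).  Percentile 95% intervals are returned along with Bonferroni-
    corrected significance flags: an advice-difference in v is flagged when
    its corrected interval excludes 0, the starting-point displacement when
    it excludes 0 (i.e. z_rel differs from the 0.5 midpoint).
    """
    opts = options or FitOptions()
    fit = point_fit if point_fit is not None else fit_model(trials, spec, opts)
    packing = _Packing(spec, opts.bounds, opts.fixed)
    cells, _ = _prepare_cells(trials, spec, opts)
    point = _advice_stats(fit.theta, packing, spec)

    # pre-extract per-cell RT/response arrays for fast resampling
    cell_data = []
    for cell in cells:
        sub = trials[(trials["disparity_norm"] == cell.d_norm)
                     & (trials["advice"] == cell.advice)]
        if "terminated" in sub.columns:
            sub = sub[sub["terminated"]]
        cell_data.append((cell, sub["rt_s"].to_numpy(dtype=float),
                          (sub["response"] == "left").to_numpy()))

    rng = np.random.default_rng(seed)
    stats_boot = {k: np.empty(n_boot) for k in point}
    small = [c.n < 20 for c in cells]
    for b in range(n_boot):
        bcells = []
        for cell, rts, is_left in cell_data:
            idx = rng.integers(0, len(rts), len(rts))
            r, l = rts[idx], is_left[idx]
            e_up, c_up = _edges_counts(r[l], opts.quantile_probs,
                                       opts.full_bin_min, opts.any_bin_min)
            e_lo, c_lo = _edges_counts(r[~l], opts.quantile_probs,
                                       opts.full_bin_min, opts.any_bin_min)
            bcells.append(_Cell(cell.d_idx, cell.adv_idx, cell.d_norm, cell.advice,
                                e_up, e_lo, np.concatenate([c_up, c_lo]), len(r)))
        th = _coordinate_refit(bcells, packing, fit.theta, opts, sweeps=sweeps)
        for k_, v_ in _advice_stats(th, packing, spec).items():
            stats_boot[k_][b] = v_

    n_tests = len(point)
    a_bonf = alpha / n_tests
    rows = []
    for name, est in point.items():
        bs = stats_boot[name]
        lo, hi = np.percentile(bs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        lob, hib = np.percentile(bs, [100 * a_bonf / 2, 100 * (1 - a_bonf / 2)])
        rows.append({"quantity": name, "estimate": est, "ci_low": lo, "ci_high": hi,
                     "ci_low_bonf": lob, "ci_high_bonf": hib,
                     "significant": bool(lob > 0.0 or hib < 0.0),
                     "widened": bool(any(small))})
    out = pd.DataFrame(rows)
    out.attrs["n_boot"] = n_boot
    out.attrs["seed"] = seed
    return out


def fit_diagnostics(fit: FitResult, trials: pd.DataFrame,
                    n_grid: int = 80) -> dict:
    """Observed vs predicted overlays for a completed fit.

    Returns tidy tables: ``rt_cdf`` (per cell, empirical and predicted
    cumulative RT distributions of each response on a common grid) and
    ``choice`` (observed vs predicted P(left) per disparity x advice).
    """
    from .ddm import choice_probability, fpt_cdf

    opts = fit.options
    rows_cdf = []
    rows_choice = []
    for _, e in fit.estimates.iterrows():
        sub = trials[(trials["disparity_norm"] == e.disparity_norm)
                     & (trials["advice"] == e.advice)]
        if "terminated" in sub.columns:
            sub = sub[sub["terminated"]]
        params = DiffusionParams(v=e.v, a=e.a, z_rel=e.z_rel, ter=e.ter,
                                 eta=e.eta, sz=e.sz, st=e.st, s=fit.s)
        p_left_pred = choice_probability(params, "left")
        obs_left = (sub["response"] == "left").mean()
        rows_choice.append({"disparity_norm": e.disparity_norm, "advice": e.advice,
                            "p_left_obs": float(obs_left),
                            "p_left_pred": float(p_left_pred), "n": len(sub)})
        grid = np.linspace(0.0, float(sub["rt_s"].max()) * 1.05, n_grid)
        for resp, bname in (("left", "upper"), ("right", "lower")):
            rts = np.sort(sub.loc[sub["response"] == resp, "rt_s"].to_numpy())
            pred = fpt_cdf(grid, bname, params, opts.eps)
            emp = np.searchsorted(rts, grid, side="right") / max(len(sub), 1)
            for g, pr, em in zip(grid, pred, emp):
                rows_cdf.append({"disparity_norm": e.disparity_norm,
                                 "advice": e.advice, "response": resp,
                                 "rt": g, "cdf_pred": pr, "cdf_obs": em})
    return {"rt_cdf": pd.DataFrame(rows_cdf), "choice": pd.DataFrame(rows_choice)}
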