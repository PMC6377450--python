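"""Full drift-diffusion (Wiener) model: densities, probabilities, quantiles
and a seeded trial simulator.

The decision variable starts at ``z_rel * a`` and drifts with rate ``v``
(evidence units per second, diffusion coefficient ``s``) between absorbing
boundaries at 0 and ``a``.  The *upper* boundary codes a "left" response and
positive drift points leftward.  Across-trial variability follows the
conventional forms: drift ~ Normal(v, eta), starting point ~ Uniform over a
range ``sz`` (absolute evidence units), non-decision time ~ Uniform over a
range ``st`` seconds centred on ``Ter``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _wfpt
from .config import (DT_DEFAULT, QUAD_NODES, S_DEFAULT, SERIES_EPS,
                     T_MAX_DEFAULT)

BOUNDARY_ALIASES = {
    "upper": True, "left": True,
    "lower": False, "right": False,
}


class ParameterError(ValueError):
    """A diffusion parameter lies outside its valid domain."""


class DegenerateCellError(ValueError):
    """Requested quantiles of a boundary with (numerically) zero mass."""


@dataclass(frozen=True)
class DiffusionParams:
    """Seven-parameter diffusion model plus the fixed scaling constant.

    v : drift rate (signed; positive drifts toward the upper/"left" boundary)
    a : boundary separation (> 0, evidence units)
    z_rel : relative starting point in (0, 1); 0.5 = unbiased midpoint
    ter : non-decision time (s)
    eta : across-trial SD of drift
    sz : across-trial range of the starting point (absolute evidence units)
    st : across-trial range of the non-decision time (s)
    s : diffusion coefficient, held fixed within any fit
    """

    v: float
    a: float
    z_rel: float = 0.5
    ter: float = 0.3
    eta: float = 0.0
    sz: float = 0.0
    st: float = 0.0
    s: float = S_DEFAULT

    def validate(self) -> "DiffusionParams":
        if not (self.a > 0.0):
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z_rel < 1.0):
            raise ParameterError(f"z_rel must lie in (0, 1), got {self.z_rel}")
        if self.eta < 0.0 or self.sz < 0.0 or self.st < 0.0:
            raise ParameterError("variability parameters eta, sz, st must be >= 0")
        z_abs = self.z_rel * self.a
        if z_abs - 0.5 * self.sz <= 0.0 or z_abs + 0.5 * self.sz >= self.a:
            raise ParameterError(
                "starting-point support z_rel*a +/- sz/2 must stay inside (0, a)")
        if self.ter - 0.5 * self.st < 0.0:
            raise ParameterError("Ter - st/2 must be >= 0")
        if not (self.s > 0.0):
            raise ParameterError("diffusion coefficient s must be > 0")
        return self

    def replace(self, **kw) -> "DiffusionParams":
        return _dc_replace(self, **kw)


def _as_upper(boundary) -> bool:
    if isinstance(boundary, str):
        try:
            return BOUNDARY_ALIASES[boundary.lower()]
        except KeyError:
            raise ValueError(f"unknown boundary {boundary!r}; use upper/left or lower/right")
    return bool(boundary)


def quad_nodes(params: DiffusionParams, n: int = QUAD_NODES):
    """Quadrature node/weight arrays in unit-diffusion coordinates.

    Returns (vp_nodes, v_wts, w_nodes, w_wts, ter_nodes, ter_wts, ap).
    A variability parameter of zero collapses its dimension to one node.
    """
    s = params.s
    ap = params.a / s
    if params.eta > 0.0:
        x, wt = np.polynomial.hermite.hermgauss(n)
        vp = (params.v + math.sqrt(2.0) * params.eta * x) / s
        vw = wt / math.sqrt(math.pi)
    else:
        vp = np.array([params.v / s])
        vw = np.array([1.0])
    z_abs = params.z_rel * params.a
    if params.sz > 0.0:
        u, wt = np.polynomial.legendre.leggauss(n)
        wn = (z_abs + 0.5 * params.sz * u) / params.a
        ww = wt / 2.0
    else:
        wn = np.array([params.z_rel])
        ww = np.array([1.0])
    if params.st > 0.0:
        u, wt = np.polynomial.legendre.leggauss(n)
        tn = params.ter + 0.5 * params.st * u
        tw = wt / 2.0
    else:
        tn = np.array([params.ter])
        tw = np.array([1.0])
    return vp, vw, wn, ww, tn, tw, ap


def choice_probability(params: DiffusionParams, boundary="upper",
                       eps: float = SERIES_EPS) -> float:
    """P(absorption at ``boundary``); P(upper) + P(lower) = 1.

    Closed form when eta = sz = 0, otherwise Gauss-Hermite/Legendre
    quadrature over the variability distributions.
    """
    params.validate()
    upper = _as_upper(boundary)
    vp, vw, wn, ww, _, _, ap = quad_nodes(params)
    return float(_wfpt.prob_nodes(upper, vp, vw, wn, ww, ap))


def fpt_density(t, boundary, params: DiffusionParams,
                eps: float = SERIES_EPS):
    """Defective first-passage-time density (s^-1) at reaction time(s) t.

    Zero for t below ``Ter - st/2`` (no decision before the non-decision
    time); the two boundary densities jointly integrate to 1.
    """
    params.validate()
    upper = _as_upper(boundary)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    vp, vw, wn, ww, tn, tw, ap = quad_nodes(params)
    out = _wfpt.density_nodes(ts, upper, vp, vw, wn, ww, tn, tw, ap, eps)
    return out if np.ndim(t) else float(out[0])


def fpt_cdf(t, boundary, params: DiffusionParams,
            eps: float = SERIES_EPS):
    """Defective first-passage-time CDF; tends to choice_probability as
    t -> infinity."""
    params.validate()
    upper = _as_upper(boundary)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    vp, vw, wn, ww, tn, tw, ap = quad_nodes(params)
    out = _wfpt.cdf_nodes(ts, upper, vp, vw, wn, ww, tn, tw, ap, eps)
    return out if np.ndim(t) else float(out[0])


def fpt_quantiles(boundary, params: DiffusionParams, probs,
                  eps: float = SERIES_EPS) -> np.ndarray:
    """RT quantiles conditional on absorption at ``boundary``.

    ``probs`` must be strictly increasing in (0, 1).  Raises
    DegenerateCellError when the boundary carries (numerically) no mass.
    """
    params.validate()
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or np.any(probs <= 0.0) or np.any(probs >= 1.0) \
            or np.any(np.diff(probs) <= 0.0):
        raise ValueError("probs must be strictly increasing within (0, 1)")
    upper = _as_upper(boundary)
    p_b = choice_probability(params, "upper" if upper else "lower", eps)
    if p_b < 1e-8:
        raise DegenerateCellError(
            f"boundary {'upper' if upper else 'lower'} has probability {p_b:.3g}")
    vp, vw, wn, ww, tn, tw, ap = quad_nodes(params)

    def cond_cdf(t):
        return float(_wfpt.cdf_nodes(np.array([t]), upper, vp, vw, wn, ww,
                                     tn, tw, ap, eps)[0]) / p_b

    t_lo = max(params.ter - 0.5 * params.st, 0.0)
    # bracket the upper end
    t_hi = t_lo + 0.5
    while cond_cdf(t_hi) < probs[-1] + 1e-9:
        t_hi = t_lo + (t_hi - t_lo) * 2.0
        if t_hi > 1e4:
            raise DegenerateCellError("quantile bracket exceeded 1e4 s")
    out = np.empty(probs.shape[0])
    lo = t_lo
    for i, p in enumerate(probs):
        out[i] = brentq(lambda t: cond_cdf(t) - p, lo, t_hi, xtol=1e-8)
        lo = out[i]
    return out


def bin_probabilities(params: DiffusionParams, edges_upper, edges_lower,
                      eps: float = SERIES_EPS) -> np.ndarray:
    """Multinomial cell probabilities given interior RT edges per boundary.

    With 5 interior edges per boundary this yields the 12 quantile-bin
    probabilities of the fitting objective; they are nonnegative and sum
    to 1 (within series tolerance).
    """
    params.validate()
    edges_upper = np.asarray(edges_upper, dtype=float)
    edges_lower = np.asarray(edges_lower, dtype=float)
    for e in (edges_upper, edges_lower):
        if e.size > 1 and np.any(np.diff(e) <= 0.0):
            raise ValueError("quantile edges must be strictly increasing")
    vp, vw, wn, ww, tn, tw, ap = quad_nodes(params)
    return _wfpt.cell_bin_probs(edges_upper, edges_lower, vp, vw, wn, ww,
                                tn, tw, ap, eps)


def simulate_paths(vs, z_abs, ters, a, s=S_DEFAULT, seed=0,
                   dt: float = DT_DEFAULT, t_max: float = T_MAX_DEFAULT,
                   bridge: bool = True):
    """Integrate first-passage paths for per-trial drift/start/non-decision
    arrays.  Returns (code, rt): code 1 = upper/left, 0 = lower/right,
    -1 = not absorbed by ``t_max``; rt includes the non-decision time."""
    vs = np.ascontiguousarray(vs, dtype=float)
    z_abs = np.ascontiguousarray(z_abs, dtype=float)
    ters = np.ascontiguousarray(ters, dtype=float)
    if np.any(z_abs <= 0.0) or np.any(z_abs >= a):
        raise ParameterError("starting points must lie strictly inside (0, a)")
    if np.any(ters < 0.0):
        raise ParameterError("non-decision times must be >= 0")
    code, tdec = _wfpt.euler_sim(vs, z_abs, a, s, dt, t_max, int(seed) % (2 ** 31 - 1),
                                 bridge)
    return code, tdec + ters


def simulate_trials(params: DiffusionParams, n: int, seed: int,
                    dt: float = DT_DEFAULT, t_max: float = T_MAX_DEFAULT,
                    bridge: bool = True) -> pd.DataFrame:
    """Simulate ``n`` first-passage outcomes by Euler-Maruyama integration.

    Per trial, drift ~ Normal(v, eta), start ~ Uniform(z +/- sz/2) and
    non-decision time ~ Uniform(Ter +/- st/2) are drawn, then the path is
    integrated to absorption (Brownian-bridge crossing test between steps).
    Paths that have not absorbed by ``t_max`` are returned flagged with
    ``terminated=False``, never dropped.

    Returns a DataFrame with columns ``response`` ('left' = upper boundary,
    'right' = lower), ``rt`` (s) and ``terminated``; reproducible given
    (params, n, seed, dt).
    """
    params.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    vs = rng.normal(params.v, params.eta, n) if params.eta > 0 else np.full(n, params.v)
    z_abs = params.z_rel * params.a
    zs = rng.uniform(z_abs - 0.5 * params.sz, z_abs + 0.5 * params.sz, n) \
        if params.sz > 0 else np.full(n, z_abs)
    ters = rng.uniform(params.ter - 0.5 * params.st, params.ter + 0.5 * params.st, n) \
        if params.st > 0 else np.full(n, params.ter)
    path_seed = int(ss.generate_state(2)[1] % np.uint32(2 ** 31 - 1))
    code, rt = simulate_paths(vs, zs, ters, params.a, params.s, path_seed,
                              dt, t_max, bridge)
    # code 1 = upper = left, code 0 = lower = right, -1 = not absorbed
    resp = pd.Categorical.from_codes(
        np.select([code == 1, code == 0], [0, 1], default=-1),
        categories=["left", "right"])
    out = pd.DataFrame({
        "response": resp,
        "rt": rt,
        "terminated": code >= 0,
    })
    out.attrs["params"] = params
    out.attrs["seed"] = seed
    out.attrs["dt"] = dt
    return out
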