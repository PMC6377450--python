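"""Compiled kernels for Wiener first-passage-time numerics.

All functions here work in *unit-diffusion* coordinates: drift ``vp = v/s``,
boundary separation ``ap = a/s``, relative start ``w`` in (0, 1), decision
time ``td`` in seconds (reaction time minus non-decision time).  The lower
boundary sits at 0, the upper at ``ap``.  Densities returned are "defective":
each boundary's density integrates to that boundary's absorption probability.

Two exact series expansions are used, selected by the scaled time
``tau = td / ap**2``:

* small tau: method-of-images sums (Gaussian images for the density, an
  inverse-Gaussian/erfc image sum for the CDF), which converge in a handful
  of terms when tau is small;
* large tau: the spectral (sine) series, whose terms decay like
  ``exp(-k^2 pi^2 tau / 2)``.

Truncation is adaptive with an absolute tolerance per evaluation (1e-7 by
default, set by the caller).
"""

import math

import numpy as np
from numba import njit

# Scaled-time switch points between the image and spectral expansions.  Both
# are exact; 0.12 keeps term counts small on either side for scalar use.
# The vectorized CDF kernel switches lower (0.035): its spectral terms are
# shared across quadrature nodes, and down to that point the worst-case
# cancellation error exp(w^2/(2 tau)) * 1e-16 stays below the 1e-7 series
# tolerance.
TAU_SWITCH = 0.12
TAU_SWITCH_VEC = 0.035

_SQRT2PI = math.sqrt(2.0 * math.pi)
_MAX_SPECTRAL_TERMS = 64


@njit(cache=True)
def _log_ndtr(x):
    """log of the standard normal CDF, stable for large negative x."""
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    # asymptotic expansion of the Mills ratio
    x2 = x * x
    return (-0.5 * x2 - math.log(-x) - 0.5 * math.log(2.0 * math.pi)
            + math.log1p(-1.0 / x2 + 3.0 / (x2 * x2)))


@njit(cache=True)
def p_lower_unit(vp, ap, w):
    """Absorption probability at the lower boundary (no variability)."""
    q = 2.0 * vp * ap
    if abs(q) < 1e-8:
        return (1.0 - w) * (1.0 - 0.5 * q * w)
    if q > 0.0:
        # stable for large positive q
        return math.exp(-q * w) * (-math.expm1(-q * (1.0 - w))) / (-math.expm1(-q))
    # mirror: P_lower(vp, w) = 1 - P_lower(-vp, 1 - w)
    qm = -q
    return 1.0 - math.exp(-qm * (1.0 - w)) * (-math.expm1(-qm * w)) / (-math.expm1(-qm))


@njit(cache=True)
def fpt_density_unit(td, vp, ap, w, eps):
    """Defective FPT density at the *lower* boundary at decision time td."""
    if td <= 0.0:
        return 0.0
    tau = td / (ap * ap)
    drift_exp = -vp * ap * w - 0.5 * vp * vp * td

    # term counts after Navarro & Fuss
    if math.pi * tau * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tau)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))
    arg = 2.0 * eps * math.sqrt(2.0 * math.pi * tau)
    if arg < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(arg))
        ks = max(ks, math.sqrt(tau) + 1.0)
    else:
        ks = 2.0

    if ks < kl:
        # image expansion; fold the drift exponent into each term so that no
        # intermediate overflows for extreme drifts
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-K, K + 1):
            wk = w + 2.0 * k
            e = drift_exp - wk * wk / (2.0 * tau)
            if e > -745.0:
                acc += wk * math.exp(e)
        f0 = acc / math.sqrt(2.0 * math.pi * tau ** 3)
    else:
        K = int(math.ceil(kl))
        acc = 0.0
        de = math.exp(drift_exp) if drift_exp < 700.0 else math.exp(700.0)
        for k in range(1, K + 1):
            acc += k * math.exp(-0.5 * k * k * math.pi * math.pi * tau) * math.sin(k * math.pi * w)
        f0 = math.pi * acc * de
        return max(f0 / (ap * ap), 0.0)
    return max(f0 / (ap * ap), 0.0)


@njit(cache=True)
def _cdf_images_unit(td, vp, ap, w, eps):
    """Lower-boundary defective CDF via the image (inverse-Gaussian) sum.

    Exact for all td; converges fast when tau = td/ap^2 is small.  Evaluated
    in log space so that drift/image exponentials never overflow.
    """
    if td <= 0.0:
        return 0.0
    sqt = math.sqrt(td)
    zp = w * ap
    acc = 0.0
    for k in range(0, 40):
        # positive image at c = zp + 2 k ap
        c = zp + 2.0 * k * ap
        b = 2.0 * k * ap * vp
        t1 = math.exp(b + _log_ndtr((-vp * td - c) / sqt))
        t2 = math.exp(b - 2.0 * vp * c + _log_ndtr((vp * td - c) / sqt))
        inc = t1 + t2
        acc += inc
        if k >= 1:
            # negative image at c = zp - 2 k ap  ->  reflected barrier 2k ap - zp
            ct = 2.0 * k * ap - zp
            bm = -2.0 * k * ap * vp
            t3 = math.exp(bm + _log_ndtr((vp * td - ct) / sqt))
            t4 = math.exp(bm + 2.0 * vp * ct + _log_ndtr((-vp * td - ct) / sqt))
            acc -= t3 + t4
            if inc + t3 + t4 < eps * 0.1:
                break
    if acc < 0.0:
        acc = 0.0
    return acc


@njit(cache=True)
def _cdf_spectral_unit(td, vp, ap, w, eps):
    """Lower-boundary defective CDF via the integrated spectral series."""
    pref_exp = -vp * ap * w
    c = math.pi * math.pi / (ap * ap)
    s = 0.0
    for m in range(1, 513):
        lam = 0.5 * (vp * vp + c * m * m)
        coef = (2.0 * math.pi * m / (ap * ap)) / (2.0 * lam)
        e = pref_exp - lam * td
        term_bound = coef * (math.exp(e) if e < 700.0 else math.exp(700.0))
        if term_bound < eps * 0.1 and m >= 3:
            break
        s += coef * math.sin(m * math.pi * w) * math.exp(e)
    out = p_lower_unit(vp, ap, w) - s
    if out < 0.0:
        out = 0.0
    elif out > 1.0:
        out = 1.0
    return out


@njit(cache=True)
def fpt_cdf_unit(td, vp, ap, w, eps):
    """Defective FPT CDF at the *lower* boundary at decision time td."""
    if td <= 0.0:
        return 0.0
    tau = td / (ap * ap)
    if tau < TAU_SWITCH:
        return _cdf_images_unit(td, vp, ap, w, eps)
    return _cdf_spectral_unit(td, vp, ap, w, eps)


# ---------------------------------------------------------------------------
# quadrature over across-trial variability (eta: Gaussian drift, sz: uniform
# start, st: uniform non-decision time).  Node/weight arrays are prepared by
# the caller; a parameter with zero variability contributes a single node.
# ---------------------------------------------------------------------------

@njit(cache=True)
def density_nodes(ts, upper, vp_nodes, vw, w_nodes, ww, ter_nodes, tw, ap, eps):
    out = np.zeros(ts.shape[0])
    for it in range(ts.shape[0]):
        acc = 0.0
        for kt in range(ter_nodes.shape[0]):
            td = ts[it] - ter_nodes[kt]
            if td <= 0.0:
                continue
            for i in range(vp_nodes.shape[0]):
                for j in range(w_nodes.shape[0]):
                    if upper:
                        f = fpt_density_unit(td, -vp_nodes[i], ap, 1.0 - w_nodes[j], eps)
                    else:
                        f = fpt_density_unit(td, vp_nodes[i], ap, w_nodes[j], eps)
                    acc += tw[kt] * vw[i] * ww[j] * f
        out[it] = acc
    return out


@njit(cache=True)
def cdf_nodes(ts, upper, vp_nodes, vw, w_nodes, ww, ter_nodes, tw, ap, eps):
    nw = w_nodes.shape[0]
    nv = vp_nodes.shape[0]
    nt = ts.shape[0]
    out = np.zeros(nt)
    # tables shared across times and non-decision nodes: sines for the
    # spectral branch, absorption probabilities and drift prefactors per
    # (drift, start) node pair
    sin_tab = np.empty((nw, _MAX_SPECTRAL_TERMS + 1))
    for j in range(nw):
        wj = 1.0 - w_nodes[j] if upper else w_nodes[j]
        for m in range(1, _MAX_SPECTRAL_TERMS + 1):
            sin_tab[j, m] = math.sin(m * math.pi * wj)
    pl_tab = np.empty((nv, nw))
    pref_tab = np.empty((nv, nw))
    pmax_tab = np.empty(nv)
    for i in range(nv):
        vpi = -vp_nodes[i] if upper else vp_nodes[i]
        pm = 0.0
        for j in range(nw):
            wj = 1.0 - w_nodes[j] if upper else w_nodes[j]
            pl_tab[i, j] = p_lower_unit(vpi, ap, wj)
            e = -vpi * ap * wj
            pref_tab[i, j] = math.exp(e) if e < 700.0 else 1e300
            if pref_tab[i, j] > pm:
                pm = pref_tab[i, j]
        pmax_tab[i] = pm
    c = math.pi * math.pi / (ap * ap)
    two_pi_ap2 = 2.0 * math.pi / (ap * ap)
    svals = np.zeros(nw)
    for it in range(nt):
        acc = 0.0
        for kt in range(ter_nodes.shape[0]):
            td = ts[it] - ter_nodes[kt]
            if td <= 0.0:
                continue
            tau = td / (ap * ap)
            for i in range(nv):
                vpi = -vp_nodes[i] if upper else vp_nodes[i]
                if tau < TAU_SWITCH_VEC:
                    for j in range(nw):
                        wj = 1.0 - w_nodes[j] if upper else w_nodes[j]
                        acc += tw[kt] * vw[i] * ww[j] * _cdf_images_unit(td, vpi, ap, wj, eps)
                else:
                    # spectral branch: exp(-lam_m td) shared across start nodes
                    for j in range(nw):
                        svals[j] = 0.0
                    vpi2 = vpi * vpi
                    for m in range(1, _MAX_SPECTRAL_TERMS + 1):
                        lam = 0.5 * (vpi2 + c * m * m)
                        coef = two_pi_ap2 * m / (2.0 * lam)
                        em = math.exp(-lam * td)
                        if coef * em * pmax_tab[i] < eps * 0.1 and m >= 3:
                            break
                        ce = coef * em
                        for j in range(nw):
                            svals[j] += ce * sin_tab[j, m]
                    for j in range(nw):
                        fj = pl_tab[i, j] - pref_tab[i, j] * svals[j]
                        if fj < 0.0:
                            fj = 0.0
                        acc += tw[kt] * vw[i] * ww[j] * fj
        out[it] = acc
    return out


@njit(cache=True)
def prob_nodes(upper, vp_nodes, vw, w_nodes, ww, ap):
    """Absorption probability with drift/start variability."""
    acc = 0.0
    for i in range(vp_nodes.shape[0]):
        for j in range(w_nodes.shape[0]):
            if upper:
                p = p_lower_unit(-vp_nodes[i], ap, 1.0 - w_nodes[j])
            else:
                p = p_lower_unit(vp_nodes[i], ap, w_nodes[j])
            acc += vw[i] * ww[j] * p
    return acc


@njit(cache=True)
def cell_bin_probs(edges_up, edges_lo, vp_nodes, vw, w_nodes, ww,
                   ter_nodes, tw, ap, eps):
    """Multinomial bin probabilities for one condition cell.

    ``edges_up``/``edges_lo`` are interior RT edges (seconds) for the upper
    (left) and lower (right) boundary.  Returns the concatenated bin
    probabilities, upper bins first; each boundary contributes
    ``len(edges)+1`` bins and the total sums to 1 (within series tolerance).
    """
    n_up = edges_up.shape[0] + 1
    n_lo = edges_lo.shape[0] + 1
    out = np.empty(n_up + n_lo)

    p_up = prob_nodes(True, vp_nodes, vw, w_nodes, ww, ap)
    f_up = cdf_nodes(edges_up, True, vp_nodes, vw, w_nodes, ww, ter_nodes, tw, ap, eps)
    prev = 0.0
    for b in range(edges_up.shape[0]):
        out[b] = f_up[b] - prev
        prev = f_up[b]
    out[n_up - 1] = p_up - prev

    f_lo = cdf_nodes(edges_lo, False, vp_nodes, vw, w_nodes, ww, ter_nodes, tw, ap, eps)
    prev = 0.0
    for b in range(edges_lo.shape[0]):
        out[n_up + b] = f_lo[b] - prev
        prev = f_lo[b]
    out[n_up + n_lo - 1] = (1.0 - p_up) - prev

    for b in range(n_up + n_lo):
        if out[b] < 0.0:
            out[b] = 0.0
    return out


# ---------------------------------------------------------------------------
# Euler–Maruyama path simulator.
# ---------------------------------------------------------------------------

_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_DINV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, fastmath=True)
def euler_sim(vs, zs, a, s, dt, tmax, seed, bridge):
    """Simulate first-passage outcomes for per-trial drifts/starts.

    Returns (code, tdec): code 1 = upper boundary, 0 = lower, -1 = path did
    not absorb before tmax; tdec is the decision time (tmax when code=-1).

    With ``bridge`` enabled, a Brownian-bridge crossing test is applied at
    each step so that excursions beyond a boundary *between* grid points are
    detected; this removes the O(sqrt(dt)) first-passage bias of naive Euler
    stepping.

    Noise comes from an inlined xoshiro256+ stream (seeded by splitmix64
    from ``seed``) with polar-method Gaussians; per-step RNG in compiled
    code is the throughput bottleneck of the whole simulator.
    """
    # splitmix64 seeding of the xoshiro256+ state
    z = np.uint64(seed)
    st0 = np.uint64(0)
    st1 = np.uint64(0)
    st2 = np.uint64(0)
    st3 = np.uint64(0)
    for k in range(4):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & _U64_MASK
        r = z
        r = ((r ^ (r >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _U64_MASK
        r = ((r ^ (r >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _U64_MASK
        r = r ^ (r >> np.uint64(31))
        if k == 0:
            st0 = r
        elif k == 1:
            st1 = r
        elif k == 2:
            st2 = r
        else:
            st3 = r

    n = vs.shape[0]
    code = np.empty(n, dtype=np.int8)
    tdec = np.empty(n)
    sq = s * math.sqrt(dt)
    band = 6.0 * sq
    inv = 1.0 / (s * s * dt)
    spare = 0.0
    have_spare = False
    for i in range(n):
        x = zs[i]
        vdt = vs[i] * dt
        t = 0.0
        ci = np.int8(-1)
        while t < tmax:
            # polar-method standard normal from the inline uniform stream
            if have_spare:
                g = spare
                have_spare = False
            else:
                while True:
                    r0 = (st0 + st3) & _U64_MASK
                    tt = (st1 << np.uint64(17)) & _U64_MASK
                    st2 ^= st0
                    st3 ^= st1
                    st1 ^= st2
                    st0 ^= st3
                    st2 ^= tt
                    st3 = ((st3 << np.uint64(45)) | (st3 >> np.uint64(19))) & _U64_MASK
                    u1 = float(r0 >> np.uint64(11)) * _DINV53 * 2.0 - 1.0
                    r0 = (st0 + st3) & _U64_MASK
                    tt = (st1 << np.uint64(17)) & _U64_MASK
                    st2 ^= st0
                    st3 ^= st1
                    st1 ^= st2
                    st0 ^= st3
                    st2 ^= tt
                    st3 = ((st3 << np.uint64(45)) | (st3 >> np.uint64(19))) & _U64_MASK
                    u2 = float(r0 >> np.uint64(11)) * _DINV53 * 2.0 - 1.0
                    rr = u1 * u1 + u2 * u2
                    if 0.0 < rr < 1.0:
                        fac = math.sqrt(-2.0 * math.log(rr) / rr)
                        g = u1 * fac
                        spare = u2 * fac
                        have_spare = True
                        break
            xo = x
            x = x + vdt + sq * g
            t += dt
            if x >= a:
                ci = np.int8(1)
                break
            if x <= 0.0:
                ci = np.int8(0)
                break
            if bridge:
                if a - x < band and a - xo < band:
                    r0 = (st0 + st3) & _U64_MASK
                    tt = (st1 << np.uint64(17)) & _U64_MASK
                    st2 ^= st0
                    st3 ^= st1
                    st1 ^= st2
                    st0 ^= st3
                    st2 ^= tt
                    st3 = ((st3 << np.uint64(45)) | (st3 >> np.uint64(19))) & _U64_MASK
                    u = float(r0 >> np.uint64(11)) * _DINV53
                    if u < math.exp(-2.0 * (a - xo) * (a - x) * inv):
                        ci = np.int8(1)
                        break
                if x < band and xo < band:
                    r0 = (st0 + st3) & _U64_MASK
                    tt = (st1 << np.uint64(17)) & _U64_MASK
                    st2 ^= st0
                    st3 ^= st1
                    st1 ^= st2
                    st0 ^= st3
                    st2 ^= tt
                    st3 = ((st3 << np.uint64(45)) | (st3 >> np.uint64(19))) & _U64_MASK
                    u = float(r0 >> np.uint64(11)) * _DINV53
                    if u < math.exp(-2.0 * xo * x * inv):
                        ci = np.int8(0)
                        break
        code[i] = ci
        tdec[i] = t if ci >= 0 else tmax
    return code, tdec
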