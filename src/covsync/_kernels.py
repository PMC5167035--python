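"""Low-level numerical kernels for the Tweedie likelihood.

The compound Poisson-gamma series and the panel log-likelihood loop are the
hot path of the samplers; both are compiled with numba when it is available
and fall back to pure Python otherwise (same code, much slower).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


#: hard cap on the number of series terms summed on either side of the peak
MAX_TERMS = 10_000
#: terms smaller than this, relative to the running sum, stop the summation
REL_TOL = 1e-12
#: stand-in for log(0) that still sums without producing NaN
LOG_ZERO = -1.0e300


@njit(cache=True)
def tweedie_logpdf(y: float, mu: float, phi: float, p: float) -> float:
    """Log density of Tw(mu, phi, p) for p in (1, 2) at a single point.

    At y == 0 this is the log of the discrete mass exp(-lambda); for y > 0
    the compound Poisson-gamma series is summed outward from its largest
    term until terms fall below REL_TOL relative to the running sum.
    Returns NaN if the series fails to converge within MAX_TERMS.
    """
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    if y == 0.0:
        return -lam
    if mu < 1e-100 or not math.isfinite(lam):
        return LOG_ZERO
    alpha = (2.0 - p) / (p - 1.0)  # gamma shape per Poisson event
    tau = phi * (p - 1.0) * mu ** (p - 1.0)  # gamma scale per event
    base = -lam - y / tau - math.log(y)
    # log of the j-dependent factor: j*log(lam) + j*alpha*log(y/tau)
    c = math.log(lam) + alpha * (math.log(y) - math.log(tau))
    # index of the maximal term (Dunn & Smyth)
    jmax = y ** (2.0 - p) / (phi * (2.0 - p))
    j0 = int(jmax)
    if j0 < 1:
        j0 = 1
    tpeak = j0 * c - math.lgamma(j0 + 1.0) - math.lgamma(j0 * alpha)
    s = 0.0
    converged_up = False
    j = j0
    while j <= j0 + MAX_TERMS:
        t = j * c - math.lgamma(j + 1.0) - math.lgamma(j * alpha)
        if t > tpeak:  # peak estimate was off: rescale to avoid overflow
            s = s * math.exp(tpeak - t)
            tpeak = t
        e = math.exp(t - tpeak)
        s += e
        if j > j0 and e < REL_TOL * s:
            converged_up = True
            break
        j += 1
    if not converged_up:
        return math.nan
    j = j0 - 1
    while j >= 1:
        t = j * c - math.lgamma(j + 1.0) - math.lgamma(j * alpha)
        if t > tpeak:
            s = s * math.exp(tpeak - t)
            tpeak = t
        e = math.exp(t - tpeak)
        s += e
        if e < REL_TOL * s:
            break
        j -= 1
    res = base + tpeak + math.log(s)
    if not math.isfinite(res):
        return math.nan
    return res


@njit(cache=True)
def tweedie_logpdf_array(y, mu, phi, p, out):
    for k in range(y.shape[0]):
        out[k] = tweedie_logpdf(y[k], mu[k], phi, p)
    return out


#: per-species lgamma tables are built up to this many series terms; larger
#: indices fall back to direct lgamma evaluation (identical values, slower)
TABLE_CAP = 20_000


@njit(cache=True)
def _logpdf_tabulated(y, mu, phi, p, alpha, lgfact, lgalpha):
    """tweedie_logpdf with lgamma(j+1) / lgamma(j*alpha) read from tables;
    bitwise identical to the direct version (tables hold the same lgamma
    values) but amortizes the transcendental calls across observations."""
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    if y == 0.0:
        return -lam
    if mu < 1e-100 or not math.isfinite(lam):
        return LOG_ZERO
    tau = phi * (p - 1.0) * mu ** (p - 1.0)
    base = -lam - y / tau - math.log(y)
    c = math.log(lam) + alpha * (math.log(y) - math.log(tau))
    j0 = int(y ** (2.0 - p) / (phi * (2.0 - p)))
    if j0 < 1:
        j0 = 1
    n_tab = lgfact.shape[0]
    if j0 < n_tab:
        tpeak = j0 * c - lgfact[j0] - lgalpha[j0]
    else:
        tpeak = j0 * c - math.lgamma(j0 + 1.0) - math.lgamma(j0 * alpha)
    s = 0.0
    converged_up = False
    j = j0
    while j <= j0 + MAX_TERMS:
        if j < n_tab:
            t = j * c - lgfact[j] - lgalpha[j]
        else:
            t = j * c - math.lgamma(j + 1.0) - math.lgamma(j * alpha)
        if t > tpeak:  # peak estimate was off: rescale to avoid overflow
            s = s * math.exp(tpeak - t)
            tpeak = t
        e = math.exp(t - tpeak)
        s += e
        if j > j0 and e < REL_TOL * s:
            converged_up = True
            break
        j += 1
    if not converged_up:
        return math.nan
    j = j0 - 1
    while j >= 1:
        if j < n_tab:
            t = j * c - lgfact[j] - lgalpha[j]
        else:
            t = j * c - math.lgamma(j + 1.0) - math.lgamma(j * alpha)
        if t > tpeak:
            s = s * math.exp(tpeak - t)
            tpeak = t
        e = math.exp(t - tpeak)
        s += e
        if e < REL_TOL * s:
            break
        j -= 1
    res = base + tpeak + math.log(s)
    if not math.isfinite(res):
        return math.nan
    return res


@njit(cache=True)
def panel_loglik(
    y,  # (n_s, N) observations, sites concatenated
    v,  # (N, d_v) time-varying covariates, same layout
    offsets,  # (n_sites + 1,) site slice boundaries into the N axis
    mu0,  # (n_s, n_sites) augmented initial means
    eps,  # (n_sites,) synchronous random effects
    delta,  # (n_s, n_sites) asynchronous random effects
    gamma_sp,  # (n_s, d_v) per-species time-varying coefficients
    nu,  # (n_s, n_s) interaction matrix, 0 where excluded; nu[l, s] acts on s
    phi_sp,  # (n_s,) per-species Tweedie dispersion
    p_sp,  # (n_s,) per-species Tweedie index
    species_mask,  # (n_s,) bool: which species' rows to (re)compute
    lgfact,  # (n_fact,) lgamma(j + 1) lookup, shared across species
    lgalpha,  # (n_s, n_tab_max) lgamma(j * alpha_s) lookup rows
    n_tab,  # (n_s,) valid prefix length of each lgalpha row
    out,  # (n_s, n_sites) log-likelihood contributions, written in place
):
    """Per-(species, site) log-likelihood of the growth-rate recursion.

    log mu[s,i,t] accumulates v[i,t]'gamma{s} + sum_l nu[l,s]*ylag[l] +
    eps[i] + delta[s,i] from the augmented mu0[s,i]; the lagged regressor is
    mu0[l,i] in the first observed year and the observed count thereafter.
    Numerically degenerate states (overflowing mu, non-convergent series)
    contribute LOG_ZERO so Metropolis-Hastings simply rejects them.
    """
    n_s = y.shape[0]
    n_sites = offsets.shape[0] - 1
    d_v = v.shape[1]
    for s in range(n_s):
        if not species_mask[s]:
            continue
        phi = phi_sp[s]
        p = p_sp[s]
        alpha = (2.0 - p) / (p - 1.0)
        nt = min(n_tab[s], lgfact.shape[0])
        lgf = lgfact[:nt]
        lga = lgalpha[s, :nt]
        for i in range(n_sites):
            o0 = offsets[i]
            L = offsets[i + 1] - o0
            if mu0[s, i] <= 0.0:
                out[s, i] = LOG_ZERO
                continue
            logmu = math.log(mu0[s, i])
            ll = 0.0
            for k in range(L):
                inc = eps[i] + delta[s, i]
                for j in range(d_v):
                    inc += v[o0 + k, j] * gamma_sp[s, j]
                for l in range(n_s):
                    nls = nu[l, s]
                    if nls != 0.0:
                        ylag = mu0[l, i] if k == 0 else y[l, o0 + k - 1]
                        inc += nls * ylag
                logmu += inc
                if not (-230.0 < logmu < 230.0):  # mu outside ~[1e-100, 1e100]
                    ll = LOG_ZERO
                    break
                lp = _logpdf_tabulated(
                    y[s, o0 + k], math.exp(logmu), phi, p, alpha, lgf, lga
                )
                if math.isnan(lp):
                    ll = LOG_ZERO
                    break
                ll += lp
            out[s, i] = ll
    return out
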