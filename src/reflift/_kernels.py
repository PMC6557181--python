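"""Compiled numerical kernels for the hot paths.

Everything here is called ~10^5-10^6 times per annealing run, so complex
arithmetic is spelled out on real/imaginary pairs to keep values in registers
and let LLVM vectorise.  The Python-facing modules (`abeles`, `anneal`) wrap
these with validated, documented interfaces; nothing in here validates input.
"""

import math

import numpy as np
from numba import njit

_FOUR_PI = 4.0 * math.pi


@njit(cache=True, fastmath=True)
def abeles_matrix(q, thick, sld, rough, out):
    """Specular reflectivity of a stratified stack via 2x2 characteristic
    matrices.

    q : (nq,) momentum transfer, 1/Angstrom (> 0)
    thick : (L,) interior layer thicknesses, Angstrom
    sld : (L+2,) real SLDs, fronting..backing, 1/Angstrom^2
    rough : (L+1,) Nevot-Croce interfacial roughnesses, Angstrom (0 = sharp)
    out : (nq,) filled with R(q)
    """
    nq = q.shape[0]
    L = thick.shape[0]
    s0 = sld[0]
    for iq in range(nq):
        qq = q[iq]
        k2 = qq * qq * 0.25
        knr = qq * 0.5  # wavevector in the fronting medium
        kni = 0.0
        m00r = 1.0
        m00i = 0.0
        m01r = 0.0
        m01i = 0.0
        m10r = 0.0
        m10i = 0.0
        m11r = 1.0
        m11i = 0.0
        dprev = 0.0
        for n in range(L + 1):
            rad = k2 - _FOUR_PI * (sld[n + 1] - s0)
            if rad >= 0.0:
                k1r = math.sqrt(rad)
                k1i = 0.0
            else:
                # principal branch, positive imaginary part: decaying
                # evanescent wave below the critical edge
                k1r = 0.0
                k1i = math.sqrt(-rad)
            dr = knr + k1r
            di = kni + k1i
            den = dr * dr + di * di
            if den == 0.0:
                rr = 0.0
                ri = 0.0
            else:
                nr = knr - k1r
                ni = kni - k1i
                rr = (nr * dr + ni * di) / den
                ri = (ni * dr - nr * di) / den
            sig = rough[n]
            if sig > 0.0:
                # r *= exp(-2 k_n k_{n+1} sigma^2)
                pr = knr * k1r - kni * k1i
                pi = knr * k1i + kni * k1r
                wr = -2.0 * pr * sig * sig
                wi = -2.0 * pi * sig * sig
                ex = math.exp(wr)
                cr = ex * math.cos(wi)
                ci = ex * math.sin(wi)
                t = rr * cr - ri * ci
                ri = rr * ci + ri * cr
                rr = t
            # phase across the layer above this interface (zero for fronting)
            br = knr * dprev
            bi = kni * dprev
            ea = math.exp(bi)
            cb = math.cos(br)
            sb = math.sin(br)
            epr = ea * cb
            epi = -ea * sb  # e^{-i beta}
            eb = 1.0 / ea
            emr = eb * cb
            emi = eb * sb  # e^{+i beta}
            c01r = rr * epr - ri * epi
            c01i = rr * epi + ri * epr
            c10r = rr * emr - ri * emi
            c10i = rr * emi + ri * emr
            t00r = m00r * epr - m00i * epi + m01r * c10r - m01i * c10i
            t00i = m00r * epi + m00i * epr + m01r * c10i + m01i * c10r
            t01r = m00r * c01r - m00i * c01i + m01r * emr - m01i * emi
            t01i = m00r * c01i + m00i * c01r + m01r * emi + m01i * emr
            t10r = m10r * epr - m10i * epi + m11r * c10r - m11i * c10i
            t10i = m10r * epi + m10i * epr + m11r * c10i + m11i * c10r
            t11r = m10r * c01r - m10i * c01i + m11r * emr - m11i * emi
            t11i = m10r * c01i + m10i * c01r + m11r * emi + m11i * emr
            m00r = t00r
            m00i = t00i
            m01r = t01r
            m01i = t01i
            m10r = t10r
            m10i = t10i
            m11r = t11r
            m11i = t11i
            knr = k1r
            kni = k1i
            if n < L:
                dprev = thick[n]
        den = m00r * m00r + m00i * m00i
        out[iq] = (m10r * m10r + m10i * m10i) / den
    return out


@njit(cache=True, fastmath=True)
def smeared_profiles(zb, plat_rho, plat_h, sigma, zsamp, dry, hyd, estep):
    """Error-function-smeared dry-SLD and hydration profiles at `zsamp`.

    zb : (N+1,) internal boundary positions 0..D
    plat_rho : (N+1,) plateau values [rho_fronting, rho_1 .. rho_N]; the final
        step at z = D toward the backing is *not* applied here -- its smeared
        unit step is returned in `estep` so the caller can add the
        contrast-dependent tail (rho_solvent - rho_N) * estep.
    plat_h : (N+2,) plateau values [0, h_1 .. h_N, 1]
    """
    n = zsamp.shape[0]
    nb = zb.shape[0]
    inv = 1.0 / (math.sqrt(2.0) * sigma)
    for i in range(n):
        z = zsamp[i]
        r = plat_rho[0]
        h = plat_h[0]
        for b in range(nb):
            x = (z - zb[b]) * inv
            if x > 6.0:
                w = 1.0
            elif x < -6.0:
                w = 0.0
            else:
                w = 0.5 * (1.0 + math.erf(x))
            if b < nb - 1:
                r += (plat_rho[b + 1] - plat_rho[b]) * w
            else:
                estep[i] = w
            h += (plat_h[b + 1] - plat_h[b]) * w
        dry[i] = r
        hyd[i] = h


@njit(cache=True, fastmath=True)
def forward_logsmear(qfine, thick, sld, rough, idx, w4, wg, rs, logbuf):
    """Exact reflectivity on the fine log-q grid, then resolution smearing by
    Gaussian-weighted p-point average with cubic interpolation in
    (ln q, ln R)."""
    abeles_matrix(qfine, thick, sld, rough, logbuf)
    n = logbuf.shape[0]
    for i in range(n):
        v = logbuf[i]
        if v < 1e-300:
            v = 1e-300
        logbuf[i] = math.log(v)
    nd = idx.shape[0]
    p = idx.shape[1]
    for j in range(nd):
        acc = 0.0
        for a in range(p):
            i0 = idx[j, a]
            v0 = logbuf[i0]
            v1 = logbuf[i0 + 1]
            v2 = logbuf[i0 + 2]
            v3 = logbuf[i0 + 3]
            lo = w4[j, a, 0] * v0 + w4[j, a, 1] * v1 + w4[j, a, 2] * v2 + w4[j, a, 3] * v3
            # clamp to the stencil range: the negative lobes of the cubic
            # must not amplify the floored log at exact reflectivity nulls
            hi = v0
            if v1 > hi:
                hi = v1
            if v2 > hi:
                hi = v2
            if v3 > hi:
                hi = v3
            lw = v0
            if v1 < lw:
                lw = v1
            if v2 < lw:
                lw = v2
            if v3 < lw:
                lw = v3
            if lo > hi:
                lo = hi
            elif lo < lw:
                lo = lw
            acc += wg[a] * math.exp(lo)
        rs[j] = acc


@njit(cache=True, fastmath=True)
def score_model(
    rho,
    h,
    sigma,
    rho0,
    zb,
    zsamp,
    thick,
    rho_solv,
    qfine,
    nfine,
    idx,
    w4,
    wg,
    ndata,
    q4,
    q4rexp,
    logrexp,
    inorm,
    plat_rho,
    plat_h,
    dry,
    hyd,
    estep,
    sld,
    rough0,
    logbuf,
    rs,
):
    """Composite score f: per contrast the mean squared normalised q^4 R
    difference plus the mean squared log-R difference, averaged over
    contrasts."""
    N = rho.shape[0]
    plat_rho[0] = rho0
    for n in range(N):
        plat_rho[n + 1] = rho[n]
    plat_h[0] = 0.0
    for n in range(N):
        plat_h[n + 1] = h[n]
    plat_h[N + 1] = 1.0
    smeared_profiles(zb, plat_rho, plat_h, sigma, zsamp, dry, hyd, estep)
    C = rho_solv.shape[0]
    L = zsamp.shape[0]
    f = 0.0
    for c in range(C):
        rsolv = rho_solv[c]
        sld[0] = rho0
        sld[L + 1] = rsolv
        for i in range(L):
            hh = hyd[i]
            sld[i + 1] = dry[i] * (1.0 - hh) + hh * rsolv
        nf = nfine[c]
        forward_logsmear(qfine[c, :nf], thick, sld, rough0, idx[c], w4[c], wg,
                         rs, logbuf[:nf])
        nd = ndata[c]
        s1 = 0.0
        s2 = 0.0
        for j in range(nd):
            y = q4[c, j] * rs[j]
            dd = y - q4rexp[c, j]
            s1 += dd * dd
            dl = math.log(rs[j]) - logrexp[c, j]
            s2 += dl * dl
        f += (s1 / nd) * inorm[c] * inorm[c] + s2 / nd
    return f / C


@njit(cache=True)
def anneal_loop(
    seed,
    rho,
    h,
    sigma_init,
    rho_min,
    rho_max,
    smin,
    smax,
    free_rho,
    free_h,
    p_rho,
    p_h,
    local_frac,
    local_width,
    t0,
    trials_per_t,
    cooling,
    stop_rejections,
    t_min,
    max_trials,
    randomize_start,
    # score data
    rho0,
    zb,
    zsamp,
    thick,
    rho_solv,
    qfine,
    nfine,
    idx,
    w4,
    wg,
    ndata,
    q4,
    q4rexp,
    logrexp,
    inorm,
    plat_rho,
    plat_h,
    dry,
    hyd,
    estep,
    sld,
    rough0,
    logbuf,
    rs,
    # outputs
    best_rho,
    best_h,
    trace_T,
    trace_fcur,
    trace_fbest,
    trace_acc,
):
    """Metropolis simulated annealing on (rho_n, h_n, sigma).

    Each trial changes exactly one randomly chosen free parameter within its
    admissible interval: with probability `local_frac` by a uniform step of
    half-width `local_width` times the interval (clipped to the bounds),
    otherwise by a fresh uniform draw over the whole interval.  A trial is
    accepted when df <= 0 or with probability exp(-df/T); the run stops after
    `stop_rejections` consecutive rejections (global counter across
    temperature decrements).

    Returns (best_f, best_sigma, f_final, sigma_final, n_temps, n_trials,
    abort_flag).
    """
    np.random.seed(seed)
    nfr = free_rho.shape[0]
    nfh = free_h.shape[0]
    if randomize_start != 0:
        for ii in range(nfr):
            rho[free_rho[ii]] = rho_min + (rho_max - rho_min) * np.random.random()
        for ii in range(nfh):
            h[free_h[ii]] = np.random.random()
    sigma = sigma_init

    def _score(rr, hh, ss):
        return score_model(
            rr, hh, ss, rho0, zb, zsamp, thick, rho_solv, qfine, nfine, idx,
            w4, wg,
            ndata, q4, q4rexp, logrexp, inorm, plat_rho, plat_h, dry, hyd,
            estep, sld, rough0, logbuf, rs,
        )

    f = _score(rho, h, sigma)
    best_f = f
    best_sigma = sigma
    for i in range(rho.shape[0]):
        best_rho[i] = rho[i]
        best_h[i] = h[i]

    T = t0
    consec = 0
    trials = 0
    itemp = 0
    stop = False
    while not stop:
        nacc = 0
        for _ in range(trials_per_t):
            u = np.random.random()
            local = np.random.random() < local_frac
            if u < p_rho and nfr > 0:
                m = int(np.random.random() * nfr)
                if m >= nfr:
                    m = nfr - 1
                ilay = free_rho[m]
                old = rho[ilay]
                if local:
                    new = old + (2.0 * np.random.random() - 1.0) * local_width * (
                        rho_max - rho_min
                    )
                    if new < rho_min:
                        new = rho_min
                    elif new > rho_max:
                        new = rho_max
                else:
                    new = rho_min + (rho_max - rho_min) * np.random.random()
                rho[ilay] = new
                kind = 0
            elif u < p_rho + p_h and nfh > 0:
                m = int(np.random.random() * nfh)
                if m >= nfh:
                    m = nfh - 1
                ilay = free_h[m]
                old = h[ilay]
                if local:
                    new = old + (2.0 * np.random.random() - 1.0) * local_width
                    if new < 0.0:
                        new = 0.0
                    elif new > 1.0:
                        new = 1.0
                else:
                    new = np.random.random()
                h[ilay] = new
                kind = 1
            else:
                ilay = -1
                old = sigma
                if local:
                    new = sigma + (2.0 * np.random.random() - 1.0) * local_width * (
                        smax - smin
                    )
                    if new < smin:
                        new = smin
                    elif new > smax:
                        new = smax
                    sigma = new
                else:
                    sigma = smin + (smax - smin) * np.random.random()
                kind = 2
            fnew = _score(rho, h, sigma)
            trials += 1
            if not math.isfinite(fnew):
                return best_f, best_sigma, f, sigma, itemp, trials, 1
            df = fnew - f
            accept = False
            if df <= 0.0:
                accept = True
            elif T > 0.0:
                arg = -df / T
                if arg > -700.0 and np.random.random() < math.exp(arg):
                    accept = True
            if accept:
                f = fnew
                nacc += 1
                consec = 0
                if f < best_f:
                    best_f = f
                    best_sigma = sigma
                    for i in range(rho.shape[0]):
                        best_rho[i] = rho[i]
                        best_h[i] = h[i]
            else:
                if kind == 0:
                    rho[ilay] = old
                elif kind == 1:
                    h[ilay] = old
                else:
                    sigma = old
                consec += 1
                if consec >= stop_rejections:
                    stop = True
                    break
            if trials >= max_trials:
                stop = True
                break
        trace_T[itemp] = T
        trace_fcur[itemp] = f
        trace_fbest[itemp] = best_f
        trace_acc[itemp] = nacc
        itemp += 1
        if itemp >= trace_T.shape[0]:
            stop = True
        T *= cooling
        if T < t_min:
            stop = True
    return best_f, best_sigma, f, sigma, itemp, trials, 0
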