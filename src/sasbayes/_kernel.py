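"""Compiled inner loops of the replica-exchange sampler.

Everything here is an implementation detail of :mod:`sasbayes.remc`.  The
kernels operate on flat per-replica state arrays and are written so that
LLVM can vectorize the hot loops:

* the sphere form factor is evaluated through a dense lookup table in
  ``x = q R`` (uniform spacing, linear interpolation; absolute error below
  ~1e-9, verified in the test suite), with an exact sin/cos fallback for
  arguments beyond the table;
* ``ln lambda`` inside the Poisson cost uses a branch-predicated
  exponent/mantissa split with an atanh-style polynomial (fdlibm
  coefficients, relative error ~1e-15), which vectorizes where libm's
  scalar ``log`` does not;
* data points are pre-permuted so that all ``y > 0`` points come first and
  the ``y ln lambda`` reduction runs branch-free over a prefix.

Randomness is injected from the caller as pre-drawn arrays (standard
normals, log-uniforms), so determinism is owned entirely by the Python
layer's ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LN2 = 0.6931471805599453
_SQRT2 = 1.4142135623730951
# fdlibm log() polynomial coefficients for s = (m-1)/(m+1)
_LG = (
    0.6666666666666735,
    0.3999999999940942,
    0.2857142874366239,
    0.22222198432149784,
    0.1818357216161805,
    0.15313837699209373,
    0.14798198605116586,
)


def build_phi2_table(xmax: float, h: float) -> np.ndarray:
    """Tabulate the squared sphere amplitude on a uniform grid in x = qR."""
    n = int(np.ceil(xmax / h)) + 2
    x = np.arange(n, dtype=float) * h
    out = np.empty(n)
    small = x < 1e-2
    xs = x[small]
    out[small] = (1.0 - xs**2 / 10.0 + xs**4 / 280.0) ** 2
    xl = x[~small]
    phi = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    out[~small] = phi * phi
    return out


@njit(cache=True, fastmath=True, inline="always")
def _fast_log(v: float) -> float:
    """Double-precision natural log via exponent/mantissa split."""
    bits = np.int64(np.float64(v).view(np.int64))
    e = float((bits >> 52) & 0x7FF) - 1023.0
    mb = (bits & np.int64(0x000FFFFFFFFFFFFF)) | np.int64(0x3FF0000000000000)
    m = np.int64(mb).view(np.float64)
    if m > _SQRT2:
        m *= 0.5
        e += 1.0
    t = (m - 1.0) / (m + 1.0)
    t2 = t * t
    p = t * (
        2.0
        + t2
        * (
            _LG[0]
            + t2
            * (
                _LG[1]
                + t2 * (_LG[2] + t2 * (_LG[3] + t2 * (_LG[4] + t2 * (_LG[5] + t2 * _LG[6]))))
            )
        )
    )
    return e * _LN2 + p


@njit(cache=True, fastmath=True, inline="always")
def _weighted_log_sum(buf, y, npos):
    """sum_{i < npos} y[i] * ln(buf[i]) (buf strictly positive)."""
    s = 0.0
    for i in range(npos):
        s += y[i] * _fast_log(buf[i])
    return s


@njit(cache=True, fastmath=True)
def _write_sorted(th_tr, R, S, Bv, s, l, K):
    """Record replica l's parameters with components sorted by radius
    (non-increasing) — the canonical label order.

    Sorting happens at output only.  Inside the chain the component labels
    wander freely: the priors are iid across components, so the unordered
    parameterization is exchangeable and sequential-scan Metropolis
    preserves it; re-sorting the *state* after each accepted move would
    break detailed balance of the per-site scan kernels.
    """
    # selection sort of component indices (K <= 4: negligible cost)
    taken = 0  # bitmask of already-placed components
    for pos in range(K):
        best = -1
        best_val = -1.0
        for k in range(K):
            if not (taken >> k) & 1 and R[l, k] > best_val:
                best_val = R[l, k]
                best = k
        taken |= 1 << best
        th_tr[s, l, pos] = R[l, best]
        th_tr[s, l, K + pos] = S[l, best]
    th_tr[s, l, 2 * K] = Bv[l]


@njit(cache=True, fastmath=True)
def _sweep(
    R, S, Bv, C, I, E, LPRI,
    betas, q, y, npos, sy, T,
    tab, inv_h, xlim, qmax,
    aR, sR, aS, sS, aB, sB,
    steps, z, lu, acc, att,
    buf, cnew,
):
    """One Metropolis sweep: every scalar parameter of every replica.

    Proposals are additive in log space (multiplicative in natural space);
    the log-normal Jacobian is folded into the prior increment so the
    Gamma-prior acceptance term needs no extra transcendentals:
    for Gamma(a, s), d(log prior) + d(log Jacobian) = a*dz - dv/s.
    """
    L, K = R.shape
    N = q.shape[0]
    P = 2 * K + 1
    logT = np.log(T)
    for l in range(L):
        bl = betas[l]
        for j in range(P):
            att[l, j] += 1
            dz = steps[l, j] * z[l, j]
            fac = np.exp(dz)
            if j < K:
                v = R[l, j]
                vp = v * fac
                dpj = aR * dz - (vp - v) / sR
                sjv = S[l, j] * vp * vp * vp  # scale times particle volume R^3
                if vp * qmax <= xlim:
                    for i in range(N):
                        t = q[i] * vp * inv_h
                        jj = np.int64(t)
                        w = t - jj
                        p2 = tab[jj] * (1.0 - w) + tab[jj + 1] * w
                        cn = sjv * p2
                        cnew[i] = cn
                        buf[i] = I[l, i] - C[l, j, i] + cn
                else:
                    for i in range(N):
                        xx = q[i] * vp
                        ph = 3.0 * (np.sin(xx) - xx * np.cos(xx)) / (xx * xx * xx)
                        cn = sjv * ph * ph
                        cnew[i] = cn
                        buf[i] = I[l, i] - C[l, j, i] + cn
            elif j < 2 * K:
                k = j - K
                v = S[l, k]
                vp = v * fac
                dpj = aS * dz - (vp - v) / sS
                for i in range(N):
                    cn = fac * C[l, k, i]
                    cnew[i] = cn
                    buf[i] = I[l, i] - C[l, k, i] + cn
            else:
                v = Bv[l]
                vp = v * fac
                dpj = aB * dz - (vp - v) / sB
                db = vp - v
                for i in range(N):
                    buf[i] = I[l, i] + db
            s1 = 0.0
            for i in range(N):
                s1 += buf[i]
            s2 = _weighted_log_sum(buf, y, npos)
            Enew = (T * s1 - sy * logT - s2) / N
            if lu[l, j] < -bl * N * (Enew - E[l]) + dpj:
                acc[l, j] += 1
                E[l] = Enew
                LPRI[l] += dpj - dz
                for i in range(N):
                    I[l, i] = buf[i]
                if j < K:
                    R[l, j] = vp
                    for i in range(N):
                        C[l, j, i] = cnew[i]
                elif j < 2 * K:
                    k = j - K
                    S[l, k] = vp
                    for i in range(N):
                        C[l, k, i] = cnew[i]
                else:
                    Bv[l] = vp


@njit(cache=True, fastmath=True)
def _exchange(R, S, Bv, C, I, E, LPRI, betas, N, start, lu_ex, eacc, eatt):
    """Neighbor swaps for pairs (l, l+1), l = start, start+2, ...

    Swap probability min(1, exp(N * (beta_{l+1} - beta_l) * (E_{l+1} - E_l)));
    the shared prior cancels, so only the cost enters.
    """
    L = betas.shape[0]
    K = R.shape[1]
    Np = I.shape[1]
    for l in range(start, L - 1, 2):
        eatt[l] += 1
        d = N * (betas[l + 1] - betas[l]) * (E[l + 1] - E[l])
        if lu_ex[l] < d:
            eacc[l] += 1
            for k in range(K):
                R[l, k], R[l + 1, k] = R[l + 1, k], R[l, k]
                S[l, k], S[l + 1, k] = S[l + 1, k], S[l, k]
                for i in range(Np):
                    tmp = C[l, k, i]
                    C[l, k, i] = C[l + 1, k, i]
                    C[l + 1, k, i] = tmp
            Bv[l], Bv[l + 1] = Bv[l + 1], Bv[l]
            for i in range(Np):
                tmp = I[l, i]
                I[l, i] = I[l + 1, i]
                I[l + 1, i] = tmp
            E[l], E[l + 1] = E[l + 1], E[l]
            LPRI[l], LPRI[l + 1] = LPRI[l + 1], LPRI[l]


@njit(cache=True, fastmath=True)
def _refresh_intensity(C, I, Bv):
    """Recompute I from C and B, clearing accumulated round-off drift."""
    L, K, N = C.shape
    for l in range(L):
        for i in range(N):
            s = Bv[l]
            for k in range(K):
                s += C[l, k, i]
            I[l, i] = s


@njit(cache=True, fastmath=True)
def _chi2_top(I, y, T):
    """Pearson chi-squared of the beta = 1 replica against the counts."""
    N = I.shape[1]
    top = I.shape[0] - 1
    s = 0.0
    for i in range(N):
        lam = T * I[top, i]
        r = y[i] - lam
        s += r * r / lam
    return s


@njit(cache=True, fastmath=True)
def _run_chunk(
    R, S, Bv, C, I, E, LPRI,
    betas, q, y, npos, sy, T, Ndata,
    tab, inv_h, xlim, qmax,
    aR, sR, aS, sS, aB, sB,
    steps, Z, LU, LUX, parities,
    acc, att, eacc, eatt,
    buf, cnew,
    record, th_tr, E_tr, LP_tr, chi2_tr,
):
    """Run ``Z.shape[0]`` sweeps; optionally record traces per sweep.

    ``parities[s]`` selects the exchange parity after sweep ``s``
    (-1: no exchange this sweep).
    """
    nsw = Z.shape[0]
    L, K = R.shape
    for s in range(nsw):
        _sweep(
            R, S, Bv, C, I, E, LPRI,
            betas, q, y, npos, sy, T,
            tab, inv_h, xlim, qmax,
            aR, sR, aS, sS, aB, sB,
            steps, Z[s], LU[s], acc, att,
            buf, cnew,
        )
        if parities[s] >= 0:
            _exchange(R, S, Bv, C, I, E, LPRI, betas, Ndata, parities[s], LUX[s], eacc, eatt)
        if record:
            for l in range(L):
                _write_sorted(th_tr, R, S, Bv, s, l, K)
                E_tr[s, l] = E[l]
                LP_tr[s, l] = LPRI[l]
            chi2_tr[s] = _chi2_top(I, y, T)
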