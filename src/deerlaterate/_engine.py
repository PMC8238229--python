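"""Jit-compiled inner loop of the simulated-annealing multilateration.

Everything here operates on flat padded arrays prepared by
``multilateration._build_inputs``. Per trial, exactly one rotamer weight
changes, so each affected trace's distance histogram is updated
incrementally and its background parameters are re-fit with a
warm-started damped Gauss-Newton (Levenberg-Marquardt) step. The
simulated decay is evaluated through a precomputed per-trace operator
``A = K @ (M G)`` (dipolar kernel x masked broadening matrix), so

    V_intra(t) = (A @ h) / (s . h)

with ``h`` the raw weighted pair-distance histogram and ``s`` the
column sums of ``M G`` (kept probability mass); the normalization of
``h`` cancels in the ratio.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LAM_LO = 1e-4
_LAM_HI = 1.0
_K_LO = 1e-6
_K_HI = 50.0
_D_LO = 2.0
_D_HI = 3.5
_BAD_SSR = 1e280


@njit(cache=True)
def _bg_eval(t, nt, vexp, v, lam, k, d):
    ssr = 0.0
    e = d / 3.0
    for i in range(nt):
        b = np.exp(-((k * t[i]) ** e))
        r = vexp[i] - b * (1.0 - lam * (1.0 - v[i]))
        ssr += r * r
    return ssr


@njit(cache=True)
def _bg_gn(t, nt, vexp, v, lam, k, d, free_d, n_iter):
    """Damped Gauss-Newton on (lam, k[, d]), box-projected; returns raw SSR."""
    p0, p1, p2 = lam, k, d
    ssr = _bg_eval(t, nt, vexp, v, p0, p1, p2)
    mu = 1e-3
    for _ in range(n_iter):
        e = p2 / 3.0
        a00 = a01 = a02 = a11 = a12 = a22 = 0.0
        g0 = g1 = g2 = 0.0
        for i in range(nt):
            kt = p1 * t[i]
            g = kt**e
            b = np.exp(-g)
            f = 1.0 - p0 * (1.0 - v[i])
            r = vexp[i] - b * f
            j0 = -b * (1.0 - v[i])
            j1 = -b * f * (e * g / p1)
            a00 += j0 * j0
            a01 += j0 * j1
            a11 += j1 * j1
            g0 += j0 * r
            g1 += j1 * r
            if free_d:
                if kt > 1e-12:
                    j2 = -b * f * (g * np.log(kt) / 3.0)
                else:
                    j2 = 0.0
                a02 += j0 * j2
                a12 += j1 * j2
                a22 += j2 * j2
                g2 += j2 * r
        stepped = False
        for _try in range(4):
            d00 = a00 * (1.0 + mu)
            d11 = a11 * (1.0 + mu)
            if not free_d:
                det = d00 * d11 - a01 * a01
                if abs(det) < 1e-300:
                    break
                s0 = (d11 * g0 - a01 * g1) / det
                s1 = (-a01 * g0 + d00 * g1) / det
                s2 = 0.0
            else:
                d22 = a22 * (1.0 + mu) + 1e-12
                c00 = d11 * d22 - a12 * a12
                c01 = -(a01 * d22 - a12 * a02)
                c02 = a01 * a12 - d11 * a02
                det = d00 * c00 + a01 * c01 + a02 * c02
                if abs(det) < 1e-300:
                    break
                c11 = d00 * d22 - a02 * a02
                c12 = -(d00 * a12 - a01 * a02)
                c22 = d00 * d11 - a01 * a01
                s0 = (c00 * g0 + c01 * g1 + c02 * g2) / det
                s1 = (c01 * g0 + c11 * g1 + c12 * g2) / det
                s2 = (c02 * g0 + c12 * g1 + c22 * g2) / det
            q0 = min(max(p0 + s0, _LAM_LO), _LAM_HI)
            q1 = min(max(p1 + s1, _K_LO), _K_HI)
            q2 = min(max(p2 + s2, _D_LO), _D_HI) if free_d else p2
            ssr_new = _bg_eval(t, nt, vexp, v, q0, q1, q2)
            if ssr_new < ssr:
                p0, p1, p2, ssr = q0, q1, q2, ssr_new
                mu = max(mu / 3.0, 1e-8)
                stepped = True
                break
            mu *= 10.0
        if not stepped:
            break
    return p0, p1, p2, ssr


@njit(cache=True)
def _bg_grid(t, nt, vexp, v, lam_grid, k_grid, d_grid, free_d):
    """Coarse grid search followed by a full Gauss-Newton refinement."""
    best_ssr = 1e300
    bl, bk, bd = lam_grid[0], k_grid[0], d_grid[0]
    for di in range(d_grid.size):
        for li in range(lam_grid.size):
            for ki in range(k_grid.size):
                ssr = _bg_eval(t, nt, vexp, v, lam_grid[li], k_grid[ki], d_grid[di])
                if ssr < best_ssr:
                    best_ssr = ssr
                    bl, bk, bd = lam_grid[li], k_grid[ki], d_grid[di]
    return _bg_gn(t, nt, vexp, v, bl, bk, bd, free_d, 15)


@njit(cache=True)
def _calc_h(didx, nu, nv, wu, wv, h):
    h[:] = 0.0
    for a in range(nu):
        wa = wu[a]
        if wa != 0.0:
            for b in range(nv):
                if wv[b] != 0.0:
                    h[didx[a, b]] += wa * wv[b]


@njit(cache=True)
def _vintra(a_mat, svec, h, nt, out):
    den = 0.0
    for j in range(h.size):
        den += svec[j] * h[j]
    if den < 1e-280:
        return False
    num = np.dot(a_mat[:nt], h)
    for i in range(nt):
        out[i] = num[i] / den
    return True


@njit(cache=True)
def _refresh(
    w, res_off, u_res, v_res, nt_arr, tmat, vexp, sigma2, a3, svec, didx,
    lam_grid, k_grid, d_grid, free_d, lam, kk, dd, ssr, h, vwork,
):
    """Recompute histograms, V_intra, and a full background re-fit per trace.

    Takes the better of a warm Gauss-Newton continuation and the grid
    restart; returns the total noise-normalized SSR.
    """
    n_traces = u_res.size
    ssr_tot = 0.0
    for ti in range(n_traces):
        u = u_res[ti]
        v = v_res[ti]
        wu = w[res_off[u]:res_off[u + 1]]
        wv = w[res_off[v]:res_off[v + 1]]
        _calc_h(didx[ti], wu.size, wv.size, wu, wv, h[ti])
        nt = nt_arr[ti]
        if not _vintra(a3[ti], svec[ti], h[ti], nt, vwork):
            ssr[ti] = _BAD_SSR
        else:
            l1, k1, d1, raw1 = _bg_gn(
                tmat[ti], nt, vexp[ti], vwork, lam[ti], kk[ti], dd[ti], free_d, 15
            )
            l2, k2, d2, raw2 = _bg_grid(
                tmat[ti], nt, vexp[ti], vwork, lam_grid, k_grid, d_grid, free_d
            )
            if raw1 <= raw2:
                lam[ti], kk[ti], dd[ti] = l1, k1, d1
                ssr[ti] = raw1 / sigma2[ti]
            else:
                lam[ti], kk[ti], dd[ti] = l2, k2, d2
                ssr[ti] = raw2 / sigma2[ti]
        ssr_tot += ssr[ti]
    return ssr_tot


@njit(cache=True)
def _apply_weight_change(
    g, r, w_new, w, res_off, rot_res, u_res, v_res, nt_arr, tmat, vexp,
    sigma2, a3, svec, didx, res_tr_off, res_tr, free_d,
    lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb, vwork,
):
    """Set w[g] = w_new, update affected traces incrementally (histograms,
    V_intra, warm background re-fit), stash backups for reversal; returns
    the change in total noise-normalized SSR."""
    dw = w_new - w[g]
    w[g] = w_new
    local = g - res_off[r]
    dssr = 0.0
    for ei in range(res_tr_off[r], res_tr_off[r + 1]):
        ti = res_tr[ei]
        hb[ti, :] = h[ti, :]
        lamb[ti] = lam[ti]
        kb[ti] = kk[ti]
        db[ti] = dd[ti]
        ssrb[ti] = ssr[ti]
        u = u_res[ti]
        v = v_res[ti]
        if u == r:
            wv = w[res_off[v]:res_off[v + 1]]
            for b in range(wv.size):
                if wv[b] != 0.0:
                    h[ti, didx[ti, local, b]] += dw * wv[b]
        else:
            wu = w[res_off[u]:res_off[u + 1]]
            for a in range(wu.size):
                if wu[a] != 0.0:
                    h[ti, didx[ti, a, local]] += dw * wu[a]
        nt = nt_arr[ti]
        if not _vintra(a3[ti], svec[ti], h[ti], nt, vwork):
            ssr[ti] = _BAD_SSR
        else:
            l0, k0, d0, raw = _bg_gn(
                tmat[ti], nt, vexp[ti], vwork, lam[ti], kk[ti], dd[ti], free_d, 2
            )
            lam[ti] = l0
            kk[ti] = k0
            dd[ti] = d0
            ssr[ti] = raw / sigma2[ti]
        dssr += ssr[ti] - ssrb[ti]
    return dssr


@njit(cache=True)
def _revert_weight_change(
    g, r, w_old, w, res_tr_off, res_tr,
    lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb,
):
    w[g] = w_old
    for ei in range(res_tr_off[r], res_tr_off[r + 1]):
        ti = res_tr[ei]
        h[ti, :] = hb[ti, :]
        lam[ti] = lamb[ti]
        kk[ti] = kb[ti]
        dd[ti] = db[ti]
        ssr[ti] = ssrb[ti]


@njit(cache=True)
def run_anneal(
    seed,
    res_off,            # (n_res+1,) rotamer offsets per residue
    rot_res,            # (R,) owning residue of each rotamer
    u_res, v_res,       # (T,) residue indices per trace
    nt_arr,             # (T,) points per trace
    tmat, vexp,         # (T, max_nt) time axes / experimental decays
    sigma2,             # (T,) noise variances
    a3,                 # (T, max_nt, nb) composed kernel operators
    svec,               # (T, nb) kept-mass column sums
    didx,               # (T, maxNu, maxNv) pair-distance bin indices
    res_tr_off, res_tr, # CSR residue -> trace incidence
    lam_grid, k_grid, d_grid_free,
    kt_init, kt_final_frac,
    trials_per_trace, abort_fail,
    mag0, mag_floor, shrink,
    d_policy,           # 0: d fixed at 3; 1: free after the first round
    max_rounds,
    ssr_mean_floor,
):
    n_res = res_off.size - 1
    n_rot = rot_res.size
    n_traces = u_res.size
    nb = svec.shape[1]
    max_nt = tmat.shape[1]
    n_total = 0.0
    for ti in range(n_traces):
        n_total += nt_arr[ti]

    np.random.seed(seed)
    w = np.zeros(n_rot)
    for r in range(n_res):
        lo = res_off[r]
        w[lo + np.random.randint(res_off[r + 1] - lo)] = 1.0

    h = np.zeros((n_traces, nb))
    hb = np.zeros((n_traces, nb))
    lam = np.full(n_traces, 0.3)
    kk = np.full(n_traces, 0.2)
    dd = np.full(n_traces, 3.0)
    lamb = np.zeros(n_traces)
    kb = np.zeros(n_traces)
    db = np.zeros(n_traces)
    ssr = np.zeros(n_traces)
    ssrb = np.zeros(n_traces)
    vwork = np.empty(max_nt)
    d_grid_fixed = np.full(1, 3.0)

    ssr_tot = _refresh(
        w, res_off, u_res, v_res, nt_arr, tmat, vexp, sigma2, a3, svec, didx,
        lam_grid, k_grid, d_grid_fixed, False, lam, kk, dd, ssr, h, vwork,
    )
    ssr_initial = ssr_tot
    # best-sampled state: the replica's result is the lowest-SSR model visited
    ssr_best = ssr_tot
    w_best = w.copy()
    lam_best = lam.copy()
    k_best = kk.copy()
    d_best = dd.copy()

    n_sched = trials_per_trace * n_traces
    c = (1.0 / kt_final_frac - 1.0) / max(n_sched - 1, 1)
    mag = mag0
    round_idx = 0
    trials_done = 0
    round_ssr = np.zeros(max_rounds)

    while True:
        round_idx += 1
        free_now = (d_policy == 1) and (round_idx >= 2)
        improvements = 0
        consec_fail = 0
        for j in range(n_sched):
            kt = kt_init / (1.0 + c * j)
            # --- propose: one rotamer, uniform increment, clip at zero,
            #     redraw if the residue would be left with all-zero weights
            g = 0
            r = 0
            w_new = 0.0
            for _redraw in range(10000):
                g = np.random.randint(n_rot)
                r = rot_res[g]
                w_new = w[g] + (2.0 * np.random.random() - 1.0) * mag
                if w_new < 0.0:
                    w_new = 0.0
                if w_new == 0.0:
                    rest = 0.0
                    for q in range(res_off[r], res_off[r + 1]):
                        if q != g:
                            rest += w[q]
                    if rest <= 0.0:
                        continue
                break
            trials_done += 1
            w_old = w[g]
            if w_new == w_old:
                consec_fail += 1
                if consec_fail >= abort_fail:
                    break
                continue
            dssr = _apply_weight_change(
                g, r, w_new, w, res_off, rot_res, u_res, v_res, nt_arr, tmat,
                vexp, sigma2, a3, svec, didx, res_tr_off, res_tr, free_now,
                lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb, vwork,
            )
            ssr_tot_new = ssr_tot + dssr
            m_old = max(ssr_tot / n_total, ssr_mean_floor)
            m_new = max(ssr_tot_new / n_total, ssr_mean_floor)
            dlnl = -0.5 * n_total * (np.log(m_new) - np.log(m_old))
            if dlnl >= 0.0:
                accept = True
            else:
                accept = np.random.random() < np.exp(dlnl / kt)
            if accept:
                # an "improvement" beats the best SSR sampled so far; this is
                # what arms the consecutive-failure abort and the shrink rule
                if ssr_tot_new < ssr_best:
                    ssr_best = ssr_tot_new
                    w_best[:] = w
                    lam_best[:] = lam
                    k_best[:] = kk
                    d_best[:] = dd
                    improvements += 1
                    consec_fail = 0
                else:
                    consec_fail += 1
                ssr_tot = ssr_tot_new
            else:
                _revert_weight_change(
                    g, r, w_old, w, res_tr_off, res_tr,
                    lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb,
                )
                consec_fail += 1
            if consec_fail >= abort_fail:
                break
        # --- round boundary: restart from the best-sampled state, then an
        #     exact refresh + full background re-fit
        w[:] = w_best
        lam[:] = lam_best
        kk[:] = k_best
        dd[:] = d_best
        free_b = (d_policy == 1) and (round_idx >= 1)
        d_grid = d_grid_free if free_b else d_grid_fixed
        ssr_tot = _refresh(
            w, res_off, u_res, v_res, nt_arr, tmat, vexp, sigma2, a3, svec, didx,
            lam_grid, k_grid, d_grid, free_b, lam, kk, dd, ssr, h, vwork,
        )
        if ssr_tot < ssr_best:
            ssr_best = ssr_tot
            w_best[:] = w
            lam_best[:] = lam
            k_best[:] = kk
            d_best[:] = dd
        round_ssr[round_idx - 1] = ssr_best
        if improvements == 0:
            mag /= shrink
            if mag < mag_floor * (1.0 + 1e-9):
                break
        if round_idx >= max_rounds:
            break
    # conclude on the best-sampled state
    w[:] = w_best
    lam[:] = lam_best
    kk[:] = k_best
    dd[:] = d_best
    free_b = d_policy == 1
    d_grid = d_grid_free if free_b else d_grid_fixed
    ssr_tot = _refresh(
        w, res_off, u_res, v_res, nt_arr, tmat, vexp, sigma2, a3, svec, didx,
        lam_grid, k_grid, d_grid, free_b, lam, kk, dd, ssr, h, vwork,
    )

    # --- greedy descent polish: strict SSR descent over the magnitude ladder
    #     (short fixed budget per magnitude; gains saturate quickly)
    polish_trials = min(n_sched, 3000)
    for p in range(3):
        mag_p = mag0 / shrink**p
        if mag_p < mag_floor:
            break
        consec_fail = 0
        for j in range(polish_trials):
            g = 0
            r = 0
            w_new = 0.0
            for _redraw in range(10000):
                g = np.random.randint(n_rot)
                r = rot_res[g]
                w_new = w[g] + (2.0 * np.random.random() - 1.0) * mag_p
                if w_new < 0.0:
                    w_new = 0.0
                if w_new == 0.0:
                    rest = 0.0
                    for q in range(res_off[r], res_off[r + 1]):
                        if q != g:
                            rest += w[q]
                    if rest <= 0.0:
                        continue
                break
            w_old = w[g]
            if w_new == w_old:
                consec_fail += 1
                if consec_fail >= abort_fail:
                    break
                continue
            dssr = _apply_weight_change(
                g, r, w_new, w, res_off, rot_res, u_res, v_res, nt_arr, tmat,
                vexp, sigma2, a3, svec, didx, res_tr_off, res_tr, free_b,
                lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb, vwork,
            )
            if dssr < 0.0:
                ssr_tot += dssr
                consec_fail = 0
            else:
                _revert_weight_change(
                    g, r, w_old, w, res_tr_off, res_tr,
                    lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb,
                )
                consec_fail += 1
            if consec_fail >= abort_fail:
                break

    # --- AICc-guided pruning: drop rotamers whenever the information
    #     criterion improves (small SSR increase is outweighed by -1 parameter)
    n_bg_params = 2.0 if d_policy == 0 else 3.0
    nnz = 0
    for g in range(n_rot):
        if w[g] > 0.0:
            nnz += 1
    changed = True
    while changed:
        changed = False
        for g in range(n_rot):
            if w[g] <= 0.0:
                continue
            r = rot_res[g]
            rest = 0.0
            for q in range(res_off[r], res_off[r + 1]):
                if q != g:
                    rest += w[q]
            if rest <= 0.0:
                continue  # last active rotamer of its residue stays
            w_old = w[g]
            dssr = _apply_weight_change(
                g, r, 0.0, w, res_off, rot_res, u_res, v_res, nt_arr, tmat,
                vexp, sigma2, a3, svec, didx, res_tr_off, res_tr, free_b,
                lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb, vwork,
            )
            m_old = max(ssr_tot / n_total, ssr_mean_floor)
            m_new = max((ssr_tot + dssr) / n_total, ssr_mean_floor)
            d2lnl = n_total * (np.log(m_new) - np.log(m_old))  # = -2 dlnL
            k_now = nnz + n_bg_params * n_traces
            k_new = k_now - 1.0
            d_pen = (
                2.0 * k_new + 2.0 * k_new * (k_new + 1.0) / (n_total - k_new - 1.0)
            ) - (
                2.0 * k_now + 2.0 * k_now * (k_now + 1.0) / (n_total - k_now - 1.0)
            )
            if d2lnl + d_pen < 0.0:
                ssr_tot += dssr
                nnz -= 1
                changed = True
            else:
                _revert_weight_change(
                    g, r, w_old, w, res_tr_off, res_tr,
                    lam, kk, dd, ssr, h, hb, lamb, kb, db, ssrb,
                )

    # final exact refresh on the concluded state
    ssr_tot = _refresh(
        w, res_off, u_res, v_res, nt_arr, tmat, vexp, sigma2, a3, svec, didx,
        lam_grid, k_grid, d_grid, free_b, lam, kk, dd, ssr, h, vwork,
    )
    return w, lam, kk, dd, ssr_tot, ssr_initial, round_idx, trials_done, round_ssr[:round_idx]
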