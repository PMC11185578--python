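"""Compiled inner loops for the sliding-window seeding DP.

The kernels are element-wise transcriptions of the recurrences in
:mod:`subseqseed.dp`; they must stay bit-identical to the pure-Python
``elementwise`` and numpy ``vectorized`` engines there (this is asserted by
the test suite).  Infeasible subproblems are tracked with explicit boolean
masks; the value arrays hold a canonical 0 wherever the mask is False.

Array layout: every span of the input is addressed as (start, length);
``fmin/fmax`` hold extreme forward omega values over length-l subsequences of
the span with forward residue j, ``rmin/rmax`` the reverse-function
equivalents.  Shapes are (N+1, n+1, k+1, d).
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["fill_tables", "optimize_windows"]


@numba.njit(cache=False)
def fill_tables(codes, n, k, d,
                CF, CR, AF, AR, BF1, BF2, BR1, BR2,
                fmin, fmax, rmin, rmax, ffeas, rfeas):  # pragma: no cover - exercised via dp
    N = codes.shape[0]
    # length-0 spans: only the empty subsequence, residue 0, value 0
    for s in range(N + 1):
        for l in range(k + 1):
            for j in range(d):
                feas = l == 0 and j == 0
                ffeas[s, 0, l, j] = feas
                rfeas[s, 0, l, j] = feas
                fmin[s, 0, l, j] = 0
                fmax[s, 0, l, j] = 0
                rmin[s, 0, l, j] = 0
                rmax[s, 0, l, j] = 0
    # forward family: extend span [s, s+b) on the right with codes[s+b-1]
    for s in range(N + 1):
        maxb = n if N - s > n else N - s
        for b in range(1, maxb + 1):
            sigma = codes[s + b - 1]
            for l in range(k + 1):
                for j in range(d):
                    sk_ok = ffeas[s, b - 1, l, j]
                    sk_min = fmin[s, b - 1, l, j]
                    sk_max = fmax[s, b - 1, l, j]
                    tk_ok = False
                    tk_min = 0
                    tk_max = 0
                    if l > 0 and sigma >= 0:
                        jp = (j - CF[l - 1, sigma]) % d
                        if jp < 0:
                            jp += d
                        if ffeas[s, b - 1, l - 1, jp]:
                            tk_ok = True
                            a2 = AF[l - 1, j, sigma] * BF2[l - 1, j, sigma]
                            if BF1[l - 1, j, sigma] == 1:
                                tk_min = a2 + fmin[s, b - 1, l - 1, jp]
                                tk_max = a2 + fmax[s, b - 1, l - 1, jp]
                            else:
                                tk_min = a2 - fmax[s, b - 1, l - 1, jp]
                                tk_max = a2 - fmin[s, b - 1, l - 1, jp]
                    if sk_ok and tk_ok:
                        ffeas[s, b, l, j] = True
                        fmin[s, b, l, j] = sk_min if sk_min < tk_min else tk_min
                        fmax[s, b, l, j] = sk_max if sk_max > tk_max else tk_max
                    elif sk_ok:
                        ffeas[s, b, l, j] = True
                        fmin[s, b, l, j] = sk_min
                        fmax[s, b, l, j] = sk_max
                    elif tk_ok:
                        ffeas[s, b, l, j] = True
                        fmin[s, b, l, j] = tk_min
                        fmax[s, b, l, j] = tk_max
                    else:
                        ffeas[s, b, l, j] = False
                        fmin[s, b, l, j] = 0
                        fmax[s, b, l, j] = 0
    # reverse family: extend span [s, s+b) on the left with codes[s]; the
    # first span character, if used, is the last character of the reversed
    # subsequence (table row l-1)
    for b in range(1, n + 1):
        for s in range(N - b + 1):
            sigma = codes[s]
            for l in range(k + 1):
                for j in range(d):
                    sk_ok = rfeas[s + 1, b - 1, l, j]
                    sk_min = rmin[s + 1, b - 1, l, j]
                    sk_max = rmax[s + 1, b - 1, l, j]
                    tk_ok = False
                    tk_min = 0
                    tk_max = 0
                    if l > 0 and sigma >= 0:
                        jp = (j - CR[l - 1, sigma]) % d
                        if jp < 0:
                            jp += d
                        if rfeas[s + 1, b - 1, l - 1, jp]:
                            tk_ok = True
                            a2 = AR[l - 1, j, sigma] * BR2[l - 1, j, sigma]
                            if BR1[l - 1, j, sigma] == 1:
                                tk_min = a2 + rmin[s + 1, b - 1, l - 1, jp]
                                tk_max = a2 + rmax[s + 1, b - 1, l - 1, jp]
                            else:
                                tk_min = a2 - rmax[s + 1, b - 1, l - 1, jp]
                                tk_max = a2 - rmin[s + 1, b - 1, l - 1, jp]
                    if sk_ok and tk_ok:
                        rfeas[s, b, l, j] = True
                        rmin[s, b, l, j] = sk_min if sk_min < tk_min else tk_min
                        rmax[s, b, l, j] = sk_max if sk_max > tk_max else tk_max
                    elif sk_ok:
                        rfeas[s, b, l, j] = True
                        rmin[s, b, l, j] = sk_min
                        rmax[s, b, l, j] = sk_max
                    elif tk_ok:
                        rfeas[s, b, l, j] = True
                        rmin[s, b, l, j] = tk_min
                        rmax[s, b, l, j] = tk_max
                    else:
                        rfeas[s, b, l, j] = False
                        rmin[s, b, l, j] = 0
                        rmax[s, b, l, j] = 0


@numba.njit(cache=False)
def optimize_windows(codes, n, k, d,
                     CF, CR, AF, AR, BF1, BF2, BR1, BR2,
                     AP, BP1, BP2, CP,
                     fmin, fmax, rmin, rmax, ffeas, rfeas,
                     order_idx, window_ok, use_rc_orientation,
                     out_psi, out_omega, out_pos):  # pragma: no cover - exercised via dp
    """Per window and selected order: optimal (psi, omega) over all pivot
    positions, then traceback of the winning subsequence's positions.

    ``order_idx`` holds 0-based order indices; ``out_psi`` is set to -1 for
    windows flagged invalid (or infeasible, which cannot happen for clean
    windows with n >= k).  Positions written to ``out_pos`` are
    window-relative.  With ``use_rc_orientation`` (rc-symmetric DNA tables)
    windows whose reverse complement is lexicographically smaller break ties
    with the mirrored rule, so that tied argmins of a window and of its
    reverse complement still correspond.
    """
    N = codes.shape[0]
    W = N - n + 1
    T = order_idx.shape[0]
    for w in range(W):
        if not window_ok[w]:
            for ti in range(T):
                out_psi[w, ti] = -1
            continue
        flipped = False
        if use_rc_orientation:
            for p in range(n):
                a = codes[w + p]
                bq = 3 - codes[w + n - 1 - p]
                if bq < a:
                    flipped = True
                    break
                if bq > a:
                    break
        for ti in range(T):
            io = order_idx[ti]
            lpre = io          # prefix subsequence length (i-1)
            lsuf = k - 1 - io  # suffix subsequence length (k-i)
            best_psi = -1
            best_omega = 0
            best_b = -1
            for b in range(1, n + 1):
                if lpre > b - 1 or lsuf > n - b:
                    continue
                pivot = codes[w + b - 1]
                c = CP[io, pivot]
                # smallest achievable residue: early-exit double scan
                psi_b = -1
                for r in range(d):
                    found = False
                    for j1 in range(d):
                        if rfeas[w, b - 1, lpre, j1]:
                            j2 = (r - c - j1) % d
                            if j2 < 0:
                                j2 += d
                            if ffeas[w + b, n - b, lsuf, j2]:
                                found = True
                                break
                    if found:
                        psi_b = r
                        break
                if psi_b == -1:
                    continue
                bp1 = BP1[io, pivot]
                bp2 = BP2[io, pivot]
                om_b = 0
                have = False
                for j1 in range(d):
                    if not rfeas[w, b - 1, lpre, j1]:
                        continue
                    j2 = (psi_b - c - j1) % d
                    if j2 < 0:
                        j2 += d
                    if not ffeas[w + b, n - b, lsuf, j2]:
                        continue
                    rv = rmax[w, b - 1, lpre, j1] if bp1 == 1 else -rmin[w, b - 1, lpre, j1]
                    fv = fmax[w + b, n - b, lsuf, j2] if bp2 == 1 else -fmin[w + b, n - b, lsuf, j2]
                    tot = rv + AP[io, pivot] + fv
                    if not have or tot > om_b:
                        om_b = tot
                        have = True
                better = (best_b == -1 or psi_b < best_psi
                          or (psi_b == best_psi and om_b > best_omega))
                if not better and flipped and psi_b == best_psi and om_b == best_omega:
                    better = True  # mirrored rule keeps the largest tied pivot
                if better:
                    best_psi = psi_b
                    best_omega = om_b
                    best_b = b
            if best_b == -1:
                out_psi[w, ti] = -1
                continue
            out_psi[w, ti] = best_psi
            out_omega[w, ti] = best_omega
            # traceback --------------------------------------------------
            b = best_b
            pivot = codes[w + b - 1]
            c = CP[io, pivot]
            bp1 = BP1[io, pivot]
            bp2 = BP2[io, pivot]
            # smallest achieving residue class: prefix class j1 ascending in
            # the forward orientation, suffix class j2 ascending when mirrored
            j1s = -1
            for jq in range(d):
                if flipped:
                    j1 = (best_psi - c - jq) % d
                else:
                    j1 = jq
                if j1 < 0:
                    j1 += d
                if not rfeas[w, b - 1, lpre, j1]:
                    continue
                j2 = (best_psi - c - j1) % d
                if j2 < 0:
                    j2 += d
                if not ffeas[w + b, n - b, lsuf, j2]:
                    continue
                rv = rmax[w, b - 1, lpre, j1] if bp1 == 1 else -rmin[w, b - 1, lpre, j1]
                fv = fmax[w + b, n - b, lsuf, j2] if bp2 == 1 else -fmin[w + b, n - b, lsuf, j2]
                if rv + AP[io, pivot] + fv == best_omega:
                    j1s = j1
                    break
            j2s = (best_psi - c - j1s) % d
            if j2s < 0:
                j2s += d
            out_pos[w, ti, io] = b - 1
            # prefix: trace the reverse family from the span's left end.
            # Forward orientation prefers TAKE (leftmost-packed positions);
            # mirrored orientation prefers SKIP (rightmost-packed).
            s = w
            B = b - 1
            l = lpre
            j = j1s
            fam = 1 if bp1 == 1 else 0  # 1 -> tracking the max table
            v = rmax[w, b - 1, lpre, j1s] if bp1 == 1 else rmin[w, b - 1, lpre, j1s]
            idx = 0
            while l > 0:
                sigma = codes[s]
                take_ok = False
                jp = 0
                child_fam = 0
                child_v = 0
                if sigma >= 0:
                    jp = (j - CR[l - 1, sigma]) % d
                    if jp < 0:
                        jp += d
                    if rfeas[s + 1, B - 1, l - 1, jp]:
                        a2 = AR[l - 1, j, sigma] * BR2[l - 1, j, sigma]
                        b1 = BR1[l - 1, j, sigma]
                        child_v = b1 * (v - a2)
                        child_fam = fam if b1 == 1 else 1 - fam
                        stored = rmin[s + 1, B - 1, l - 1, jp] if child_fam == 0 \
                            else rmax[s + 1, B - 1, l - 1, jp]
                        if stored == child_v:
                            take_ok = True
                take = take_ok
                if take_ok and flipped:
                    if B - 1 >= l and rfeas[s + 1, B - 1, l, j]:
                        stored = rmin[s + 1, B - 1, l, j] if fam == 0 \
                            else rmax[s + 1, B - 1, l, j]
                        if stored == v:
                            take = False  # mirrored rule skips when possible
                if take:
                    out_pos[w, ti, idx] = s - w
                    idx += 1
                    l -= 1
                    j = jp
                    fam = child_fam
                    v = child_v
                s += 1
                B -= 1
            # suffix: trace the forward family from the span's right end.
            # Forward orientation prefers SKIP (leftmost-packed positions);
            # mirrored orientation prefers TAKE (rightmost-packed).
            s0 = w + b
            B = n - b
            l = lsuf
            j = j2s
            fam = 1 if bp2 == 1 else 0
            v = fmax[w + b, n - b, lsuf, j2s] if bp2 == 1 else fmin[w + b, n - b, lsuf, j2s]
            idx = k - 1
            while l > 0:
                skip_ok = False
                if B - 1 >= l and ffeas[s0, B - 1, l, j]:
                    stored = fmin[s0, B - 1, l, j] if fam == 0 else fmax[s0, B - 1, l, j]
                    if stored == v:
                        skip_ok = True
                skip = skip_ok
                if skip_ok and flipped:
                    sigma = codes[s0 + B - 1]
                    if sigma >= 0:
                        jp = (j - CF[l - 1, sigma]) % d
                        if jp < 0:
                            jp += d
                        if ffeas[s0, B - 1, l - 1, jp]:
                            a2 = AF[l - 1, j, sigma] * BF2[l - 1, j, sigma]
                            b1 = BF1[l - 1, j, sigma]
                            child_v = b1 * (v - a2)
                            child_fam = fam if b1 == 1 else 1 - fam
                            stored = fmin[s0, B - 1, l - 1, jp] if child_fam == 0 \
                                else fmax[s0, B - 1, l - 1, jp]
                            if stored == child_v:
                                skip = False  # mirrored rule takes when possible
                if skip:
                    B -= 1
                else:
                    sigma = codes[s0 + B - 1]
                    jp = (j - CF[l - 1, sigma]) % d
                    if jp < 0:
                        jp += d
                    a2 = AF[l - 1, j, sigma] * BF2[l - 1, j, sigma]
                    b1 = BF1[l - 1, j, sigma]
                    out_pos[w, ti, idx] = s0 + B - 1 - w
                    idx -= 1
                    v = b1 * (v - a2)
                    fam = fam if b1 == 1 else 1 - fam
                    j = jp
                    l -= 1
                    B -= 1
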