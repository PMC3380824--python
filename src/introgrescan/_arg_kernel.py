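"""Numba kernel for the two-deme ancestral-recombination-graph simulator.

Segment lists live in a preallocated pool chained by ``nxt`` indices;
descendant sets are uint64 bitmasks (up to 64 sampled haplotypes).  The
kernel mirrors the reference implementation in
:func:`introgrescan.coalsim.simulate_ancestry` (same model, same rates)
and returns the mutation-bearing pieces (weight, descendant mask).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dep of the env
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap


SEG_CAP = 1 << 17
LIN_CAP = 512
PIECE_CAP = 1 << 20


@njit(cache=True)
def _arg_kernel(
    theta1, theta2, thetaA, t_split, m1, m2, rho,
    pulse_time, pulse1, pulse2, pulse_sweep,
    n1, n2, seed,
):  # pragma: no cover - exercised via the wrapper (compiled code)
    np.random.seed(seed)
    n = n1 + n2
    full = np.uint64(0)
    for i in range(n):
        full |= np.uint64(1) << np.uint64(i)

    s_left = np.empty(SEG_CAP, np.float64)
    s_right = np.empty(SEG_CAP, np.float64)
    s_mask = np.empty(SEG_CAP, np.uint64)
    s_next = np.empty(SEG_CAP, np.int64)
    free_head = 0
    for i in range(SEG_CAP - 1):
        s_next[i] = i + 1
    s_next[SEG_CAP - 1] = -1

    # lineage slots
    l_head = np.full(LIN_CAP, -1, np.int64)
    l_tail = np.full(LIN_CAP, -1, np.int64)
    l_birth = np.zeros(LIN_CAP, np.float64)
    l_span = np.zeros(LIN_CAP, np.float64)
    lin_free = np.empty(LIN_CAP, np.int64)
    for i in range(LIN_CAP):
        lin_free[i] = LIN_CAP - 1 - i
    lin_free_top = LIN_CAP

    # per-deme pools of lineage ids
    pool = np.full((3, LIN_CAP), -1, np.int64)
    pool_n = np.zeros(3, np.int64)

    pieces_w = np.empty(PIECE_CAP, np.float64)
    pieces_m = np.empty(PIECE_CAP, np.uint64)
    n_pieces = 0

    merged = t_split == 0.0
    start_deme = 2 if merged else 0

    # init sample lineages
    for i in range(n):
        seg = free_head
        free_head = s_next[seg]
        s_left[seg] = 0.0
        s_right[seg] = 1.0
        s_mask[seg] = np.uint64(1) << np.uint64(i)
        s_next[seg] = -1
        lin_free_top -= 1
        lid = lin_free[lin_free_top]
        l_head[lid] = seg
        l_tail[lid] = seg
        l_birth[lid] = 0.0
        l_span[lid] = 1.0
        d = 2 if merged else (0 if i < n1 else 1)
        pool[d, pool_n[d]] = lid
        pool_n[d] += 1

    tau = 0.0
    half_rho = rho / 2.0
    span_sum = float(n) if rho > 0 else 0.0
    pulse_done = merged or (pulse1 == 0.0 and pulse2 == 0.0)

    while pool_n[0] + pool_n[1] + pool_n[2] > 0:
        if n_pieces > PIECE_CAP - 8192 or lin_free_top < 8 or free_head == -1:
            raise RuntimeError(
                "ancestry simulation exceeded preallocated capacity"
            )
        k0 = pool_n[0]
        k1 = pool_n[1]
        k2 = pool_n[2]
        if k0 + k1 + k2 == 1 and rho == 0.0:
            break
        if merged:
            c0 = 0.0
            c1 = 0.0
            mg0 = 0.0
            mg1 = 0.0
            c2 = k2 * (k2 - 1) / thetaA
        else:
            c0 = k0 * (k0 - 1) / theta1
            c1 = k1 * (k1 - 1) / theta2
            mg0 = k0 * m1 / 2.0
            mg1 = k1 * m2 / 2.0
            c2 = 0.0
        rec = half_rho * span_sum if rho > 0 else 0.0
        total = c0 + c1 + mg0 + mg1 + c2 + rec
        if total > 0:
            wait = np.random.exponential(1.0 / total)
        else:
            wait = np.inf
        if not pulse_done and tau + wait >= pulse_time:
            tau = pulse_time
            pulse_done = True
            for d in range(2):
                frac = pulse1 if d == 0 else pulse2
                if frac <= 0.0:
                    continue
                kd = pool_n[d]
                k_move = int(np.round(frac * kd))
                if k_move <= 0:
                    continue
                # partial Fisher-Yates over the pool row
                for j in range(k_move):
                    pick = j + np.random.randint(0, kd - j)
                    tmp = pool[d, j]
                    pool[d, j] = pool[d, pick]
                    pool[d, pick] = tmp
                # retire movers
                for j in range(k_move):
                    lid = pool[d, j]
                    life = tau - l_birth[lid]
                    if life > 0:
                        seg = l_head[lid]
                        while seg != -1:
                            pieces_w[n_pieces] = life * (s_right[seg] - s_left[seg])
                            pieces_m[n_pieces] = s_mask[seg]
                            n_pieces += 1
                            seg = s_next[seg]
                if pulse_sweep and k_move > 1:
                    # star-coalesce movers into pool[d,0]
                    for j in range(k_move):
                        span_sum -= l_span[pool[d, j]]
                    base = pool[d, 0]
                    for j in range(1, k_move):
                        other = pool[d, j]
                        (base, free_head, lin_free_top, span_sum) = _merge_into(
                            base, other, full, tau,
                            s_left, s_right, s_mask, s_next,
                            l_head, l_tail, l_birth, l_span,
                            lin_free, lin_free_top, free_head, span_sum,
                            False,
                        )
                        if base == -1:
                            break
                    # compact pool: remove moved slots
                    survivors = 0
                    if base != -1:
                        l_birth[base] = tau
                        span_sum += l_span[base]
                        pool[1 - d, pool_n[1 - d]] = base
                        pool_n[1 - d] += 1
                    for j in range(k_move, kd):
                        pool[d, j - k_move + survivors] = pool[d, j]
                    pool_n[d] = kd - k_move
                else:
                    for j in range(k_move):
                        lid = pool[d, j]
                        l_birth[lid] = tau
                        pool[1 - d, pool_n[1 - d]] = lid
                        pool_n[1 - d] += 1
                    for j in range(k_move, kd):
                        pool[d, j - k_move] = pool[d, j]
                    pool_n[d] = kd - k_move
            continue
        if not merged and tau + wait >= t_split:
            tau = t_split
            merged = True
            for d in range(2):
                for j in range(pool_n[d]):
                    pool[2, pool_n[2]] = pool[d, j]
                    pool_n[2] += 1
                pool_n[d] = 0
            continue
        if wait == np.inf:
            break
        tau += wait
        u = np.random.random() * total
        if u < rec:
            # recombination: pick lineage weighted by span
            target = u / half_rho
            acc = 0.0
            lid = -1
            dd = -1
            jj = -1
            done = False
            for d in range(3):
                if done:
                    break
                for j in range(pool_n[d]):
                    acc += l_span[pool[d, j]]
                    if acc >= target:
                        lid = pool[d, j]
                        dd = d
                        jj = j
                        done = True
                        break
            if lid == -1:
                for d in range(3):
                    if pool_n[d] > 0:
                        dd = d
                        jj = pool_n[d] - 1
                        lid = pool[d, jj]
            first = s_left[l_head[lid]]
            bp = first + np.random.random() * l_span[lid]
            # split chain at bp
            left_head = l_head[lid]
            prev = -1
            seg = left_head
            right_head = -1
            while seg != -1:
                if s_right[seg] <= bp:
                    prev = seg
                    seg = s_next[seg]
                elif s_left[seg] >= bp:
                    right_head = seg
                    if prev == -1:
                        left_head = -1
                    else:
                        s_next[prev] = -1
                    break
                else:
                    # straddles: split the segment
                    new = free_head
                    free_head = s_next[new]
                    s_left[new] = bp
                    s_right[new] = s_right[seg]
                    s_mask[new] = s_mask[seg]
                    s_next[new] = s_next[seg]
                    s_right[seg] = bp
                    s_next[seg] = -1
                    right_head = new
                    break
            if left_head == -1 or right_head == -1:
                continue
            # retire original lineage
            life = tau - l_birth[lid]
            if life > 0:
                sg = left_head
                while sg != -1:
                    pieces_w[n_pieces] = life * (s_right[sg] - s_left[sg])
                    pieces_m[n_pieces] = s_mask[sg]
                    n_pieces += 1
                    sg = s_next[sg]
                sg = right_head
                while sg != -1:
                    pieces_w[n_pieces] = life * (s_right[sg] - s_left[sg])
                    pieces_m[n_pieces] = s_mask[sg]
                    n_pieces += 1
                    sg = s_next[sg]
            old_span = l_span[lid]
            # reuse lid slot for left part
            l_head[lid] = left_head
            tail = left_head
            while s_next[tail] != -1:
                tail = s_next[tail]
            l_tail[lid] = tail
            l_birth[lid] = tau
            l_span[lid] = s_right[tail] - s_left[left_head]
            # new lineage for right part
            lin_free_top -= 1
            rid = lin_free[lin_free_top]
            l_head[rid] = right_head
            tail = right_head
            while s_next[tail] != -1:
                tail = s_next[tail]
            l_tail[rid] = tail
            l_birth[rid] = tau
            l_span[rid] = s_right[tail] - s_left[right_head]
            pool[dd, pool_n[dd]] = rid
            pool_n[dd] += 1
            span_sum += l_span[lid] + l_span[rid] - old_span
        elif u < rec + c0 + c1 + c2:
            if merged:
                d = 2
            else:
                d = 0 if u - rec < c0 else 1
            kd = pool_n[d]
            ia = np.random.randint(0, kd)
            ib = np.random.randint(0, kd - 1)
            if ib >= ia:
                ib += 1
            if ia > ib:
                ia, ib = ib, ia
            la = pool[d, ia]
            lb = pool[d, ib]
            # swap-remove both (ia < ib, so ia is never the last slot)
            pool[d, ib] = pool[d, kd - 1]
            kd -= 1
            pool[d, ia] = pool[d, kd - 1]
            kd -= 1
            pool_n[d] = kd
            # retire both
            for lx in (la, lb):
                life = tau - l_birth[lx]
                if life > 0:
                    sg = l_head[lx]
                    while sg != -1:
                        pieces_w[n_pieces] = life * (s_right[sg] - s_left[sg])
                        pieces_m[n_pieces] = s_mask[sg]
                        n_pieces += 1
                        sg = s_next[sg]
            span_sum -= l_span[la] + l_span[lb]
            (nid, free_head, lin_free_top, span_sum) = _merge_into(
                la, lb, full, tau,
                s_left, s_right, s_mask, s_next,
                l_head, l_tail, l_birth, l_span,
                lin_free, lin_free_top, free_head, span_sum,
                True,
            )
            if nid != -1:
                pool[d, pool_n[d]] = nid
                pool_n[d] += 1
        else:
            v = u - rec - c0 - c1 - c2
            d = 0 if v < mg0 else 1
            kd = pool_n[d]
            j = np.random.randint(0, kd)
            lid = pool[d, j]
            life = tau - l_birth[lid]
            if life > 0:
                sg = l_head[lid]
                while sg != -1:
                    pieces_w[n_pieces] = life * (s_right[sg] - s_left[sg])
                    pieces_m[n_pieces] = s_mask[sg]
                    n_pieces += 1
                    sg = s_next[sg]
            l_birth[lid] = tau
            pool[d, j] = pool[d, kd - 1]
            pool_n[d] -= 1
            pool[1 - d, pool_n[1 - d]] = lid
            pool_n[1 - d] += 1

    return pieces_w[:n_pieces].copy(), pieces_m[:n_pieces].copy()


@njit(cache=True)
def _merge_into(
    la, lb, full, tau,
    s_left, s_right, s_mask, s_next,
    l_head, l_tail, l_birth, l_span,
    lin_free, lin_free_top, free_head, span_sum,
    add_span,
):  # pragma: no cover - exercised via the wrapper (compiled code)
    """Coalesce lineages la and lb into a fresh lineage; frees both input
    chains and both slots, allocates the merged chain.  Returns the new
    lineage id (or -1 if all material reached its MRCA)."""
    # linear sweep over the two sorted chains
    a = l_head[la]
    b = l_head[lb]
    out_head = -1
    out_tail = -1
    pos_a = s_left[a] if a != -1 else np.inf
    pos_b = s_left[b] if b != -1 else np.inf
    pos = min(pos_a, pos_b)
    while a != -1 or b != -1:
        mask = np.uint64(0)
        nxt = np.inf
        if a != -1:
            if s_left[a] <= pos:
                if s_right[a] > pos:
                    mask |= s_mask[a]
                    if s_right[a] < nxt:
                        nxt = s_right[a]
                else:
                    a = s_next[a]
                    continue
            else:
                if s_left[a] < nxt:
                    nxt = s_left[a]
        if b != -1:
            if s_left[b] <= pos:
                if s_right[b] > pos:
                    mask |= s_mask[b]
                    if s_right[b] < nxt:
                        nxt = s_right[b]
                else:
                    b = s_next[b]
                    continue
            else:
                if s_left[b] < nxt:
                    nxt = s_left[b]
        if nxt == np.inf:
            break
        if mask != np.uint64(0) and mask != full:
            if out_tail != -1 and s_mask[out_tail] == mask and s_right[out_tail] == pos:
                s_right[out_tail] = nxt
            else:
                seg = free_head
                free_head = s_next[seg]
                s_left[seg] = pos
                s_right[seg] = nxt
                s_mask[seg] = mask
                s_next[seg] = -1
                if out_tail == -1:
                    out_head = seg
                else:
                    s_next[out_tail] = seg
                out_tail = seg
        pos = nxt
    # free input chains
    for lx in (la, lb):
        seg = l_head[lx]
        while seg != -1:
            nx = s_next[seg]
            s_next[seg] = free_head
            free_head = seg
            seg = nx
        l_head[lx] = -1
        lin_free[lin_free_top] = lx
        lin_free_top += 1
    if out_head == -1:
        return -1, free_head, lin_free_top, span_sum
    lin_free_top -= 1
    nid = lin_free[lin_free_top]
    l_head[nid] = out_head
    l_tail[nid] = out_tail
    l_birth[nid] = tau
    l_span[nid] = s_right[out_tail] - s_left[out_head]
    if add_span:
        span_sum += l_span[nid]
    return nid, free_head, lin_free_top, span_sum
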