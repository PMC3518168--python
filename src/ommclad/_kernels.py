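"""Numba kernels for parsimony scoring and tree rearrangement.

Trees are adjacency arrays (see :mod:`ommclad.tree`); character data is
an ``(n_taxa, n_characters)`` int64 array of state bitmasks in which
missing/inapplicable cells carry the full state set.  All kernels treat
characters as unordered (Fitch) with unit cost.

The TBR machinery scores each reconnection in O(n_characters) by
precomputing, for every edge of each bisection component, the Fitch
state set and cost of the component rooted on that edge; joining two
rooted components then costs one set intersection per character.
"""

import numpy as np
from numba import njit

INF = np.int64(1) << 30


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=True)
def _traverse(adj, root, parent, order):
    """Preorder traversal; fills parent/order, returns node count."""
    M = adj.shape[0]
    for i in range(M):
        parent[i] = -1
    stack = np.empty(M, np.int32)
    top = 0
    stack[0] = root
    parent[root] = -2
    cnt = 0
    while top >= 0:
        v = stack[top]
        top -= 1
        order[cnt] = v
        cnt += 1
        for k in range(3):
            u = adj[v, k]
            if u >= 0 and u != parent[v] and parent[u] == -1:
                parent[u] = v
                top += 1
                stack[top] = u
    return cnt


@njit(cache=True)
def fitch_total(adj, states, root):
    """Fitch length of the (possibly partial) tree containing ``root``.

    ``root`` must be a leaf present in the tree.
    """
    M = adj.shape[0]
    n = states.shape[0]
    C = states.shape[1]
    parent = np.empty(M, np.int32)
    order = np.empty(M, np.int32)
    cnt = _traverse(adj, root, parent, order)
    sets = np.empty(M, np.int64)
    total = 0
    for c in range(C):
        for i in range(cnt - 1, -1, -1):
            v = order[i]
            if v < n:
                sets[v] = states[v, c]
            else:
                s = np.int64(-1)
                for k in range(3):
                    u = adj[v, k]
                    if u >= 0 and u != parent[v]:
                        if s == np.int64(-1):
                            s = sets[u]
                        else:
                            t = s & sets[u]
                            if t == 0:
                                total += 1
                                s = s | sets[u]
                            else:
                                s = t
                sets[v] = s
        ch = adj[root, 0]
        if ch >= 0 and cnt > 1:
            if sets[ch] & states[root, c] == 0:
                total += 1
    return total


@njit(cache=True)
def fitch_per_character(adj, states, root, out):
    """Per-character Fitch steps; ``out`` must have length n_characters."""
    M = adj.shape[0]
    n = states.shape[0]
    C = states.shape[1]
    parent = np.empty(M, np.int32)
    order = np.empty(M, np.int32)
    cnt = _traverse(adj, root, parent, order)
    sets = np.empty(M, np.int64)
    for c in range(C):
        steps = 0
        for i in range(cnt - 1, -1, -1):
            v = order[i]
            if v < n:
                sets[v] = states[v, c]
            else:
                s = np.int64(-1)
                for k in range(3):
                    u = adj[v, k]
                    if u >= 0 and u != parent[v]:
                        if s == np.int64(-1):
                            s = sets[u]
                        else:
                            t = s & sets[u]
                            if t == 0:
                                steps += 1
                                s = s | sets[u]
                            else:
                                s = t
                sets[v] = s
        ch = adj[root, 0]
        if ch >= 0 and cnt > 1:
            if sets[ch] & states[root, c] == 0:
                steps += 1
        out[c] = steps


@njit(cache=True)
def _positions(adj, states, root, avoid, lparent, lorder,
               pos_a, pos_b, pos_cost, pos_set):
    """Edge-rooting positions of the component containing ``root``.

    The component is the tree seen from ``root`` with the edge towards
    ``avoid`` removed (``avoid=-1``: the whole tree).  For every
    reattachment position p, ``pos_set[p, c]`` / ``pos_cost[p]`` give
    the Fitch state set and cost of the component rooted on that edge.
    Returns (n_positions, index_of_original_position).
    """
    M = adj.shape[0]
    n = states.shape[0]
    C = states.shape[1]
    for i in range(M):
        lparent[i] = -1
    if avoid >= 0:
        lparent[avoid] = -3
    stack = np.empty(M, np.int32)
    top = 0
    stack[0] = root
    lparent[root] = -2
    cnt = 0
    while top >= 0:
        v = stack[top]
        top -= 1
        lorder[cnt] = v
        cnt += 1
        for k in range(3):
            u = adj[v, k]
            if u >= 0 and u != lparent[v] and lparent[u] == -1:
                lparent[u] = v
                top += 1
                stack[top] = u
    if cnt == 1:
        pos_a[0] = root
        pos_b[0] = root
        pos_cost[0] = 0
        for c in range(C):
            pos_set[0, c] = states[root, c]
        return 1, 0

    # root's children within the component
    rc1 = np.int32(-1)
    rc2 = np.int32(-1)
    for k in range(3):
        u = adj[root, k]
        if u >= 0 and u != avoid and lparent[u] == root:
            if rc1 == -1:
                rc1 = u
            else:
                rc2 = u
    # enumerate positions (skip rc2: its edge merges with rc1's)
    pmap = np.full(M, -1, np.int32)
    npos = 0
    for i in range(1, cnt):
        x = lorder[i]
        if x == rc2:
            continue
        pos_a[npos] = x
        pos_b[npos] = rc2 if (x == rc1 and rc2 >= 0) else lparent[x]
        pos_cost[npos] = 0
        pmap[x] = npos
        npos += 1

    ldown = np.empty(M, np.int64)
    cdown = np.empty(M, np.int64)
    lup = np.empty(M, np.int64)
    cup = np.empty(M, np.int64)
    for c in range(C):
        # postorder: downward sets
        for i in range(cnt - 1, -1, -1):
            x = lorder[i]
            if x < n:
                ldown[x] = states[x, c]
                cdown[x] = 0
            else:
                s = np.int64(-1)
                cost = np.int64(0)
                for k in range(3):
                    u = adj[x, k]
                    if u >= 0 and u != avoid and lparent[u] == x:
                        cost += cdown[u]
                        if s == np.int64(-1):
                            s = ldown[u]
                        else:
                            t = s & ldown[u]
                            if t == 0:
                                cost += 1
                                s = s | ldown[u]
                            else:
                                s = t
                ldown[x] = s
                cdown[x] = cost
        # preorder: upward sets
        for i in range(1, cnt):
            x = lorder[i]
            p = lparent[x]
            if p == root:
                if rc2 == -1:
                    lup[x] = states[root, c]
                    cup[x] = 0
                else:
                    sib = rc2 if x == rc1 else rc1
                    lup[x] = ldown[sib]
                    cup[x] = cdown[sib]
            else:
                sib = np.int32(-1)
                for k in range(3):
                    u = adj[p, k]
                    if u >= 0 and u != x and lparent[u] == p:
                        sib = u
                s = lup[p] & ldown[sib]
                cost = cup[p] + cdown[sib]
                if s == 0:
                    s = lup[p] | ldown[sib]
                    cost += 1
                lup[x] = s
                cup[x] = cost
            pp = pmap[x]
            if pp >= 0:
                s = ldown[x] & lup[x]
                cost = cdown[x] + cup[x]
                if s == 0:
                    s = ldown[x] | lup[x]
                    cost += 1
                pos_set[pp, c] = s
                pos_cost[pp] += cost
    return npos, pmap[rc1]


@njit(cache=True)
def apply_tbr(adj, out, n, v, pv, a1, b1, a2, b2):
    """Write the tree after the TBR move into ``out``.

    The edge (v, pv) is cut; the component that contained v is rooted
    back on its edge (a1, b1) (ignored if v is a leaf), symmetrically
    for pv with (a2, b2), and the two junctions are reconnected.
    """
    M = adj.shape[0]
    for i in range(M):
        for k in range(3):
            out[i, k] = adj[i, k]
    # disconnect v - pv
    for k in range(3):
        if out[v, k] == pv:
            out[v, k] = -1
        if out[pv, k] == v:
            out[pv, k] = -1

    # side of v
    conn_a = v
    if v >= n:
        x = np.int32(-1)
        y = np.int32(-1)
        for k in range(3):
            u = out[v, k]
            if u >= 0:
                if x == -1:
                    x = u
                else:
                    y = u
            out[v, k] = -1
        for k in range(3):
            if out[x, k] == v:
                out[x, k] = y
            if out[y, k] == v:
                out[y, k] = x
        for k in range(3):
            if out[a1, k] == b1:
                out[a1, k] = v
            if out[b1, k] == a1:
                out[b1, k] = v
        out[v, 0] = a1
        out[v, 1] = b1
        out[v, 2] = -1

    # side of pv
    conn_b = pv
    if pv >= n:
        x = np.int32(-1)
        y = np.int32(-1)
        for k in range(3):
            u = out[pv, k]
            if u >= 0:
                if x == -1:
                    x = u
                else:
                    y = u
            out[pv, k] = -1
        for k in range(3):
            if out[x, k] == pv:
                out[x, k] = y
            if out[y, k] == pv:
                out[y, k] = x
        for k in range(3):
            if out[a2, k] == b2:
                out[a2, k] = pv
            if out[b2, k] == a2:
                out[b2, k] = pv
        out[pv, 0] = a2
        out[pv, 1] = b2
        out[pv, 2] = -1

    # join
    for k in range(3):
        if out[conn_a, k] == -1:
            out[conn_a, k] = conn_b
            break
    for k in range(3):
        if out[conn_b, k] == -1:
            out[conn_b, k] = conn_a
            break


@njit(cache=True)
def constraints_ok(adj, root, n, full_mask, masks, signs):
    """Check clade constraints on the tree containing leaf ``root``.

    signs: +1 the mask must form a clade, -1 it must not.  A mask equal
    to a trivial side (single leaf, whole leaf set minus root side) is
    treated as present.
    """
    M = adj.shape[0]
    parent = np.empty(M, np.int32)
    order = np.empty(M, np.int32)
    cnt = _traverse(adj, root, parent, order)
    below = np.zeros(M, np.int64)
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if v < n:
            below[v] = np.int64(1) << v
        else:
            acc = np.int64(0)
            for k in range(3):
                u = adj[v, k]
                if u >= 0 and u != parent[v]:
                    acc |= below[u]
            below[v] = acc
    for g in range(masks.shape[0]):
        gm = masks[g] & full_mask
        found = False
        if _popcount(gm) <= 1 or gm == full_mask:
            found = True
        else:
            for i in range(1, cnt):
                v = order[i]
                side = below[v]
                if side == gm or (full_mask ^ side) == gm:
                    found = True
                    break
        if signs[g] > 0 and not found:
            return False
        if signs[g] < 0 and found:
            return False
    return True


@njit(cache=True)
def tbr_scan(adj, states, n, mode, threshold, req_masks, req_signs, out_moves):
    """One full TBR neighbourhood scan.

    mode 0 (steepest): find the shortest constraint-satisfying
    neighbour strictly shorter than ``threshold``; returns its length
    and move, or (threshold, -1, ...) if none.
    mode 1 (collect): write every satisfying neighbour of length
    exactly ``threshold`` into ``out_moves`` (6 ints per row); the
    returned count may exceed the buffer, in which case only the first
    rows are stored.
    """
    M = adj.shape[0]
    C = states.shape[1]
    parent = np.empty(M, np.int32)
    order = np.empty(M, np.int32)
    cnt = _traverse(adj, 0, parent, order)
    full_mask = (np.int64(1) << n) - 1

    lparA = np.empty(M, np.int32)
    lordA = np.empty(M, np.int32)
    posAa = np.empty(M, np.int32)
    posAb = np.empty(M, np.int32)
    posAc = np.empty(M, np.int64)
    posAs = np.empty((M, C), np.int64)
    lparB = np.empty(M, np.int32)
    lordB = np.empty(M, np.int32)
    posBa = np.empty(M, np.int32)
    posBb = np.empty(M, np.int32)
    posBc = np.empty(M, np.int64)
    posBs = np.empty((M, C), np.int64)
    scratch = np.empty_like(adj)

    best_len = threshold
    bu = bv = ba1 = bb1 = ba2 = bb2 = np.int32(-1)
    nout = 0
    check = req_masks.shape[0] > 0

    for ei in range(1, cnt):
        v = order[ei]
        pv = parent[v]
        nA, origA = _positions(adj, states, v, pv, lparA, lordA,
                               posAa, posAb, posAc, posAs)
        nB, origB = _positions(adj, states, pv, v, lparB, lordB,
                               posBa, posBb, posBc, posBs)
        for ia in range(nA):
            ca = posAc[ia]
            if ca > best_len:
                continue
            for ib in range(nB):
                if ia == origA and ib == origB:
                    continue
                cand = ca + posBc[ib]
                if cand > best_len:
                    continue
                for c in range(C):
                    if posAs[ia, c] & posBs[ib, c] == 0:
                        cand += 1
                        if cand > best_len:
                            break
                if mode == 0:
                    if cand >= best_len:
                        continue
                else:
                    if cand != threshold:
                        continue
                if check:
                    apply_tbr(adj, scratch, n, v, pv,
                              posAa[ia], posAb[ia], posBa[ib], posBb[ib])
                    if not constraints_ok(scratch, 0, n, full_mask,
                                          req_masks, req_signs):
                        continue
                if mode == 0:
                    best_len = cand
                    bu, bv = v, pv
                    ba1, bb1 = posAa[ia], posAb[ia]
                    ba2, bb2 = posBa[ib], posBb[ib]
                else:
                    if nout < out_moves.shape[0]:
                        out_moves[nout, 0] = v
                        out_moves[nout, 1] = pv
                        out_moves[nout, 2] = posAa[ia]
                        out_moves[nout, 3] = posAb[ia]
                        out_moves[nout, 4] = posBa[ib]
                        out_moves[nout, 5] = posBb[ib]
                    nout += 1
    return best_len, bu, bv, ba1, bb1, ba2, bb2, nout


@njit(cache=True)
def wagner_build(states, n, order, seed, req_masks, req_signs):
    """Greedy stepwise-addition (Wagner) tree.

    Taxa are inserted in the given order, each on the edge minimising
    the resulting Fitch length; ties are broken by a seeded uniform
    choice.  Groups with sign +1 are kept monophyletic at every stage
    (their insertion positions are filtered); sign -1 groups are
    ignored here.
    """
    np.random.seed(seed)
    M = 2 * n - 2
    C = states.shape[1]
    adj = np.full((M, 3), -1, np.int32)
    t0, t1, t2 = order[0], order[1], order[2]
    hub = n
    adj[hub, 0] = t0
    adj[hub, 1] = t1
    adj[hub, 2] = t2
    adj[t0, 0] = hub
    adj[t1, 0] = hub
    adj[t2, 0] = hub
    placed = (np.int64(1) << t0) | (np.int64(1) << t1) | (np.int64(1) << t2)
    next_int = n + 1

    lpar = np.empty(M, np.int32)
    lord = np.empty(M, np.int32)
    pos_a = np.empty(M, np.int32)
    pos_b = np.empty(M, np.int32)
    pos_c = np.empty(M, np.int64)
    pos_s = np.empty((M, C), np.int64)
    cand = np.empty(M, np.int32)
    scratch = np.empty_like(adj)
    one = np.empty(1, np.int64)
    sg = np.ones(1, np.int8)
    ngroups = req_masks.shape[0]
    check = ngroups > 0

    for idx in range(3, n):
        t = order[idx]
        new_placed = placed | (np.int64(1) << t)
        npos, _ = _positions(adj, states, t0, -1, lpar, lord,
                             pos_a, pos_b, pos_c, pos_s)
        best = INF
        ncand = 0
        for p in range(npos):
            cost = pos_c[p]
            for c in range(C):
                if pos_s[p, c] & states[t, c] == 0:
                    cost += 1
            if cost > best:
                continue
            if check:
                _copy_adj(adj, scratch)
                _insert_leaf(scratch, t, next_int, pos_a[p], pos_b[p])
                ok = True
                for g in range(ngroups):
                    if req_signs[g] <= 0:
                        continue
                    one[0] = req_masks[g] & new_placed
                    if not constraints_ok(scratch, t0, n, new_placed, one, sg):
                        ok = False
                        break
                if not ok:
                    continue
            if cost < best:
                best = cost
                ncand = 0
            cand[ncand] = p
            ncand += 1
        choice = cand[np.random.randint(ncand)]
        _insert_leaf(adj, t, next_int, pos_a[choice], pos_b[choice])
        next_int += 1
        placed = new_placed
    return adj


@njit(cache=True)
def _copy_adj(src, dst):
    for i in range(src.shape[0]):
        for k in range(3):
            dst[i, k] = src[i, k]


@njit(cache=True)
def _insert_leaf(out, leaf, junction, a, b):
    """Insert ``leaf`` (in place) via a new ``junction`` on edge (a, b)."""
    if a == b:  # single-node component: direct edge
        out[leaf, 0] = a
        for k in range(3):
            if out[a, k] == -1:
                out[a, k] = leaf
                break
        return
    for k in range(3):
        if out[a, k] == b:
            out[a, k] = junction
        if out[b, k] == a:
            out[b, k] = junction
    out[junction, 0] = a
    out[junction, 1] = b
    out[junction, 2] = leaf
    out[leaf, 0] = junction


@njit(cache=True)
def collapsed_splits(adj, states, n, nstates, rule, out_masks):
    """Splits retained after zero-length-branch collapsing.

    rule 0 (min_zero): collapse an internal edge if some most
    parsimonious reconstruction puts zero changes on it; rule 1
    (max_zero): collapse only if every MPR does; rule 2: keep all.
    Fills ``out_masks`` with the leaf-mask below each retained internal
    edge and returns the count.
    """
    M = adj.shape[0]
    C = states.shape[1]
    parent = np.empty(M, np.int32)
    order = np.empty(M, np.int32)
    cnt = _traverse(adj, 0, parent, order)
    below = np.zeros(M, np.int64)
    for i in range(cnt - 1, -1, -1):
        v = order[i]
        if v < n:
            below[v] = np.int64(1) << v
        else:
            acc = np.int64(0)
            for k in range(3):
                u = adj[v, k]
                if u >= 0 and u != parent[v]:
                    acc |= below[u]
            below[v] = acc

    keep = np.zeros(M, np.int8)
    for i in range(1, cnt):
        v = order[i]
        if v >= n and parent[v] >= n:
            keep[v] = 1
    if rule != 2:
        K = 8
        D = np.empty((M, K), np.int64)
        V = np.empty((M, K), np.int64)
        minD = np.empty(M, np.int64)
        minV = np.empty(M, np.int64)
        for c in range(C):
            k = nstates[c]
            # subtree costs
            for i in range(cnt - 1, -1, -1):
                v = order[i]
                if v < n:
                    for s in range(k):
                        D[v, s] = 0 if (states[v, c] >> s) & 1 else INF
                else:
                    for s in range(k):
                        D[v, s] = 0
                    for kk in range(3):
                        u = adj[v, kk]
                        if u >= 0 and u != parent[v]:
                            m = INF
                            for s in range(k):
                                if D[u, s] < m:
                                    m = D[u, s]
                            for s in range(k):
                                add = D[u, s]
                                if m + 1 < add:
                                    add = m + 1
                                D[v, s] += add
                m = INF
                for s in range(k):
                    if D[v, s] < m:
                        m = D[v, s]
                minD[v] = m
            c0 = adj[0, 0]
            Lc = INF
            for s in range(k):
                cost = D[c0, s] + (0 if (states[0, c] >> s) & 1 else 1)
                if cost < Lc:
                    Lc = cost
            # complement costs, conditioned on the parent's state
            for i in range(1, cnt):
                v = order[i]
                p = parent[v]
                if p == 0:
                    for s in range(k):
                        V[v, s] = 0 if (states[0, c] >> s) & 1 else INF
                else:
                    sib = np.int32(-1)
                    for kk in range(3):
                        u = adj[p, kk]
                        if u >= 0 and u != v and parent[u] == p:
                            sib = u
                    for s in range(k):
                        a = D[sib, s]
                        if minD[sib] + 1 < a:
                            a = minD[sib] + 1
                        b = V[p, s]
                        if minV[p] + 1 < b:
                            b = minV[p] + 1
                        V[v, s] = a + b
                m = INF
                for s in range(k):
                    if V[v, s] < m:
                        m = V[v, s]
                minV[v] = m
                if keep[v] == 1:
                    if rule == 0:
                        zero_possible = False
                        for s in range(k):
                            if D[v, s] + V[v, s] == Lc:
                                zero_possible = True
                                break
                        if not zero_possible:
                            keep[v] = 2  # pinned: some char needs a change
                    else:
                        change_possible = False
                        for s in range(k):
                            for s2 in range(k):
                                if s != s2 and D[v, s] + V[v, s2] + 1 <= Lc:
                                    change_possible = True
                                    break
                            if change_possible:
                                break
                        if change_possible:
                            keep[v] = 2
    nkept = 0
    for i in range(1, cnt):
        v = order[i]
        if v >= n and parent[v] >= n:
            if rule == 2 or keep[v] == 2:
                out_masks[nkept] = below[v]
                nkept += 1
    return nkept
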