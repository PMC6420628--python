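"""Numba kernels for the sliding-window emergence scan.

The genome scan rebuilds a neighbor-joining tree for every variant from a
sliding window of SNP distances.  Doing this in pure Python for hundreds of
thousands of variants is prohibitive, so the inner loop lives here: an
incrementally updated pair-difference matrix, a small-matrix NJ with the
deterministic lowest-pair tie rule, midpoint rooting, and the
child-disagreement emergence count.  The Python implementations in
:mod:`remergence.phylo` and :mod:`remergence.emergence` are the readable
reference; tests assert kernel/reference agreement.

State codes used by the emergence pass: 0/1 = genotype, 2 = emergence event,
3 = absent (missing leaves are pruned by absorption).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# flags reported per variant by the scan
FLAG_NARROW_WINDOW = 1  # fewer than 4 variants in the local window
FLAG_DEGENERATE_ROOT = 2  # zero tree diameter; rooting fell back to first edge


@njit(cache=True)
def nj_edges(D):
    """Neighbor joining (Saitou-Nei) on a symmetric distance matrix.

    Returns an undirected edge list ``(eu, ev, elen)`` over ``2n-2`` nodes:
    leaves ``0..n-1`` in input order, internal nodes numbered in join order,
    the final node being the central trifurcation.  Ties in the Q criterion
    are broken toward the lowest (i, j) index pair; negative branch-length
    estimates are clamped to zero.
    """
    n = D.shape[0]
    maxn = 2 * n - 2
    d = np.zeros((maxn, maxn), dtype=np.float64)
    d[:n, :n] = D
    active = np.zeros(maxn, dtype=np.bool_)
    active[:n] = True
    eu = np.empty(2 * n - 3, dtype=np.int32)
    ev = np.empty(2 * n - 3, dtype=np.int32)
    el = np.empty(2 * n - 3, dtype=np.float64)
    ne = 0
    nxt = n
    cnt = n
    idx = np.empty(maxn, dtype=np.int32)
    while cnt > 3:
        k = 0
        for a in range(maxn):
            if active[a]:
                idx[k] = a
                k += 1
        r = np.zeros(k, dtype=np.float64)
        for ii in range(k):
            s = 0.0
            for jj in range(k):
                s += d[idx[ii], idx[jj]]
            r[ii] = s
        best = np.inf
        bi = -1
        bj = -1
        for ii in range(k):
            for jj in range(ii + 1, k):
                q = (cnt - 2) * d[idx[ii], idx[jj]] - r[ii] - r[jj]
                if q < best:
                    best = q
                    bi = ii
                    bj = jj
        a = idx[bi]
        b = idx[bj]
        la = 0.5 * d[a, b] + (r[bi] - r[bj]) / (2.0 * (cnt - 2))
        lb = d[a, b] - la
        if la < 0.0:
            la = 0.0
        if lb < 0.0:
            lb = 0.0
        w = nxt
        nxt += 1
        for ii in range(k):
            c = idx[ii]
            if c != a and c != b:
                nd = 0.5 * (d[a, c] + d[b, c] - d[a, b])
                d[w, c] = nd
                d[c, w] = nd
        active[a] = False
        active[b] = False
        active[w] = True
        eu[ne] = a
        ev[ne] = w
        el[ne] = la
        ne += 1
        eu[ne] = b
        ev[ne] = w
        el[ne] = lb
        ne += 1
        cnt -= 1
    # final three nodes joined at the central node
    k = 0
    for a in range(maxn):
        if active[a]:
            idx[k] = a
            k += 1
    x, y, z = idx[0], idx[1], idx[2]
    c = nxt  # == maxn - 1
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    if lx < 0.0:
        lx = 0.0
    if ly < 0.0:
        ly = 0.0
    if lz < 0.0:
        lz = 0.0
    eu[ne] = x
    ev[ne] = c
    el[ne] = lx
    ne += 1
    eu[ne] = y
    ev[ne] = c
    el[ne] = ly
    ne += 1
    eu[ne] = z
    ev[ne] = c
    el[ne] = lz
    ne += 1
    return eu, ev, el


@njit(cache=True)
def midpoint_root(eu, ev, el, n_leaves):
    """Root an unrooted binary tree at the midpoint of its diameter path.

    Input nodes: ``0..n_leaves-1`` leaves, internal nodes up to ``2n-3``
    (degree 3).  Returns ``(left, right, blen, root, postorder, flag)`` over
    ``2n-1`` nodes where node ``2n-2`` is the new root; ``left``/``right``
    are -1 for leaves and ``blen`` is the branch length above each node.
    Ties (diameter pair, midpoint edge) break toward the lowest node
    indices.  ``flag`` is nonzero when the diameter is zero and the root
    placement fell back to the first edge.
    """
    n_nodes = 2 * n_leaves - 2
    n_edges = eu.shape[0]
    # adjacency, max degree 3
    adj = np.full((n_nodes, 3), -1, dtype=np.int32)
    alen = np.zeros((n_nodes, 3), dtype=np.float64)
    deg = np.zeros(n_nodes, dtype=np.int32)
    for e in range(n_edges):
        u = eu[e]
        v = ev[e]
        adj[u, deg[u]] = v
        alen[u, deg[u]] = el[e]
        deg[u] += 1
        adj[v, deg[v]] = u
        alen[v, deg[v]] = el[e]
        deg[v] += 1

    dist = np.zeros(n_nodes, dtype=np.float64)
    par = np.full(n_nodes, -1, dtype=np.int32)
    stack = np.empty(n_nodes, dtype=np.int32)

    best_d = -1.0
    best_u = 0
    best_v = 0
    for u in range(n_leaves):
        # DFS from u
        for i in range(n_nodes):
            par[i] = -1
        dist[u] = 0.0
        par[u] = u
        top = 0
        stack[top] = u
        top += 1
        while top > 0:
            top -= 1
            a = stack[top]
            for s in range(deg[a]):
                b = adj[a, s]
                if par[b] == -1:
                    par[b] = a
                    dist[b] = dist[a] + alen[a, s]
                    stack[top] = b
                    top += 1
        for v in range(u + 1, n_leaves):
            if dist[v] > best_d + 1e-12:
                best_d = dist[v]
                best_u = u
                best_v = v

    flag = 0
    if best_d <= 0.0:
        # all-zero branch lengths: deterministic fallback on the first edge
        flag = FLAG_DEGENERATE_ROOT
        ra, rb = eu[0], ev[0]
        t = 0.0
    else:
        # recompute path from best_u
        for i in range(n_nodes):
            par[i] = -1
        dist[best_u] = 0.0
        par[best_u] = best_u
        top = 0
        stack[top] = best_u
        top += 1
        while top > 0:
            top -= 1
            a = stack[top]
            for s in range(deg[a]):
                b = adj[a, s]
                if par[b] == -1:
                    par[b] = a
                    dist[b] = dist[a] + alen[a, s]
                    stack[top] = b
                    top += 1
        half = 0.5 * best_d
        # walk from best_v toward best_u (dist decreases monotonically) until
        # the edge (parent, node) straddles the midpoint
        node = best_v
        while dist[par[node]] > half:
            node = par[node]
        ra = par[node]
        rb = node
        t = half - dist[ra]
        if t < 0.0:
            t = 0.0

    # build rooted structure: new root between ra and rb
    root = n_nodes
    total = n_nodes + 1
    left = np.full(total, -1, dtype=np.int32)
    right = np.full(total, -1, dtype=np.int32)
    blen = np.zeros(total, dtype=np.float64)
    rpar = np.full(total, -1, dtype=np.int32)
    rpar[ra] = root
    rpar[rb] = root
    left[root] = ra if ra < rb else rb
    right[root] = rb if ra < rb else ra
    split_len = 0.0
    for s in range(deg[ra]):
        if adj[ra, s] == rb:
            split_len = alen[ra, s]
            break
    blen[ra] = t
    blen[rb] = split_len - t if split_len > t else 0.0
    # orient remaining edges away from root by DFS from ra and rb
    top = 0
    stack[top] = ra
    top += 1
    stack[top] = rb
    top += 1
    order = np.empty(total, dtype=np.int32)
    no = 0
    order[no] = root
    no += 1
    while top > 0:
        top -= 1
        a = stack[top]
        order[no] = a
        no += 1
        for s in range(deg[a]):
            b = adj[a, s]
            if rpar[b] == -1 and not (a == ra and b == rb) and not (a == rb and b == ra):
                rpar[b] = a
                blen[b] = alen[a, s]
                if left[a] == -1:
                    left[a] = b
                elif b < left[a]:
                    right[a] = left[a]
                    left[a] = b
                else:
                    right[a] = b
                stack[top] = b
                top += 1
    # postorder = reversed preorder (children always after parents in `order`)
    postorder = order[::-1].copy()
    return left, right, blen, root, postorder, flag


@njit(cache=True)
def count_emergence_events(left, right, postorder, states):
    """Count independent emergence events on a rooted binary tree.

    ``states`` holds, for each node slot, the leaf genotype (0/1), 3 for a
    missing (pruned) leaf; internal entries are overwritten.  A node whose
    two resolved children carry different genotypes is assigned an event
    (state 2); an event child paired with a genotype child resolves to the
    genotype; two event children merge without a further event.
    """
    events = 0
    for k in range(postorder.shape[0]):
        nd = postorder[k]
        l = left[nd]
        if l < 0:
            continue
        a = states[l]
        b = states[right[nd]]
        if a == 3:
            states[nd] = b
        elif b == 3:
            states[nd] = a
        elif a == 2 and b == 2:
            states[nd] = 2
        elif a == 2:
            states[nd] = b
        elif b == 2:
            states[nd] = a
        elif a == b:
            states[nd] = a
        else:
            states[nd] = 2
            events += 1
    return events


@njit(cache=True)
def pair_differences(calls):
    """Missing-aware SNP distance matrix: d(i,j) = #loci where both are
    called and the calls differ."""
    S, L = calls.shape
    D = np.zeros((S, S), dtype=np.float64)
    for i in range(S):
        for j in range(i + 1, S):
            c = 0
            for k in range(L):
                a = calls[i, k]
                b = calls[j, k]
                if a >= 0 and b >= 0 and a != b:
                    c += 1
            D[i, j] = c
            D[j, i] = c
    return D


@njit(cache=True)
def _update_pairs(D, calls, col, sign):
    S = calls.shape[0]
    for i in range(S):
        a = calls[i, col]
        if a < 0:
            continue
        for j in range(i + 1, S):
            b = calls[j, col]
            if b >= 0 and a != b:
                D[i, j] += sign
                D[j, i] += sign


@njit(cache=True)
def scan_events(calls, chrom_bounds, window):
    """Sliding-window emergence scan over a sorted genotype matrix.

    For every variant, builds the local NJ tree from a ``window``-variant
    window centered on it (truncated at chromosome boundaries, never
    wrapped), midpoint-roots it, prunes missing leaves, and counts
    emergence events.  Variants whose minor-genotype count among called
    strains is <= 1 have a closed-form event count (0 if monomorphic,
    otherwise exactly 1) and skip tree construction.

    Returns ``(n_events, n_alt, n_called, flags)`` arrays over all loci.
    """
    S, L = calls.shape
    n_events = np.zeros(L, dtype=np.int32)
    n_alt = np.zeros(L, dtype=np.int32)
    n_called = np.zeros(L, dtype=np.int32)
    flags = np.zeros(L, dtype=np.uint8)
    states = np.empty(2 * S - 1, dtype=np.int8)

    for c in range(chrom_bounds.shape[0] - 1):
        s0 = chrom_bounds[c]
        s1 = chrom_bounds[c + 1]
        lc = s1 - s0
        if lc == 0:
            continue
        w0 = window if window < lc else lc
        D = np.zeros((S, S), dtype=np.float64)
        for col in range(s0, s0 + w0):
            _update_pairs(D, calls, col, 1.0)
        lo = s0
        hi = s0 + w0
        have_tree = False
        left = np.empty(0, dtype=np.int32)
        right = np.empty(0, dtype=np.int32)
        postorder = np.empty(0, dtype=np.int32)
        root = -1
        rflag = 0
        for i in range(s0, s1):
            nlo = i - window // 2
            if nlo < s0:
                nlo = s0
            nhi = nlo + window
            if nhi > s1:
                nhi = s1
                nlo = nhi - window
                if nlo < s0:
                    nlo = s0
            moved = False
            while hi < nhi:
                _update_pairs(D, calls, hi, 1.0)
                hi += 1
                moved = True
            while lo < nlo:
                _update_pairs(D, calls, lo, -1.0)
                lo += 1
                moved = True
            if moved:
                have_tree = False

            na = 0
            nc = 0
            for s in range(S):
                v = calls[s, i]
                if v >= 0:
                    nc += 1
                    if v == 1:
                        na += 1
            n_alt[i] = na
            n_called[i] = nc
            f = 0
            if hi - lo < 4:
                f |= FLAG_NARROW_WINDOW
            minor = na if na <= nc - na else nc - na
            if minor == 0:
                n_events[i] = 0
                flags[i] = f
                continue
            if minor == 1 or nc < 3 or S < 3:
                n_events[i] = 1
                flags[i] = f
                continue
            if not have_tree:
                eu, ev, el = nj_edges(D)
                left, right, _blen, root, postorder, rflag = midpoint_root(
                    eu, ev, el, S
                )
                have_tree = True
            f |= rflag
            for s in range(S):
                v = calls[s, i]
                states[s] = v if v >= 0 else 3
            n_events[i] = count_emergence_events(left, right, postorder, states)
            flags[i] = f
    return n_events, n_alt, n_called, flags


@njit(cache=True)
def identity_fractions(qcalls, rcalls, chrom_bounds, window, stride):
    """Sliding-window identity between two call vectors.

    Returns ``(center_idx, identity, n_cocalled)`` for window centers every
    ``stride`` variants within each chromosome (windows truncated at
    chromosome edges).  Identity is the fraction of co-called loci with
    equal calls; NaN when no locus in the window is co-called.
    """
    L = qcalls.shape[0]
    n_out = 0
    for c in range(chrom_bounds.shape[0] - 1):
        lc = chrom_bounds[c + 1] - chrom_bounds[c]
        if lc > 0:
            n_out += (lc + stride - 1) // stride
    centers = np.empty(n_out, dtype=np.int64)
    ident = np.empty(n_out, dtype=np.float64)
    ncoc = np.empty(n_out, dtype=np.int64)
    k = 0
    for c in range(chrom_bounds.shape[0] - 1):
        s0 = chrom_bounds[c]
        s1 = chrom_bounds[c + 1]
        for i in range(s0, s1, stride):
            lo = i - window // 2
            if lo < s0:
                lo = s0
            hi = lo + window
            if hi > s1:
                hi = s1
                lo = hi - window
                if lo < s0:
                    lo = s0
            co = 0
            eq = 0
            for j in range(lo, hi):
                a = qcalls[j]
                b = rcalls[j]
                if a >= 0 and b >= 0:
                    co += 1
                    if a == b:
                        eq += 1
            centers[k] = i
            ncoc[k] = co
            ident[k] = eq / co if co > 0 else np.nan
            k += 1
    return centers[:k], ident[:k], ncoc[:k]
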