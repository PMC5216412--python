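"""Numba kernels for the STR coalescent MCMC.

Hot paths only: SMM transition kernels (Miller's backward Bessel
recurrence, normalised so probabilities over the integers sum to one),
Felsenstein pruning over a truncated integer repeat window (with per-node
scaling), the inhomogeneous structured-coalescent log prior, and the
within-sweep genealogy node-time moves.

Array conventions (n tips, 2n-1 nodes, L loci, window width W):

* ``times``/``parent``/``left``/``right``: flat genealogy arrays; tips are
  nodes ``0..n-1`` at time 0; ``parent[root] == -1``; tips have
  ``left == right == -1``.
* ``tipstates[i, l]``: window index of tip ``i``'s repeat at locus ``l``
  (-1 for missing, treated as marginalised over the whole integer line).
* ``kernels[i]``/``sups[i]``: SMM kernel and its support length for the
  branch above node ``i``.
* ``partials``/``logscale``: scaled pruning partials per node and locus.
* Population branches: ``pop_parent``, ``pop_lower`` (time the branch is
  created by the merge of its children; 0 for terminals), ``pop_weight``
  (constant fraction of the total size), ``pop_depth``; ``node_lca[i]`` is
  the population-tree LCA of the tips below genealogy node ``i``.
"""

import numba as nb
import numpy as np

NEG_INF = -np.inf


@nb.njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@nb.njit(cache=True)
def smm_kernel_fill(theta, out):
    """Fill ``out[d] = exp(-theta) I_d(theta)``; return support length."""
    W = out.shape[0]
    for j in range(W):
        out[j] = 0.0
    if theta <= 1e-300:
        out[0] = 1.0
        return 1
    start = int(max(W, theta) + 15.0 * np.sqrt(max(theta, 1.0)) + 40.0)
    fp = 0.0  # f_{d+1}
    fc = 1e-280  # f_d
    S = 0.0
    d = start
    while True:
        if d < W:
            out[d] = fc
        if d == 0:
            S += fc
            break
        S += 2.0 * fc
        fn = fp + (2.0 * d / theta) * fc
        fp = fc
        fc = fn
        d -= 1
        if fc > 1e250:
            fc *= 1e-250
            fp *= 1e-250
            S *= 1e-250
            for j in range(W):
                out[j] *= 1e-250
    inv = 1.0 / S
    sup = 1
    for j in range(W):
        out[j] *= inv
        if out[j] > 1e-13:
            sup = j + 1
    return sup


@nb.njit(cache=True)
def _message(out, kernel, sup, is_tip, tipstate_l, partial_l, W):
    """Transition message through one branch for a single locus."""
    if is_tip:
        if tipstate_l < 0:
            for w in range(W):
                out[w] = 1.0
        else:
            for w in range(W):
                d = w - tipstate_l
                if d < 0:
                    d = -d
                out[w] = kernel[d] if d < sup else 0.0
    else:
        for w in range(W):
            lo = w - sup + 1
            if lo < 0:
                lo = 0
            hi = w + sup
            if hi > W:
                hi = W
            acc = 0.0
            for v in range(lo, hi):
                d = w - v
                if d < 0:
                    d = -d
                acc += kernel[d] * partial_l[v]
            out[w] = acc


@nb.njit(cache=True)
def _combine_node(i, left, right, n_tips, tipstates, partials, logscale,
                  kernels, sups, W, L, out_partial, out_logscale, msg):
    """Compute scaled partials for internal node ``i`` into the buffers."""
    c1 = left[i]
    c2 = right[i]
    for l in range(L):
        _message(msg[0], kernels[c1], sups[c1], c1 < n_tips,
                 tipstates[c1, l] if c1 < n_tips else -1,
                 partials[c1, l], W)
        _message(msg[1], kernels[c2], sups[c2], c2 < n_tips,
                 tipstates[c2, l] if c2 < n_tips else -1,
                 partials[c2, l], W)
        mx = 0.0
        for w in range(W):
            val = msg[0][w] * msg[1][w]
            out_partial[l, w] = val
            if val > mx:
                mx = val
        ls = 0.0
        if c1 >= n_tips:
            ls += logscale[c1, l]
        if c2 >= n_tips:
            ls += logscale[c2, l]
        if mx > 0.0:
            inv = 1.0 / mx
            for w in range(W):
                out_partial[l, w] *= inv
            ls += np.log(mx)
        else:
            ls = NEG_INF
        out_logscale[l] = ls


@nb.njit(cache=True)
def full_likelihood(times, parent, left, right, n_tips, postorder,
                    tipstates, partials, logscale, kernels, sups,
                    W, L, mu, msg):
    """Recompute all kernels and partials; return the log likelihood."""
    n_nodes = 2 * n_tips - 1
    for i in range(n_nodes):
        p = parent[i]
        if p != -1:
            th = mu * (times[p] - times[i])
            if th < 0.0:
                return NEG_INF
            sups[i] = smm_kernel_fill(th, kernels[i])
    for k in range(postorder.shape[0]):
        i = postorder[k]
        _combine_node(i, left, right, n_tips, tipstates, partials, logscale,
                      kernels, sups, W, L, partials[i], logscale[i], msg)
    root = postorder[postorder.shape[0] - 1]
    ll = 0.0
    for l in range(L):
        s = 0.0
        for w in range(W):
            s += partials[root, l, w]
        if s <= 0.0 or not np.isfinite(logscale[root, l]):
            return NEG_INF
        ll += np.log(s) + logscale[root, l]
    ll -= L * np.log(W)
    return ll


@nb.njit(cache=True)
def update_node_lca(postorder, left, right, n_tips, tip_branch,
                    pop_parent, pop_depth, node_lca):
    for i in range(n_tips):
        node_lca[i] = tip_branch[i]
    for k in range(postorder.shape[0]):
        i = postorder[k]
        a = node_lca[left[i]]
        b = node_lca[right[i]]
        while a != b:
            if pop_depth[a] >= pop_depth[b]:
                a = pop_parent[a]
            else:
                b = pop_parent[b]
        node_lca[i] = a


@nb.njit(cache=True)
def _inv_size_integral(t1, t2, n0_tot, growth_rate, beta, n_anc):
    total = 0.0
    hi = t2 if t2 < beta else beta
    if hi > t1:
        if growth_rate == 0.0:
            total += (hi - t1) / n0_tot
        else:
            total += (np.exp(growth_rate * hi) - np.exp(growth_rate * t1)) / (
                n0_tot * growth_rate
            )
    lo = t1 if t1 > beta else beta
    if t2 > lo:
        total += (t2 - lo) / n_anc
    return total


@nb.njit(cache=True)
def coal_logprior(times, n_tips, node_lca, tip_branch,
                  pop_parent, pop_lower, pop_weight, n_pop_nodes,
                  split_nodes, n0_tot, growth_rate, beta):
    """Log density of the genealogy under the splitting, piecewise-growing
    coalescent.  Returns -inf for genealogies incompatible with the split
    times (inter-population coalescence below the split)."""
    n_anc = n0_tot * np.exp(-growth_rate * beta)
    n_int = n_tips - 1
    # ascending internal node times
    itimes = np.empty(n_int)
    inode = np.empty(n_int, dtype=np.int64)
    for j in range(n_int):
        itimes[j] = times[n_tips + j]
        inode[j] = n_tips + j
    order = np.argsort(itimes)

    k = np.zeros(n_pop_nodes, dtype=np.int64)
    for i in range(n_tips):
        k[tip_branch[i]] += 1

    # splits ascending by creation time
    n_splits = split_nodes.shape[0]
    stimes = np.empty(n_splits)
    for j in range(n_splits):
        stimes[j] = pop_lower[split_nodes[j]]
    sorder = np.argsort(stimes)

    def_rate = 0.0
    for b in range(n_pop_nodes):
        if k[b] >= 2:
            def_rate += k[b] * (k[b] - 1) / (2.0 * pop_weight[b])
    A = def_rate

    logp = 0.0
    t_prev = 0.0
    si = 0
    for j in range(n_int):
        e = inode[order[j]]
        t_e = times[e]
        # structural split events before this coalescence
        while si < n_splits and pop_lower[split_nodes[sorder[si]]] <= t_e:
            b = split_nodes[sorder[si]]
            t_s = pop_lower[b]
            logp -= A * _inv_size_integral(t_prev, t_s, n0_tot, growth_rate,
                                           beta, n_anc)
            t_prev = t_s
            for c in range(n_pop_nodes):
                if pop_parent[c] == b:
                    k[b] += k[c]
                    k[c] = 0
            A = 0.0
            for bb in range(n_pop_nodes):
                if k[bb] >= 2:
                    A += k[bb] * (k[bb] - 1) / (2.0 * pop_weight[bb])
            si += 1
        logp -= A * _inv_size_integral(t_prev, t_e, n0_tot, growth_rate,
                                        beta, n_anc)
        t_prev = t_e
        # population branch containing the coalescing lineages
        b = node_lca[e]
        if t_e < pop_lower[b]:
            return NEG_INF
        while pop_parent[b] != -1 and t_e >= pop_lower[pop_parent[b]]:
            b = pop_parent[b]
        if k[b] < 2:
            return NEG_INF
        n_t = n0_tot * np.exp(-growth_rate * t_e) if t_e < beta else n_anc
        logp += -np.log(pop_weight[b] * n_t)
        k[b] -= 1
        A = 0.0
        for bb in range(n_pop_nodes):
            if k[bb] >= 2:
                A += k[bb] * (k[bb] - 1) / (2.0 * pop_weight[bb])
    return logp


@nb.njit(cache=True)
def sweep_node_times(times, parent, left, right, n_tips, tipstates,
                     partials, logscale, kernels, sups, W, L, mu,
                     cur_ll, cur_lp,
                     node_lca, tip_branch, pop_parent, pop_lower, pop_weight,
                     n_pop_nodes, split_nodes, n0_tot, growth_rate, beta,
                     root_lam,
                     pbuf, lsbuf, kbuf, supbuf, path, msg):
    """One Metropolis sweep of node-time moves over all internal nodes.

    Non-root nodes propose uniformly on (max child time, parent time)
    (symmetric); the root rescales its gap above the older child.  The
    likelihood is updated incrementally along the path to the root.
    Returns (loglik, logprior, accepted, attempted).
    """
    n_nodes = 2 * n_tips - 1
    accepted = 0
    attempted = 0
    # visit internal nodes in random order (Fisher-Yates)
    order = np.empty(n_tips - 1, dtype=np.int64)
    for j in range(n_tips - 1):
        order[j] = n_tips + j
    for j in range(n_tips - 2, 0, -1):
        r = int(np.random.random() * (j + 1))
        tmp = order[j]
        order[j] = order[r]
        order[r] = tmp

    for oj in range(n_tips - 1):
        i = order[oj]
        lo = times[left[i]]
        if times[right[i]] > lo:
            lo = times[right[i]]
        is_root = parent[i] == -1
        log_hast = 0.0
        if is_root:
            u = (np.random.random() * 2.0 - 1.0) * root_lam
            tnew = lo + (times[i] - lo) * np.exp(u)
            log_hast = u
        else:
            hi = times[parent[i]]
            if hi <= lo:
                continue
            tnew = lo + np.random.random() * (hi - lo)
        attempted += 1

        # prior under proposed time
        told = times[i]
        times[i] = tnew
        new_lp = coal_logprior(times, n_tips, node_lca, tip_branch,
                               pop_parent, pop_lower, pop_weight,
                               n_pop_nodes, split_nodes,
                               n0_tot, growth_rate, beta)
        if not np.isfinite(new_lp):
            times[i] = told
            continue

        # incremental likelihood: new kernels for the three touched edges
        # kbuf rows: 0 -> left[i], 1 -> right[i], 2 -> i (if non-root)
        c1 = left[i]
        c2 = right[i]
        for w in range(W):
            kbuf[0, w] = kernels[c1, w]
            kbuf[1, w] = kernels[c2, w]
        supbuf[0] = sups[c1]
        supbuf[1] = sups[c2]
        sups[c1] = smm_kernel_fill(mu * (tnew - times[c1]), kernels[c1])
        sups[c2] = smm_kernel_fill(mu * (tnew - times[c2]), kernels[c2])
        if not is_root:
            for w in range(W):
                kbuf[2, w] = kernels[i, w]
            supbuf[2] = sups[i]
            sups[i] = smm_kernel_fill(mu * (times[parent[i]] - tnew), kernels[i])

        # recompute partials along the path i -> root into buffers
        depth = 0
        node = i
        while node != -1:
            path[depth] = node
            depth += 1
            node = parent[node]
        # stash originals, compute in place level by level using buffers:
        # we compute into pbuf and only commit on accept
        for d in range(depth):
            nd = path[d]
            if d == 0:
                _combine_node(nd, left, right, n_tips, tipstates, partials,
                              logscale, kernels, sups, W, L,
                              pbuf[d], lsbuf[d], msg)
            else:
                # child on path uses buffered partials: temporarily swap
                ch = path[d - 1]
                for l in range(L):
                    for w in range(W):
                        tmpv = partials[ch, l, w]
                        partials[ch, l, w] = pbuf[d - 1, l, w]
                        pbuf[d - 1, l, w] = tmpv
                    tmps = logscale[ch, l]
                    logscale[ch, l] = lsbuf[d - 1, l]
                    lsbuf[d - 1, l] = tmps
                _combine_node(nd, left, right, n_tips, tipstates, partials,
                              logscale, kernels, sups, W, L,
                              pbuf[d], lsbuf[d], msg)
                # swap back (originals restored; buffers hold new values)
                for l in range(L):
                    for w in range(W):
                        tmpv = partials[ch, l, w]
                        partials[ch, l, w] = pbuf[d - 1, l, w]
                        pbuf[d - 1, l, w] = tmpv
                    tmps = logscale[ch, l]
                    logscale[ch, l] = lsbuf[d - 1, l]
                    lsbuf[d - 1, l] = tmps
        root_d = depth - 1
        new_ll = 0.0
        ok = True
        for l in range(L):
            s = 0.0
            for w in range(W):
                s += pbuf[root_d, l, w]
            if s <= 0.0 or not np.isfinite(lsbuf[root_d, l]):
                ok = False
                break
            new_ll += np.log(s) + lsbuf[root_d, l]
        if ok:
            new_ll -= L * np.log(W)

        accept = False
        if ok:
            dlog = (new_ll - cur_ll) + (new_lp - cur_lp) + log_hast
            if dlog >= 0.0 or np.log(np.random.random()) < dlog:
                accept = True
        if accept:
            for d in range(depth):
                nd = path[d]
                for l in range(L):
                    for w in range(W):
                        partials[nd, l, w] = pbuf[d, l, w]
                    logscale[nd, l] = lsbuf[d, l]
            cur_ll = new_ll
            cur_lp = new_lp
            accepted += 1
        else:
            times[i] = told
            for w in range(W):
                kernels[c1, w] = kbuf[0, w]
                kernels[c2, w] = kbuf[1, w]
            sups[c1] = supbuf[0]
            sups[c2] = supbuf[1]
            if not is_root:
                for w in range(W):
                    kernels[i, w] = kbuf[2, w]
                sups[i] = supbuf[2]
    return cur_ll, cur_lp, accepted, attempted
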