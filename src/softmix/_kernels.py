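"""Numba kernels behind the soft-tree ensemble sampler.

Trees live in flat, slot-compacted arrays so the whole backfitting sweep can
run in nopython mode.  Slot 0 is always the root; every active slot k < nnode
is either a branch (``var[k] >= 0`` with two children) or a leaf
(``var[k] == -1`` carrying ``mu[k]``).  All exposures are on the internal
min-max [0, 1] scale and the response on the internal [-0.5, 0.5] scale.

Randomness is always drawn from a ``numpy.random.Generator`` passed in by the
caller, so chains are bitwise reproducible from a single seed.
"""

import numpy as np
from numba import njit

# Move codes returned by _propose.
GROW, PRUNE, CHANGE = 0, 1, 2

NMAX = 64  # slot capacity per tree; proposals beyond this are auto-rejected


@njit(cache=True)
def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _basis(var, cut, left, right, nnode, tau, Z):
    """Leaf-weight matrix Phi (n x L), leaves taken in slot order.

    Phi[i, l] is the product over the leaf's ancestors of the logistic gate
    psi((C_b - z_jb)/tau) toward the <=-child and its complement toward the
    other child; rows sum to one.
    """
    n = Z.shape[0]
    W = np.zeros((nnode, n))
    for i in range(n):
        W[0, i] = 1.0
    stack = np.empty(nnode, np.int64)
    stack[0] = 0
    top = 1
    while top > 0:
        top -= 1
        b = stack[top]
        if var[b] >= 0:
            j = var[b]
            lc = left[b]
            rc = right[b]
            for i in range(n):
                g = _logistic((cut[b] - Z[i, j]) / tau)
                W[lc, i] = W[b, i] * g
                W[rc, i] = W[b, i] * (1.0 - g)
            stack[top] = lc
            top += 1
            stack[top] = rc
            top += 1
    L = 0
    for k in range(nnode):
        if var[k] < 0:
            L += 1
    Phi = np.empty((n, L))
    l = 0
    for k in range(nnode):
        if var[k] < 0:
            for i in range(n):
                Phi[i, l] = W[k, i]
            l += 1
    return Phi


@njit(cache=True)
def _marginal_loglik(Phi, r, sigma2, sigma_mu2):
    """log N(r; 0, sigma2*I + sigma_mu2*Phi Phi^T) via the L x L Woodbury form.

    Leaf coefficients are integrated out analytically; only an L x L Cholesky
    is needed since the leaf count L is far below n.
    """
    n, L = Phi.shape
    Q = Phi.T @ Phi
    b = Phi.T @ r
    c = sigma_mu2 / sigma2
    M = c * Q
    for l in range(L):
        M[l, l] += 1.0
    C = np.linalg.cholesky(M)
    logdet = 0.0
    for l in range(L):
        logdet += 2.0 * np.log(C[l, l])
    w = np.linalg.solve(M, b)
    quad = (r @ r) / sigma2 - (sigma_mu2 / (sigma2 * sigma2)) * (b @ w)
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + quad)


@njit(cache=True)
def _draw_leaves(Phi, r, sigma2, sigma_mu2, z):
    """Joint conjugate Gaussian draw of the leaf coefficients.

    Posterior: N(P^-1 Phi^T r / sigma2, P^-1) with
    P = Phi^T Phi / sigma2 + I / sigma_mu2.  ``z`` holds L standard normals.
    """
    L = Phi.shape[1]
    P = (Phi.T @ Phi) / sigma2
    for l in range(L):
        P[l, l] += 1.0 / sigma_mu2
    b = (Phi.T @ r) / sigma2
    C = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b)
    # solve C^T x = z (back substitution) so that x ~ N(0, P^-1)
    x = np.zeros(L)
    for i in range(L - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, L):
            s -= C[j, i] * x[j]
        x[i] = s / C[i, i]
    return mean + x


@njit(cache=True)
def _leaf_conditional(Phi, r, sigma2, sigma_mu2):
    """Posterior mean and covariance of the leaf coefficients (for tests)."""
    L = Phi.shape[1]
    P = (Phi.T @ Phi) / sigma2
    for l in range(L):
        P[l, l] += 1.0 / sigma_mu2
    b = (Phi.T @ r) / sigma2
    mean = np.linalg.solve(P, b)
    cov = np.linalg.inv(P)
    return mean, cov


@njit(cache=True)
def _admissible_interval(var, cut, left, parent, node, j):
    """Cutpoint interval for coordinate j at ``node``, from ancestor rules.

    Walking toward the root: an ancestor splitting on j caps the interval at
    its cutpoint on the side the path takes.  Empty intervals (lo >= hi) mean
    the proposal is invalid.
    """
    lo = 0.0
    hi = 1.0
    child = node
    p = parent[node]
    while p >= 0:
        if var[p] == j:
            if left[p] == child:
                if cut[p] < hi:
                    hi = cut[p]
            else:
                if cut[p] > lo:
                    lo = cut[p]
        child = p
        p = parent[p]
    return lo, hi


@njit(cache=True)
def _log_tree_prior(var, cut, left, parent, depth, nnode, s, gamma, beta_depth):
    """Log prior of a tree: depth-penalized topology plus split rules.

    A branch at depth d contributes log(gamma*(1+d)^-beta) + log s_j
    + log(1/|admissible interval|); a leaf contributes
    log(1 - gamma*(1+d)^-beta).  Cutpoints outside their admissible interval
    get -inf (used to auto-reject CHANGE proposals that invalidate
    descendants).
    """
    lp = 0.0
    for k in range(nnode):
        psplit = gamma * (1.0 + depth[k]) ** (-beta_depth)
        if var[k] >= 0:
            lo, hi = _admissible_interval(var, cut, left, parent, k, var[k])
            if cut[k] <= lo or cut[k] >= hi:
                return -np.inf
            lp += np.log(psplit) + np.log(s[var[k]]) - np.log(hi - lo)
        else:
            lp += np.log(1.0 - psplit)
    return lp


@njit(cache=True)
def _count_leaves(var, nnode):
    L = 0
    for k in range(nnode):
        if var[k] < 0:
            L += 1
    return L


@njit(cache=True)
def _count_prunable(var, left, right, nnode):
    """Branches whose both children are leaves (PRUNE candidates)."""
    c = 0
    for k in range(nnode):
        if var[k] >= 0 and var[left[k]] < 0 and var[right[k]] < 0:
            c += 1
    return c


@njit(cache=True)
def _categorical(s, u):
    """Index m with cumulative probability covering u (s sums to 1)."""
    acc = 0.0
    for m in range(s.size):
        acc += s[m]
        if u < acc:
            return m
    return s.size - 1


@njit(cache=True)
def _remove_leaf_slot(var, cut, left, right, parent, depth, mu, m, k):
    """Delete leaf slot k by moving the last active slot into it."""
    last = m - 1
    if k != last:
        var[k] = var[last]
        cut[k] = cut[last]
        left[k] = left[last]
        right[k] = right[last]
        parent[k] = parent[last]
        depth[k] = depth[last]
        mu[k] = mu[last]
        p = parent[k]
        if p >= 0:
            if left[p] == last:
                left[p] = k
            elif right[p] == last:
                right[p] = k
        if var[k] >= 0:
            parent[left[k]] = k
            parent[right[k]] = k
    return m - 1


@njit(cache=True)
def _propose(var, cut, left, right, parent, depth, mu, nnode, s,
             p_grow, p_prune, p_change,
             pvar, pcut, pleft, pright, pparent, pdepth, pmu, rng):
    """Draw one GROW / PRUNE / CHANGE proposal into the p* scratch arrays.

    Returns (move, valid, log_q_ratio, new_nnode).  ``log_q_ratio`` is
    log q(reverse) - log q(forward), the Metropolis-Hastings proposal term.
    A stump only admits GROW (move type resampled to GROW with probability 1,
    accounted for in the densities).
    """
    for k in range(nnode):
        pvar[k] = var[k]
        pcut[k] = cut[k]
        pleft[k] = left[k]
        pright[k] = right[k]
        pparent[k] = parent[k]
        pdepth[k] = depth[k]
        pmu[k] = mu[k]

    if nnode == 1:
        move = GROW
        log_pmove_fwd = 0.0  # grow is the only valid move at a stump
    else:
        u = rng.random()
        if u < p_grow:
            move = GROW
        elif u < p_grow + p_prune:
            move = PRUNE
        else:
            move = CHANGE
        log_pmove_fwd = (np.log(p_grow) if move == GROW
                         else np.log(p_prune) if move == PRUNE
                         else np.log(p_change))

    if move == GROW:
        if nnode + 2 > NMAX:
            return GROW, False, 0.0, nnode
        Lc = _count_leaves(var, nnode)
        li = rng.integers(0, Lc)
        k = -1
        cnt = -1
        for kk in range(nnode):
            if var[kk] < 0:
                cnt += 1
                if cnt == li:
                    k = kk
                    break
        j = _categorical(s, rng.random())
        lo, hi = _admissible_interval(var, cut, left, parent, k, j)
        if hi - lo <= 0.0:
            return GROW, False, 0.0, nnode
        C = lo + (hi - lo) * rng.random()
        c1 = nnode
        c2 = nnode + 1
        pvar[k] = j
        pcut[k] = C
        pleft[k] = c1
        pright[k] = c2
        for c in (c1, c2):
            pvar[c] = -1
            pcut[c] = 0.0
            pleft[c] = -1
            pright[c] = -1
            pparent[c] = k
            pdepth[c] = depth[k] + 1
            pmu[c] = 0.0
        nprun = _count_prunable(pvar, pleft, pright, nnode + 2)
        lq_fwd = (log_pmove_fwd - np.log(Lc) + np.log(s[j])
                  - np.log(hi - lo))
        lq_rev = np.log(p_prune) - np.log(nprun)
        return GROW, True, lq_rev - lq_fwd, nnode + 2

    if move == PRUNE:
        nprun = _count_prunable(var, left, right, nnode)
        pi = rng.integers(0, nprun)
        k = -1
        cnt = -1
        for kk in range(nnode):
            if var[kk] >= 0 and var[left[kk]] < 0 and var[right[kk]] < 0:
                cnt += 1
                if cnt == pi:
                    k = kk
                    break
        j_old = var[k]
        lo, hi = _admissible_interval(var, cut, left, parent, k, j_old)
        c1 = pleft[k]
        c2 = pright[k]
        pvar[k] = -1
        pcut[k] = 0.0
        pleft[k] = -1
        pright[k] = -1
        pmu[k] = 0.0
        a = c1 if c1 > c2 else c2
        b = c2 if c1 > c2 else c1
        m = _remove_leaf_slot(pvar, pcut, pleft, pright, pparent, pdepth, pmu,
                              nnode, a)
        m = _remove_leaf_slot(pvar, pcut, pleft, pright, pparent, pdepth, pmu,
                              m, b)
        lq_fwd = log_pmove_fwd - np.log(nprun)
        pg_rev = 0.0 if m == 1 else np.log(p_grow)  # stump reverse-grows w.p. 1
        Lp = _count_leaves(pvar, m)
        lq_rev = (pg_rev - np.log(Lp) + np.log(s[j_old]) - np.log(hi - lo))
        return PRUNE, True, lq_rev - lq_fwd, m

    # CHANGE: redraw the split rule of a uniformly chosen branch
    nbranch = (nnode - 1) // 2
    bi = rng.integers(0, nbranch)
    k = -1
    cnt = -1
    for kk in range(nnode):
        if var[kk] >= 0:
            cnt += 1
            if cnt == bi:
                k = kk
                break
    j_old = var[k]
    lo_o, hi_o = _admissible_interval(var, cut, left, parent, k, j_old)
    j_new = _categorical(s, rng.random())
    lo, hi = _admissible_interval(var, cut, left, parent, k, j_new)
    if hi - lo <= 0.0:
        return CHANGE, False, 0.0, nnode
    C = lo + (hi - lo) * rng.random()
    pvar[k] = j_new
    pcut[k] = C
    lq_fwd = np.log(s[j_new]) - np.log(hi - lo)
    lq_rev = np.log(s[j_old]) - np.log(hi_o - lo_o)
    return CHANGE, True, lq_rev - lq_fwd, nnode


@njit(cache=True)
def _update_tree(t, var2, cut2, left2, right2, parent2, depth2, mu2,
                 nnode1, tau1, Zs, resid, fits, s, sigma2, sigma_mu2,
                 gamma, beta_depth, p_grow, p_prune, p_change,
                 tau_rate, tau_prop_sd, rng):
    """One backfitting update of tree t: structure MH, bandwidth MH, leaf draw.

    ``resid`` is the full-model residual y - X beta - sum_t fit_t and is kept
    current in place; ``fits[t]`` holds this tree's fitted values.
    Returns 1 if the structure proposal was accepted.
    """
    var = var2[t]
    cut = cut2[t]
    left = left2[t]
    right = right2[t]
    parent = parent2[t]
    depth = depth2[t]
    mu = mu2[t]
    nnode = nnode1[t]
    tau = tau1[t]
    n = Zs.shape[0]

    r = np.empty(n)
    for i in range(n):
        r[i] = resid[i] + fits[t, i]

    Phi = _basis(var, cut, left, right, nnode, tau, Zs)
    ll_cur = _marginal_loglik(Phi, r, sigma2, sigma_mu2)
    lp_cur = _log_tree_prior(var, cut, left, parent, depth, nnode, s,
                             gamma, beta_depth)

    pvar = np.empty(NMAX, np.int64)
    pcut = np.empty(NMAX)
    pleft = np.empty(NMAX, np.int64)
    pright = np.empty(NMAX, np.int64)
    pparent = np.empty(NMAX, np.int64)
    pdepth = np.empty(NMAX, np.int64)
    pmu = np.empty(NMAX)

    move, valid, lqr, pn = _propose(
        var, cut, left, right, parent, depth, mu, nnode, s,
        p_grow, p_prune, p_change,
        pvar, pcut, pleft, pright, pparent, pdepth, pmu, rng)

    accepted = 0
    if valid:
        lp_prop = _log_tree_prior(pvar, pcut, pleft, pparent, pdepth, pn, s,
                                  gamma, beta_depth)
        if lp_prop > -np.inf:
            Phi_p = _basis(pvar, pcut, pleft, pright, pn, tau, Zs)
            ll_prop = _marginal_loglik(Phi_p, r, sigma2, sigma_mu2)
            if np.log(rng.random()) < ll_prop + lp_prop - ll_cur - lp_cur + lqr:
                for k in range(pn):
                    var[k] = pvar[k]
                    cut[k] = pcut[k]
                    left[k] = pleft[k]
                    right[k] = pright[k]
                    parent[k] = pparent[k]
                    depth[k] = pdepth[k]
                    mu[k] = pmu[k]
                nnode1[t] = pn
                nnode = pn
                Phi = Phi_p
                ll_cur = ll_prop
                accepted = 1

    # bandwidth: random-walk MH on log tau, exponential prior, leaves
    # marginalized out (a single-leaf tree therefore samples its prior)
    tau_new = tau * np.exp(tau_prop_sd * rng.standard_normal())
    Phi_t = _basis(var, cut, left, right, nnode, tau_new, Zs)
    ll_t = _marginal_loglik(Phi_t, r, sigma2, sigma_mu2)
    la = (ll_t - tau_rate * tau_new + np.log(tau_new)) \
        - (ll_cur - tau_rate * tau + np.log(tau))
    if np.log(rng.random()) < la:
        tau1[t] = tau_new
        Phi = Phi_t
        ll_cur = ll_t

    # conjugate joint draw of all leaf values, then refresh cached fits
    L = Phi.shape[1]
    z = rng.standard_normal(L)
    mu_new = _draw_leaves(Phi, r, sigma2, sigma_mu2, z)
    l = 0
    for k in range(nnode):
        if var[k] < 0:
            mu[k] = mu_new[l]
            l += 1
    fit_new = Phi @ mu_new
    for i in range(n):
        resid[i] += fits[t, i] - fit_new[i]
        fits[t, i] = fit_new[i]
    return accepted


@njit(cache=True)
def _split_counts(var2, nnode1, M):
    """Number of branches splitting on each exposure, across the forest."""
    counts = np.zeros(M, np.int64)
    T = var2.shape[0]
    for t in range(T):
        for k in range(nnode1[t]):
            if var2[t, k] >= 0:
                counts[var2[t, k]] += 1
    return counts


@njit(cache=True)
def _forest_eval(offsets, var, cut, left, right, mu, taus, Z):
    """Evaluate a snapshotted forest at the rows of Z (internal scales)."""
    n = Z.shape[0]
    T = offsets.size - 1
    out = np.zeros(n)
    for t in range(T):
        o = offsets[t]
        nn = offsets[t + 1] - o
        W = np.zeros((nn, n))
        for i in range(n):
            W[0, i] = 1.0
        stack = np.empty(nn, np.int64)
        stack[0] = 0
        top = 1
        while top > 0:
            top -= 1
            b = stack[top]
            if var[o + b] >= 0:
                j = var[o + b]
                lc = left[o + b]
                rc = right[o + b]
                for i in range(n):
                    g = _logistic((cut[o + b] - Z[i, j]) / taus[t])
                    W[lc, i] = W[b, i] * g
                    W[rc, i] = W[b, i] * (1.0 - g)
                stack[top] = lc
                top += 1
                stack[top] = rc
                top += 1
        for k in range(nn):
            if var[o + k] < 0:
                for i in range(n):
                    out[i] += mu[o + k] * W[k, i]
    return out


@njit(cache=True)
def _pd_cond(offsets, var, cut, left, right, mu, taus, Zs, m, grid,
             fixed_idx, fixed_val):
    """Univariate partial dependence of a snapshotted forest.

    f(g) = mean_i h(z_m = g, fixed vars clamped, rest = row i).  Because each
    branch gates exactly one coordinate, every leaf weight factorizes into a
    grid part (branches on m), a scalar part (branches on clamped vars) and a
    row part (all other branches), so the average over rows costs
    O(L * (G + n)) per tree instead of O(L * G * n).
    """
    G = grid.size
    n = Zs.shape[0]
    T = offsets.size - 1
    f = np.zeros(G)
    for t in range(T):
        o = offsets[t]
        nn = offsets[t + 1] - o
        Wg = np.ones((nn, G))
        Wr = np.ones((nn, n))
        Ws = np.ones(nn)
        stack = np.empty(nn, np.int64)
        stack[0] = 0
        top = 1
        while top > 0:
            top -= 1
            b = stack[top]
            if var[o + b] >= 0:
                j = var[o + b]
                lc = left[o + b]
                rc = right[o + b]
                fix = -1
                for q in range(fixed_idx.size):
                    if fixed_idx[q] == j:
                        fix = q
                        break
                if j == m:
                    for g in range(G):
                        e = _logistic((cut[o + b] - grid[g]) / taus[t])
                        Wg[lc, g] = Wg[b, g] * e
                        Wg[rc, g] = Wg[b, g] * (1.0 - e)
                    for i in range(n):
                        Wr[lc, i] = Wr[b, i]
                        Wr[rc, i] = Wr[b, i]
                    Ws[lc] = Ws[b]
                    Ws[rc] = Ws[b]
                elif fix >= 0:
                    e = _logistic((cut[o + b] - fixed_val[fix]) / taus[t])
                    Ws[lc] = Ws[b] * e
                    Ws[rc] = Ws[b] * (1.0 - e)
                    for g in range(G):
                        Wg[lc, g] = Wg[b, g]
                        Wg[rc, g] = Wg[b, g]
                    for i in range(n):
                        Wr[lc, i] = Wr[b, i]
                        Wr[rc, i] = Wr[b, i]
                else:
                    for i in range(n):
                        e = _logistic((cut[o + b] - Zs[i, j]) / taus[t])
                        Wr[lc, i] = Wr[b, i] * e
                        Wr[rc, i] = Wr[b, i] * (1.0 - e)
                    for g in range(G):
                        Wg[lc, g] = Wg[b, g]
                        Wg[rc, g] = Wg[b, g]
                    Ws[lc] = Ws[b]
                    Ws[rc] = Ws[b]
                stack[top] = lc
                top += 1
                stack[top] = rc
                top += 1
        for k in range(nn):
            if var[o + k] < 0:
                mr = 0.0
                for i in range(n):
                    mr += Wr[k, i]
                mr /= n
                for g in range(G):
                    f[g] += mu[o + k] * Ws[k] * Wg[k, g] * mr
    return f


@njit(cache=True)
def _pd_pair(offsets, var, cut, left, right, mu, taus, Zs, m1, m2,
             grid1, grid2):
    """Bivariate partial dependence surface over grid1 x grid2."""
    G1 = grid1.size
    G2 = grid2.size
    n = Zs.shape[0]
    T = offsets.size - 1
    F = np.zeros((G1, G2))
    for t in range(T):
        o = offsets[t]
        nn = offsets[t + 1] - o
        W1 = np.ones((nn, G1))
        W2 = np.ones((nn, G2))
        Wr = np.ones((nn, n))
        stack = np.empty(nn, np.int64)
        stack[0] = 0
        top = 1
        while top > 0:
            top -= 1
            b = stack[top]
            if var[o + b] >= 0:
                j = var[o + b]
                lc = left[o + b]
                rc = right[o + b]
                for g in range(G1):
                    W1[lc, g] = W1[b, g]
                    W1[rc, g] = W1[b, g]
                for g in range(G2):
                    W2[lc, g] = W2[b, g]
                    W2[rc, g] = W2[b, g]
                for i in range(n):
                    Wr[lc, i] = Wr[b, i]
                    Wr[rc, i] = Wr[b, i]
                if j == m1:
                    for g in range(G1):
                        e = _logistic((cut[o + b] - grid1[g]) / taus[t])
                        W1[lc, g] = W1[b, g] * e
                        W1[rc, g] = W1[b, g] * (1.0 - e)
                elif j == m2:
                    for g in range(G2):
                        e = _logistic((cut[o + b] - grid2[g]) / taus[t])
                        W2[lc, g] = W2[b, g] * e
                        W2[rc, g] = W2[b, g] * (1.0 - e)
                else:
                    for i in range(n):
                        e = _logistic((cut[o + b] - Zs[i, j]) / taus[t])
                        Wr[lc, i] = Wr[b, i] * e
                        Wr[rc, i] = Wr[b, i] * (1.0 - e)
                stack[top] = lc
                top += 1
                stack[top] = rc
                top += 1
        for k in range(nn):
            if var[o + k] < 0:
                mr = 0.0
                for i in range(n):
                    mr += Wr[k, i]
                mr /= n
                for g1 in range(G1):
                    wk = mu[o + k] * mr * W1[k, g1]
                    for g2 in range(G2):
                        F[g1, g2] += wk * W2[k, g2]
    return F
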