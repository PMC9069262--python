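"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: scalar loops, sklearn
isotonic regression and explicit residual norms, so agreement with the
package implementations is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def wc_brute(groups: list[list[int]]):
    """Scalar-loop Weir-Cockerham variance components from genotype counts.

    ``groups`` holds called genotype codes (0/1/2) per group.  Returns
    (a, b, c, theta) with theta = nan when a + b + c = 0.
    """
    r = len(groups)
    n_i = [len(g) for g in groups]
    n_tot = sum(n_i)
    nbar = n_tot / r
    n_c = (n_tot - sum(n * n for n in n_i) / n_tot) / (r - 1)
    p_i = [sum(g) / (2 * n) for g, n in zip(groups, n_i)]
    h_i = [sum(1 for c in g if c == 1) / n for g, n in zip(groups, n_i)]
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_tot
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_tot
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if abs(denom) > 0 else math.nan
    return a, b, c, theta


def ordinal_als_brute(codes: np.ndarray, n_dim: int, n_iter: int = 2000, tol: float = 1e-12):
    """Loop-based optimal-scaling ALS with sklearn isotonic regression.

    Alternates (i) truncated SVD of the quantified matrix for the
    rank-``n_dim`` scores/loadings and (ii) per-column monotone
    re-quantification of the reconstruction target.  Same loss as the
    package fit (mean squared rank-d residual); different code path.
    Returns (eigenvalues of Q'Q/n, final loss).
    """
    from sklearn.isotonic import IsotonicRegression

    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    Q = (codes - codes.mean(0)) / codes.std(0)
    loss_prev = np.inf
    for _ in range(n_iter):
        U, S, Vt = np.linalg.svd(Q, full_matrices=False)
        recon = U[:, :n_dim] @ np.diag(S[:n_dim]) @ Vt[:n_dim]
        for j in range(m):
            iso = IsotonicRegression(increasing=True)
            qj = iso.fit_transform(codes[:, j], recon[:, j])
            sd = qj.std()
            if sd <= 1e-12:
                qj = codes[:, j]
                sd = qj.std()
            Q[:, j] = (qj - qj.mean()) / sd
        U, S, Vt = np.linalg.svd(Q, full_matrices=False)
        loss = (np.sum(S[n_dim:] ** 2)) / (n * m)
        if abs(loss_prev - loss) < tol:
            break
        loss_prev = loss
    U, S, Vt = np.linalg.svd(Q, full_matrices=False)
    return S**2 / n, loss


def hwe_loglik_brute(codes, freqs) -> float:
    """Hand product of Hardy-Weinberg genotype probabilities (one pop)."""
    total = 0.0
    for c, f in zip(codes, freqs):
        if c < 0:
            continue
        p = {0: (1 - f) ** 2, 1: 2 * f * (1 - f), 2: f * f}[int(c)]
        total += math.log(p)
    return total


def loo_self_assign_brute(codes: np.ndarray, pops: list[str], prior: float = 0.5):
    """Leave-one-out self-assignment by scalar loops (equal pop priors)."""
    labels = sorted(set(pops))
    n, L = codes.shape
    out = []
    for i in range(n):
        logls = []
        for lab in labels:
            ll = 0.0
            for j in range(L):
                c = codes[i, j]
                if c < 0:
                    continue
                count = total = 0
                for k in range(n):
                    if k == i or pops[k] != lab or codes[k, j] < 0:
                        continue
                    count += codes[k, j]
                    total += 2
                f = (count + prior) / (total + 2 * prior)
                p = {0: (1 - f) ** 2, 1: 2 * f * (1 - f), 2: f * f}[int(c)]
                ll += math.log(p)
            logls.append(ll)
        out.append(labels[int(np.argmax(logls))])
    return out
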