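"""Ordinal principal component analysis by alternating least squares.

Each locus's genotype categories (0 < 1 < 2 copies of the counted allele)
are replaced by monotone numeric quantifications chosen to maximise the
variance explained by a low-rank representation — the optimal-scaling /
homogeneity-analysis formulation of PCA for ordered categorical data.

The fit alternates three exact least-squares steps:

1. for each locus, the unconstrained quantification target is the
   projection of the object scores onto the locus loading; category
   values are its weighted per-category means, projected onto the
   monotone cone by pool-adjacent-violators, then standardised to mean 0
   and variance 1 over samples;
2. object scores X (n x d, X'X = nI) solve an orthogonal Procrustes
   problem against Q A, where Q is the quantified data matrix;
3. loadings A = Q'X / n.

The recorded loss is the mean squared residual between Q and its rank-d
reconstruction X A', which equals (m - ||A||_F^2)/m at each recording
point and is non-increasing across iterations.  Variance accounted for is
reported per dimension as eigenvalue / n_loci x 100, with eigenvalues
those of the correlation matrix Q'Q/n of the quantified data.

When every locus has only two observed categories the monotone constraint
is vacuous and the fit coincides with classical PCA of the standardised
0/1 codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PcaConfig:
    n_dim: int = 2
    tol: float = 1e-8
    max_iter: int = 2000
    missing_policy: str = "impute_modal"  # or "drop_samples"
    max_missing: float = 0.33  # per-sample threshold for drop_samples
    seed: int = 0  # degenerate tie-breaking only; the fit is deterministic

    def __post_init__(self) -> None:
        if self.n_dim < 1:
            raise ValueError("n_dim must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class OrdinalPcaResult:
    sample_ids: list[str]
    locus_ids: list[str]
    quantifications: dict[str, dict[int, float]]  # locus -> {category code: value}
    object_scores: np.ndarray  # n x d, columns orthogonal, X'X = n I
    loadings: np.ndarray  # m x d
    eigenvalues: np.ndarray  # all eigenvalues of Q'Q/n, descending
    vaf_percent: np.ndarray  # first n_dim entries, eigenvalue / m * 100
    loss_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    dropped_loci: list[str] = field(default_factory=list)


def _pava_increasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic (non-decreasing) regression, pool-adjacent-violators."""
    vals = list(map(float, y))
    wts = list(map(float, w))
    starts = list(range(len(vals)))  # block start indices for expansion
    i = 0
    blocks_v, blocks_w, blocks_n = [], [], []
    for v, wt in zip(vals, wts):
        blocks_v.append(v)
        blocks_w.append(wt)
        blocks_n.append(1)
        while len(blocks_v) > 1 and blocks_v[-2] > blocks_v[-1]:
            v2, w2, n2 = blocks_v.pop(), blocks_w.pop(), blocks_n.pop()
            v1, w1, n1 = blocks_v.pop(), blocks_w.pop(), blocks_n.pop()
            tot = w1 + w2
            blocks_v.append((v1 * w1 + v2 * w2) / tot if tot > 0 else 0.5 * (v1 + v2))
            blocks_w.append(tot)
            blocks_n.append(n1 + n2)
    out = np.empty(len(vals))
    pos = 0
    for v, n in zip(blocks_v, blocks_n):
        out[pos : pos + n] = v
        pos += n
    return out


def _prepare_codes(gm: GenotypeMatrix, cfg: PcaConfig):
    """Apply the missing policy and drop loci monomorphic afterwards."""
    codes = gm.codes.astype(float)
    sample_ids = list(gm.sample_ids)
    if cfg.missing_policy == "drop_samples":
        miss = (gm.codes == MISSING).mean(axis=1)
        keep = miss <= cfg.max_missing
        if not keep.all():
            log.info("dropping %d samples above missingness %.2f", (~keep).sum(), cfg.max_missing)
        codes = codes[keep]
        sample_ids = [s for s, k in zip(sample_ids, keep) if k]
    # impute remaining missing values to the locus modal category
    for j in range(codes.shape[1]):
        col = codes[:, j]
        miss = col == MISSING
        if miss.any():
            observed = col[~miss].astype(int)
            if observed.size == 0:
                col[miss] = 0
                continue
            counts = np.bincount(observed, minlength=3)
            col[miss] = int(np.argmax(counts))  # ties -> lowest category
    keep_loci = np.array([len(np.unique(codes[:, j])) >= 2 for j in range(codes.shape[1])])
    dropped = [lid for lid, k in zip(gm.locus_ids, keep_loci) if not k]
    if dropped:
        log.warning("dropping %d loci monomorphic after imputation: %s", len(dropped), dropped)
    return codes[:, keep_loci], sample_ids, [l for l, k in zip(gm.locus_ids, keep_loci) if k], dropped


def _standardize_columns(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (mat - mu) / sd


def fit_ordinal_pca(gm: GenotypeMatrix, cfg: PcaConfig | None = None) -> OrdinalPcaResult:
    """Fit the ordinal PCA.  See the module docstring for the algorithm.

    Raises when fewer than two loci survive preparation or when
    ``cfg.n_dim`` is not smaller than the number of active loci.
    """
    cfg = cfg or PcaConfig()
    codes, sample_ids, locus_ids, dropped = _prepare_codes(gm, cfg)
    n, m = codes.shape
    if m < 2:
        raise ValueError(f"need >= 2 polymorphic loci, have {m}")
    if cfg.n_dim >= m:
        raise ValueError(f"n_dim={cfg.n_dim} must be < number of active loci ({m})")
    d = cfg.n_dim

    # deterministic initialisation from classical PCA of standardised codes
    Z = _standardize_columns(codes)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    X = np.sqrt(n) * U[:, :d]
    A = Z.T @ X / n
    Q = Z.copy()

    cat_index = [codes[:, j].astype(int) for j in range(m)]
    cat_values = [np.unique(codes[:, j]).astype(int) for j in range(m)]

    loss_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # (1) quantification step, locus by locus
        for j in range(m):
            a = A[j]
            na2 = float(a @ a)
            if na2 <= 1e-300:
                continue  # direction undefined; keep previous quantification
            target = X @ a / na2
            cats = cat_values[j]
            idx = cat_index[j]
            means = np.empty(len(cats))
            weights = np.empty(len(cats))
            for k, cval in enumerate(cats):
                mask = idx == cval
                weights[k] = mask.sum()
                means[k] = target[mask].mean()
            iso = _pava_increasing(means, weights)
            q = iso[np.searchsorted(cats, idx)]
            sd = q.std()
            if sd <= 1e-12:
                # anti-monotone target collapsed to a constant; fall back to
                # the standardised numeric codes for this locus
                q = codes[:, j]
                sd = q.std()
            Q[:, j] = (q - q.mean()) / sd
        # (2) object scores: Procrustes against Q A
        M = Q @ A
        Um, _, Vmt = np.linalg.svd(M, full_matrices=False)
        X = np.sqrt(n) * Um @ Vmt
        # (3) loadings
        A = Q.T @ X / n
        loss = (m - float((A**2).sum())) / m
        loss_trace.append(loss)
        if len(loss_trace) > 1 and abs(loss_trace[-2] - loss_trace[-1]) < cfg.tol:
            converged = True
            break

    # final decomposition of the quantified data
    Uq, Sq, Vqt = np.linalg.svd(Q, full_matrices=False)
    eigenvalues = Sq**2 / n
    X = np.sqrt(n) * Uq[:, :d]
    A = Q.T @ X / n
    vaf = eigenvalues[:d] / m * 100.0

    quantifications: dict[str, dict[int, float]] = {}
    for j, lid in enumerate(locus_ids):
        col = Q[:, j]
        idx = cat_index[j]
        quantifications[lid] = {
            int(c): float(col[idx == c][0]) for c in cat_values[j]
        }

    if not converged:
        log.warning("ordinal PCA did not converge in %d iterations", cfg.max_iter)
    return OrdinalPcaResult(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        quantifications=quantifications,
        object_scores=X,
        loadings=A,
        eigenvalues=eigenvalues,
        vaf_percent=vaf,
        loss_trace=loss_trace,
        n_iter=it,
        converged=converged,
        dropped_loci=dropped,
    )


def fix_sign(result: OrdinalPcaResult, anchor_locus: str | None = None) -> OrdinalPcaResult:
    """Resolve the arbitrary sign of each component.

    Each dimension is flipped, if needed, so the anchor locus loads
    positively.  With no anchor (or a zero anchor loading on a
    dimension), the locus with the largest absolute loading on that
    dimension anchors it instead.
    """
    loadings = result.loadings.copy()
    scores = result.object_scores.copy()
    if anchor_locus is not None:
        if anchor_locus not in result.locus_ids:
            raise KeyError(f"anchor locus {anchor_locus!r} not in fit")
        anchor = result.locus_ids.index(anchor_locus)
    else:
        anchor = None
    for k in range(loadings.shape[1]):
        j = anchor
        if j is None or abs(loadings[j, k]) <= 1e-12:
            if j is not None:
                log.info("anchor loading ~0 on dim %d; using largest |loading|", k + 1)
            j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    out = OrdinalPcaResult(
        sample_ids=result.sample_ids,
        locus_ids=result.locus_ids,
        quantifications=result.quantifications,
        object_scores=scores,
        loadings=loadings,
        eigenvalues=result.eigenvalues,
        vaf_percent=result.vaf_percent,
        loss_trace=result.loss_trace,
        n_iter=result.n_iter,
        converged=result.converged,
        dropped_loci=result.dropped_loci,
    )
    return out
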