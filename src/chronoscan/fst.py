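"""Per-locus Weir–Cockerham F_ST and relaxed-percentile outlier selection.

The estimator is the classic variance-components theta for diploid,
biallelic data: per locus, allelic variance is decomposed into components
among groups (a), among individuals within groups (b) and within
individuals (c), and theta = a / (a + b + c).  Negative estimates are
retained in the distribution, as usual for this estimator; loci that are
monomorphic overall (a + b + c = 0) or that fail the minimum-calls rule
are excluded before the outlier quantile is computed.

The outlier rule is deliberately permissive: the candidate set is every
locus at or above a low empirical quantile (default the 90th percentile)
of theta, so that many loci of potentially small effect are carried
forward rather than only extreme outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix
from .io import GeneIndex

log = logging.getLogger(__name__)

#: Default minimum called individuals per group for a locus to count as "ok".
MIN_CALLS_DEFAULT = 5


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

def wc_components(codes: np.ndarray, group_index: np.ndarray, min_calls: int = 1):
    """Vectorised Weir–Cockerham variance components for all loci at once.

    Parameters
    ----------
    codes
        ``(n_samples, n_loci)`` genotype codes with :data:`MISSING` = -1.
    group_index
        Per-sample integer group label in ``0..r-1`` (r >= 2 groups).
    min_calls
        Minimum called individuals required in *every* group for a locus
        to receive status ``ok``.

    Returns
    -------
    dict of arrays
        ``a``, ``b``, ``c``, ``theta`` (NaN where undefined), ``n_calls``
        (r x n_loci called individuals), ``status`` (object array of
        'ok' / 'monomorphic' / 'insufficient').
    """
    codes = np.asarray(codes)
    group_index = np.asarray(group_index)
    r = int(group_index.max()) + 1 if group_index.size else 0
    if r < 2:
        raise ValueError("at least two groups are required")

    called = codes != MISSING
    n_loci = codes.shape[1]
    n_i = np.zeros((r, n_loci))      # called individuals per group
    p_i = np.zeros((r, n_loci))      # counted-allele frequency per group
    h_i = np.zeros((r, n_loci))      # observed heterozygote proportion per group
    for g in range(r):
        rows = group_index == g
        cg = codes[rows, :]
        okg = called[rows, :]
        n = okg.sum(axis=0)
        n_i[g] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[g] = np.where(n > 0, np.where(okg, cg, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            h_i[g] = np.where(n > 0, (cg == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    insufficient = (n_i < max(min_calls, 1)).any(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n_i.sum(axis=0)
        nbar = n_sum / r
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum

        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    monomorphic = np.isclose(denom, 0.0) | np.isnan(denom)
    status = np.full(n_loci, "ok", dtype=object)
    status[monomorphic] = "monomorphic"
    status[insufficient] = "insufficient"
    theta = np.where(monomorphic | insufficient, np.nan, theta)

    return {"a": a, "b": b, "c": c, "theta": theta, "n_calls": n_i.astype(int), "status": status}


def wc_fst_locus(codes_by_group: list[np.ndarray]):
    """Variance components (a, b, c, theta) for a single locus.

    ``codes_by_group`` holds the genotype codes of each group (>= 2
    groups, each with >= 1 called genotype); missing codes are excluded
    within each group.  theta is NaN when the locus is monomorphic.
    """
    if len(codes_by_group) < 2:
        raise ValueError("at least two groups are required")
    cleaned = [np.asarray(g)[np.asarray(g) != MISSING] for g in codes_by_group]
    if any(g.size == 0 for g in cleaned):
        raise ValueError("every group needs at least one called genotype")
    codes = np.concatenate(cleaned)[:, None]
    group_index = np.concatenate([np.full(g.size, i) for i, g in enumerate(cleaned)])
    res = wc_components(codes, group_index, min_calls=1)
    return float(res["a"][0]), float(res["b"][0]), float(res["c"][0]), float(res["theta"][0])


def multilocus_theta(fst: pd.DataFrame) -> float:
    """Ratio-of-sums multi-locus estimate sum(a) / sum(a+b+c) over ok loci."""
    ok = fst[fst["status"] == "ok"]
    denom = (ok["a"] + ok["b"] + ok["c"]).sum()
    if denom == 0:
        return float("nan")
    return float(ok["a"].sum() / denom)


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def resolve_groups(meta: pd.DataFrame, grouping: str = "resident_vs_migratory") -> pd.Series:
    """Map each sample to a scan group.

    ``"resident_vs_migratory"`` pools sites into two classes: residents
    versus migratory + partially migratory; samples of unknown class are
    dropped.  ``"site"`` treats every site as its own group (hierarchical
    option).  A callable mapping site/group rows to labels is also
    accepted.
    """
    if callable(grouping):
        return meta.apply(grouping, axis=1)
    if grouping == "resident_vs_migratory":
        mapping = {"resident": "resident", "migratory": "migratory", "partial": "migratory"}
        return meta["group"].map(mapping)
    if grouping == "site":
        return meta["site"].astype(str)
    raise ValueError(f"unknown grouping policy {grouping!r}")


def fst_scan(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    grouping: str = "resident_vs_migratory",
    exclude_sites: list[str] | None = None,
    min_calls: int = MIN_CALLS_DEFAULT,
) -> pd.DataFrame:
    """Per-locus Weir–Cockerham theta between phenotype-defined groups.

    Sites listed in ``exclude_sites`` (e.g. a site of ambiguous migratory
    status) are dropped before grouping.  Returns a DataFrame with one row
    per locus: locus_id, a, b, c, theta, per-group call counts and status.
    """
    meta = meta.set_index("sample_id").loc[gm.sample_ids].reset_index()
    keep = np.ones(len(meta), dtype=bool)
    if exclude_sites:
        keep &= ~meta["site"].isin(exclude_sites).to_numpy()
    labels = resolve_groups(meta, grouping)
    keep &= labels.notna().to_numpy()

    labels = labels[keep]
    codes = gm.codes[keep.nonzero()[0], :]
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError(
            f"need >= 2 groups after exclusions, got {group_names}"
        )
    for g in group_names:
        if (labels == g).sum() == 0:  # pragma: no cover - guarded by unique()
            raise ValueError(f"group {g!r} has no samples after exclusions")
    group_index = labels.map({g: i for i, g in enumerate(group_names)}).to_numpy()

    res = wc_components(codes, group_index, min_calls=min_calls)
    out = pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "a": res["a"],
            "b": res["b"],
            "c": res["c"],
            "theta": res["theta"],
            "status": res["status"],
        }
    )
    for i, g in enumerate(group_names):
        out[f"n_{g}"] = res["n_calls"][i]
    out.attrs["groups"] = group_names
    n_bad = int((out["status"] != "ok").sum())
    if n_bad:
        log.info("%d of %d loci monomorphic/insufficient in scan", n_bad, len(out))
    return out


# ---------------------------------------------------------------------------
# Outlier selection and gene annotation
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Loci at or above the percentile threshold, with optional gene map."""

    threshold_value: float
    percentile: float
    locus_ids: list[str]
    gene_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols hit by the candidate loci."""
        return sorted({g for genes in self.gene_map.values() for g in genes})


def select_outliers(fst: pd.DataFrame, percentile: float = 0.90) -> CandidateSet:
    """Select every locus with theta at or above the empirical quantile.

    The threshold is the linear-interpolation quantile of theta over
    status-ok loci; ties at the threshold are all included (inclusive
    rule, keeping small-effect loci).
    """
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    ok = fst[fst["status"] == "ok"]
    if len(ok) == 0:
        raise ValueError("no loci with status ok")
    if len(ok) < 10:
        raise ValueError(f"need >= 10 ok loci for a stable quantile, got {len(ok)}")
    threshold = float(np.quantile(ok["theta"].to_numpy(), percentile, method="linear"))
    selected = ok.loc[ok["theta"] >= threshold, "locus_id"].tolist()
    return CandidateSet(threshold, percentile, selected)


def annotate_genes(
    cs: CandidateSet,
    index: GeneIndex,
    annotations: pd.DataFrame,
) -> CandidateSet:
    """Attach overlapping gene symbols to each selected locus.

    ``annotations`` is the frame from :func:`chronoscan.datatypes.annotation_frame`.
    Loci without coordinates map to no genes, with a warning.  A locus in
    the overlap of several genes reports all of them; the distinct-gene
    tally counts each gene once.
    """
    gene_map: dict[str, list[str]] = {}
    n_missing = 0
    for lid in cs.locus_ids:
        if lid not in annotations.index:
            gene_map[lid] = []
            n_missing += 1
            continue
        row = annotations.loc[lid]
        gene_map[lid] = index.query(str(row["chrom"]), int(row["pos"]))
    if n_missing:
        log.warning("%d selected loci lack coordinates; mapped to no gene", n_missing)
    return CandidateSet(cs.threshold_value, cs.percentile, list(cs.locus_ids), gene_map)
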