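"""Genetic stock identification: baseline frequencies, EM mixture, assignment.

A baseline of reference individuals of known population builds posterior
mean allele frequencies per population and locus with a 1/2-per-allele
prior (the conditional-GSI convention for biallelic markers), so no
frequency is ever exactly 0 or 1.  Mixture individuals are scored with
Hardy-Weinberg genotype likelihoods, mixture proportions are estimated by
EM, and each individual receives a posterior over source populations plus
a maximum-a-posteriori label and a confidence flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

#: Dirichlet prior mass per allele for baseline frequencies (biallelic: 1/2).
ALLELE_PRIOR = 0.5

#: Default posterior threshold for "assigned with certainty".
CERTAINTY_DEFAULT = 0.8


@dataclass
class Baseline:
    """Baseline allele counts and posterior mean frequencies.

    ``counts``/``totals`` are populations x loci arrays of counted-allele
    copies and called alleles; ``freqs`` are the posterior means
    (count + prior) / (total + 2 prior).
    """

    populations: list[str]
    locus_ids: list[str]
    counts: np.ndarray
    totals: np.ndarray
    freqs: np.ndarray

    @property
    def n_pops(self) -> int:
        return len(self.populations)


@dataclass
class MixtureResult:
    populations: list[str]
    sample_ids: list[str]
    pi: np.ndarray  # mixture proportions, sums to 1
    posteriors: np.ndarray  # individuals x populations, rows sum to 1
    map_label: list[str]
    map_prob: np.ndarray
    certainty_flag: np.ndarray  # map_prob >= threshold
    threshold: float
    n_iter: int
    loglik_trace: list[float]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.posteriors, columns=self.populations)
        df.insert(0, "sample_id", self.sample_ids)
        df["map_label"] = self.map_label
        df["map_prob"] = self.map_prob
        df["certain"] = self.certainty_flag
        return df


def build_baseline(gm: GenotypeMatrix, meta: pd.DataFrame, pop_field: str = "site") -> Baseline:
    """Tally baseline allele counts per population and smooth with the prior.

    Every reference sample must carry a label in ``pop_field``.  A
    population with zero called genotypes at a locus falls back to the
    prior alone (posterior 0.5), with a warning.
    """
    m = meta.set_index("sample_id").loc[gm.sample_ids]
    labels = m[pop_field].astype(str)
    if labels.isin(["", "nan"]).any():
        raise ValueError(f"every reference sample needs a {pop_field!r} label")
    pops = sorted(labels.unique())
    P, L = len(pops), gm.n_loci
    counts = np.zeros((P, L))
    totals = np.zeros((P, L))
    for i, pop in enumerate(pops):
        rows = (labels == pop).to_numpy()
        codes = gm.codes[rows, :]
        called = codes != MISSING
        counts[i] = np.where(called, codes, 0).sum(axis=0)
        totals[i] = 2 * called.sum(axis=0)
    n_empty = int((totals == 0).sum())
    if n_empty:
        log.warning("%d population x locus cells have no calls; prior-only posterior", n_empty)
    freqs = (counts + ALLELE_PRIOR) / (totals + 2 * ALLELE_PRIOR)
    return Baseline(pops, list(gm.locus_ids), counts, totals, freqs)


def _loglik_matrix(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """individuals x populations Hardy-Weinberg log-likelihood matrix.

    P(2) = f^2, P(1) = 2 f (1-f), P(0) = (1-f)^2; missing loci are
    skipped (contribute 0).
    """
    logf = np.log(freqs)  # P x L; freqs strictly inside (0,1) by the prior
    log1mf = np.log1p(-freqs)
    n, P = codes.shape[0], freqs.shape[0]
    out = np.zeros((n, P))
    called = codes != MISSING
    c = np.where(called, codes, 0).astype(float)
    het = (codes == 1) & called
    # sum over loci of c*log f + (2-c)*log(1-f) + het*log 2
    for p in range(P):
        term = c * logf[p] + (2 - c) * log1mf[p]
        out[:, p] = np.where(called, term, 0.0).sum(axis=1) + np.log(2.0) * het.sum(axis=1)
    return out


def genotype_loglik(codes: np.ndarray, baseline: Baseline, pop: str) -> float:
    """HWE log-likelihood of one individual's codes under one population."""
    p = baseline.populations.index(pop)
    codes = np.asarray(codes, dtype=np.int8)[None, :]
    if codes.shape[1] != len(baseline.locus_ids):
        raise ValueError("codes must align with baseline loci")
    if (codes == MISSING).all():
        log.warning("all loci missing; individual is uninformative")
        return 0.0
    return float(_loglik_matrix(codes, baseline.freqs)[0, p])


def align_to_baseline(gm: GenotypeMatrix, baseline: Baseline):
    """Restrict matrix and baseline to their shared loci (baseline order).

    Migrant loci absent from the baseline are dropped with a logged
    count, not imputed; baseline loci the migrants lack are likewise
    dropped from the baseline.  Returns (gm, baseline) on shared loci.
    """
    have = set(gm.locus_ids)
    shared = [lid for lid in baseline.locus_ids if lid in have]
    if not shared:
        raise ValueError("no loci shared with the baseline")
    n_dropped = gm.n_loci - len(shared)
    if n_dropped:
        log.info("dropping %d migrant loci absent from the baseline", n_dropped)
    if shared != baseline.locus_ids:
        cols = [baseline.locus_ids.index(lid) for lid in shared]
        baseline = Baseline(
            list(baseline.populations),
            shared,
            baseline.counts[:, cols],
            baseline.totals[:, cols],
            baseline.freqs[:, cols],
        )
    return gm.subset_loci(shared), baseline


def mixture_em(
    migrants: GenotypeMatrix,
    baseline: Baseline,
    tol: float = 1e-8,
    max_iter: int = 1000,
    threshold: float = CERTAINTY_DEFAULT,
) -> MixtureResult:
    """EM for mixture proportions and per-individual origin posteriors.

    Starts from uniform proportions; E-step computes posteriors
    proportional to pi_c exp(loglik_ic), M-step sets pi to the posterior
    means, until the observed-data log-likelihood changes by < tol.  The
    log-likelihood trace is non-decreasing (EM guarantee).
    """
    gm, baseline = align_to_baseline(migrants, baseline)
    ll = _loglik_matrix(gm.codes, baseline.freqs)  # n x P
    if not np.isfinite(ll).all():
        bad = np.argwhere(~np.isfinite(ll))
        raise FloatingPointError(f"non-finite genotype log-likelihoods at {bad[:5]}")
    n, P = ll.shape
    pi = np.full(P, 1.0 / P)
    trace: list[float] = []
    posteriors = np.full((n, P), 1.0 / P)
    it = 0
    for it in range(1, max_iter + 1):
        weighted = ll + np.log(pi)[None, :]
        norm = logsumexp(weighted, axis=1)
        total = float(norm.sum())
        posteriors = np.exp(weighted - norm[:, None])
        trace.append(total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
        pi = posteriors.mean(axis=0)
        pi = pi / pi.sum()

    map_idx = posteriors.argmax(axis=1)
    map_prob = posteriors[np.arange(n), map_idx]
    return MixtureResult(
        populations=list(baseline.populations),
        sample_ids=list(gm.sample_ids),
        pi=pi,
        posteriors=posteriors,
        map_label=[baseline.populations[i] for i in map_idx],
        map_prob=map_prob,
        certainty_flag=map_prob >= threshold,
        threshold=threshold,
        n_iter=it,
        loglik_trace=trace,
    )


def self_assign_loo(baseline: Baseline, gm: GenotypeMatrix, meta: pd.DataFrame, pop_field: str = "site"):
    """Leave-one-out self-assignment of the reference individuals.

    Each reference individual is scored against baseline frequencies
    recomputed with its own genotypes removed (equal population priors),
    and assigned to the most likely population.  Returns (per-individual
    DataFrame, accuracy-by-population dict); a population of size 1 has
    undefined accuracy (NaN).
    """
    gm, baseline = align_to_baseline(gm, baseline)
    m = meta.set_index("sample_id").loc[gm.sample_ids]
    labels = m[pop_field].astype(str).to_numpy()
    pop_index = {p: i for i, p in enumerate(baseline.populations)}
    rows = []
    for i, sid in enumerate(gm.sample_ids):
        codes = gm.codes[i]
        true_pop = labels[i]
        p = pop_index[true_pop]
        called = codes != MISSING
        counts = baseline.counts.copy()
        totals = baseline.totals.copy()
        counts[p, called] -= codes[called]
        totals[p, called] -= 2
        freqs = (counts + ALLELE_PRIOR) / (totals + 2 * ALLELE_PRIOR)
        ll = _loglik_matrix(codes[None, :], freqs)[0]
        post = np.exp(ll - logsumexp(ll))
        j = int(np.argmax(post))
        rows.append((sid, true_pop, baseline.populations[j], float(post[j])))
    df = pd.DataFrame(rows, columns=["sample_id", "true_pop", "map_label", "map_prob"])
    accuracy = {}
    for pop in baseline.populations:
        sub = df[df["true_pop"] == pop]
        if len(sub) <= 1:
            accuracy[pop] = float("nan")
            if len(sub) == 1:
                log.warning("population %s has a single reference individual", pop)
        else:
            accuracy[pop] = float((sub["map_label"] == pop).mean())
    return df, accuracy
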