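"""Seeded generators for every input the pipeline consumes.

Three generators mirror the statistical structure of the study system:

* :func:`gen_baseline` — a multi-population biallelic SNP baseline under
  the Balding-Nichols model (population frequencies Beta-distributed
  around an ancestral frequency with divergence parameter F, genotypes in
  Hardy-Weinberg proportions), optionally with planted high-divergence
  loci shifted between resident and migratory groups;
* :func:`gen_migration_series` — a migration-station time series; under
  the ``chronotype`` scenario all migrants come from one panmictic source
  and carry per-allele additive shifts of expected passage date at
  planted timing loci, while the ``population_confound`` scenario mixes
  two sources that differ in mean passage date, allele frequency at the
  timing loci and breeding latitude;
* :func:`gen_flank_contexts` — flanking-sequence contexts with planted
  GC extremes, nearby indels/SNPs and multi-mapping flanks, labelled with
  the designability rule each one is built to violate.

All generators are deterministic given their seed; truth records are
plain dictionaries (JSON-serialisable) listing what was planted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AssayContext, GenotypeMatrix, LocusAnnotation, validate_metadata
from . import io as cio

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineSpec:
    """Conditions of the multi-population baseline simulation.

    Defaults give two weakly diverged populations (F = 0.05) of 60
    diploids each at 2000 loci — a desk-scale stand-in for a
    reduced-representation breeding-range dataset.  ``outlier_delta`` is
    the allele-frequency shift planted between the resident and migratory
    groups at ``n_outliers`` loci.
    """

    n_pops: int = 2
    n_per_pop: int = 60
    n_loci: int = 2000
    target_fst: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    n_outliers: int = 0
    outlier_delta: float = 0.4
    seed: int = 0
    pop_names: list[str] | None = None
    pop_groups: list[str] | None = None  # "resident" / "migratory" / "partial" per pop
    pop_latitude: list[tuple[float, float]] | None = None  # (mean, sd) per pop

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if self.n_outliers > self.n_loci:
            raise ValueError("n_outliers cannot exceed n_loci")
        if self.pop_names is None:
            self.pop_names = [f"pop{i + 1}" for i in range(self.n_pops)]
        if self.pop_groups is None:
            self.pop_groups = ["migratory"] * self.n_pops
        if len(self.pop_names) != self.n_pops or len(self.pop_groups) != self.n_pops:
            raise ValueError("pop_names / pop_groups must have one entry per population")


def _bn_freqs(rng, p0: np.ndarray, fst: float, size: tuple[int, int]) -> np.ndarray:
    """Balding-Nichols population frequencies around ancestral p0."""
    if fst < 1e-9:
        return np.broadcast_to(p0, size).copy()
    scale = (1 - fst) / fst
    return rng.beta(np.broadcast_to(p0 * scale, size), np.broadcast_to((1 - p0) * scale, size))


def gen_baseline(spec: BaselineSpec):
    """Simulate the baseline dataset.

    Returns (GenotypeMatrix, metadata DataFrame, truth dict).  The truth
    record carries the per-population allele frequencies, the planted
    outlier locus ids and the group of every population.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    p0 = rng.uniform(lo, hi, spec.n_loci)
    freqs = _bn_freqs(rng, p0, spec.target_fst, (spec.n_pops, spec.n_loci))

    outlier_idx = np.array([], dtype=int)
    n_regen = 0
    if spec.n_outliers > 0:
        outlier_idx = rng.choice(spec.n_loci, spec.n_outliers, replace=False)
        groups = np.array(spec.pop_groups)
        res = groups == "resident"
        mig = ~res
        if not res.any() or not mig.any():
            # no resident/migratory split: shift the first population vs the rest
            res = np.arange(spec.n_pops) == 0
            mig = ~res
        half = spec.outlier_delta / 2.0
        for j in outlier_idx:
            p = p0[j]
            while not (0.01 <= p - half and p + half <= 0.99):
                p = rng.uniform(lo, hi)
                n_regen += 1
            # the planted between-group differential is exactly outlier_delta;
            # Balding-Nichols drift noise is not layered on top, so the planted
            # effect size is the stated one
            freqs[:, j] = np.where(res, p - half, p + half)
        if n_regen:
            log.info("regenerated ancestral frequency %d times for feasible shifts", n_regen)

    codes = np.empty((spec.n_pops * spec.n_per_pop, spec.n_loci), dtype=np.int8)
    sample_ids, sites, groups_col, lats = [], [], [], []
    for i in range(spec.n_pops):
        rows = slice(i * spec.n_per_pop, (i + 1) * spec.n_per_pop)
        codes[rows] = rng.binomial(2, freqs[i], (spec.n_per_pop, spec.n_loci)).astype(np.int8)
        name = spec.pop_names[i]
        sample_ids += [f"{name}_{k + 1:03d}" for k in range(spec.n_per_pop)]
        sites += [name] * spec.n_per_pop
        groups_col += [spec.pop_groups[i]] * spec.n_per_pop
        if spec.pop_latitude is not None:
            mu, sd = spec.pop_latitude[i]
            lats += list(np.round(rng.normal(mu, sd, spec.n_per_pop), 3))
        else:
            lats += [np.nan] * spec.n_per_pop

    locus_ids = [f"L{j + 1:05d}" for j in range(spec.n_loci)]
    gm = GenotypeMatrix(sample_ids, locus_ids, codes, ["A"] * spec.n_loci)
    meta = validate_metadata(
        pd.DataFrame(
            {"sample_id": sample_ids, "site": sites, "group": groups_col, "latitude": lats}
        )
    )
    truth = {
        "model": "balding-nichols",
        "target_fst": spec.target_fst,
        "pop_names": list(spec.pop_names),
        "pop_groups": list(spec.pop_groups),
        "pop_freqs": freqs.tolist(),
        "locus_ids": locus_ids,
        "outlier_loci": [locus_ids[j] for j in sorted(outlier_idx.tolist())],
        "seed": spec.seed,
    }
    return gm, meta, truth


# ---------------------------------------------------------------------------
# Migration-station time series
# ---------------------------------------------------------------------------

@dataclass
class MigrationSeriesSpec:
    """Conditions of the migration-station time series.

    The default season (day 230-320, about mid-August to mid-November)
    is a three-month autumn window; 150 migrants matches the scale of a
    single-station panel study.  ``effect_days`` is the additive shift of
    expected passage date per copy of the counted allele at each timing
    locus (chronotype scenario).  In the confound scenario,
    ``passage_offset_days`` separates the two sources' mean passage dates
    and ``confound_freq_delta`` their allele frequencies at the timing
    loci (applied on top of the baseline truth).

    ``liability_weight`` controls the chronotype polymorphism itself: a
    latent early/late liability per migrant shifts the allele-sampling
    probability of every timing locus jointly (on the logit scale), so
    timing-locus genotypes covary — the collinearity that lets one
    principal component summarise the chronotype.  At 0 the timing loci
    are independent; the default gives strong but imperfect correlation.
    The liability enters passage date only through the genotypes.
    """

    scenario: str = "chronotype"  # or "population_confound"
    n_migrants: int = 150
    season: tuple[int, int] = (230, 320)
    n_timing_loci: int = 4
    effect_days: float = -5.0
    passage_sd: float = 7.0
    liability_weight: float = 1.5  # chronotype scenario; see docstring
    source_pop: str | None = None  # chronotype scenario; default = first pop
    mixture: tuple[float, float] = (0.6, 0.4)  # confound scenario
    passage_offset_days: float = 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("chronotype", "population_confound"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        start, end = self.season
        if end - start < 28:
            raise ValueError("season must span at least 28 days (>= 4 weekly bins)")
        if not np.isfinite(self.effect_days):
            raise ValueError("effect_days must be finite")


def gen_migration_series(spec: MigrationSeriesSpec, baseline_truth: dict):
    """Simulate migrants captured through a season at one station.

    ``baseline_truth`` is the truth record of :func:`gen_baseline`; its
    per-population frequencies are the source frequencies here, so
    baseline and migrants are mutually consistent for assignment.  Timing
    loci are drawn from the baseline's planted outliers when present,
    otherwise from loci polymorphic in the source population(s).

    Returns (GenotypeMatrix, metadata, truth) where the truth record
    stores each individual's origin and timing-locus genotypes.
    """
    rng = np.random.default_rng(spec.seed)
    start, end = spec.season
    midpoint = 0.5 * (start + end)
    freqs = np.asarray(baseline_truth["pop_freqs"])
    pops = list(baseline_truth["pop_names"])
    locus_ids = list(baseline_truth["locus_ids"])
    n_loci = len(locus_ids)

    planted = baseline_truth.get("outlier_loci") or []
    if len(planted) >= spec.n_timing_loci:
        timing_idx = [locus_ids.index(l) for l in planted[: spec.n_timing_loci]]
    else:
        poly = [j for j in range(n_loci) if 0.25 <= freqs[:, j].mean() <= 0.75]
        timing_idx = list(rng.choice(poly, spec.n_timing_loci, replace=False))
    timing_loci = [locus_ids[j] for j in timing_idx]

    if spec.scenario == "chronotype":
        src = pops.index(spec.source_pop) if spec.source_pop else 0
        origin = np.full(spec.n_migrants, src)
    else:
        origin = rng.choice(len(pops[:2]), spec.n_migrants, p=list(spec.mixture))

    codes = np.empty((spec.n_migrants, n_loci), dtype=np.int8)
    for p in np.unique(origin):
        rows = origin == p
        codes[rows] = rng.binomial(2, freqs[p], (int(rows.sum()), n_loci)).astype(np.int8)

    if spec.scenario == "chronotype" and spec.liability_weight != 0.0:
        # shared chronotype liability: redraw timing-locus genotypes with a
        # per-individual logit shift common to all timing loci
        u = rng.standard_normal(spec.n_migrants)
        src = int(origin[0])
        for j in timing_idx:
            logit = np.log(freqs[src, j] / (1 - freqs[src, j]))
            p_ind = 1.0 / (1.0 + np.exp(-(logit + spec.liability_weight * u)))
            codes[:, j] = rng.binomial(2, p_ind).astype(np.int8)

    if spec.scenario == "chronotype":
        genetic = spec.effect_days * (codes[:, timing_idx].astype(float) - 1.0).sum(axis=1)
        expected = midpoint + genetic
    else:
        offsets = np.array([-0.5, 0.5]) * spec.passage_offset_days
        expected = midpoint + offsets[origin]
    days = rng.normal(expected, spec.passage_sd)
    n_trunc = int(((days < start) | (days > end)).sum())
    if n_trunc:
        log.info("truncated %d of %d capture days to the season window", n_trunc, spec.n_migrants)
    days = np.clip(np.round(days), start, end).astype(int)

    sample_ids = [f"mig_{k + 1:03d}" for k in range(spec.n_migrants)]
    gm = GenotypeMatrix(sample_ids, locus_ids, codes, ["A"] * n_loci)
    meta = validate_metadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "site": "station",
                "group": "migratory",
                "capture_day": days,
                "sex": rng.choice(["F", "M"], spec.n_migrants),
            }
        )
    )
    truth = {
        "scenario": spec.scenario,
        "timing_loci": timing_loci,
        "effect_days": spec.effect_days,
        "origin": [pops[p] for p in origin],
        "timing_genotypes": codes[:, timing_idx].tolist(),
        "season": [start, end],
        "truncated": n_trunc,
        "seed": spec.seed,
    }
    return gm, meta, truth


def confound_baseline_spec(seed: int = 0, **overrides) -> BaselineSpec:
    """Baseline conditions for the two-source population-confound scenario.

    Two migratory source populations with an allele-frequency
    differential planted at four loci and distinct breeding-latitude
    bands (a north/south split), so passage structure at the station can
    be traced back to origin.
    """
    kw = dict(
        n_pops=2,
        n_per_pop=60,
        n_loci=100,
        target_fst=0.05,
        n_outliers=4,
        outlier_delta=0.4,
        pop_names=["north", "south"],
        pop_groups=["migratory", "migratory"],
        pop_latitude=[(48.0, 1.5), (42.0, 1.5)],
        seed=seed,
    )
    kw.update(overrides)
    return BaselineSpec(**kw)


def chronotype_baseline_spec(seed: int = 0, **overrides) -> BaselineSpec:
    """Baseline conditions for the within-population chronotype scenario.

    Two weakly diverged clusters (an east/west split) sharing one
    latitude distribution; migrants will all come from the first.
    """
    kw = dict(
        n_pops=2,
        n_per_pop=60,
        n_loci=100,
        target_fst=0.05,
        n_outliers=0,
        pop_names=["west", "east"],
        pop_groups=["migratory", "migratory"],
        pop_latitude=[(45.0, 3.0), (45.0, 3.0)],
        seed=seed,
    )
    kw.update(overrides)
    return BaselineSpec(**kw)


# ---------------------------------------------------------------------------
# Flank contexts
# ---------------------------------------------------------------------------

@dataclass
class FlankContextSpec:
    """Conditions for assay-designability test contexts.

    Planted fractions assign each context at most one rule violation
    (their sum must be <= 1); the remainder are built to pass every rule.
    """

    n_contexts: int = 100
    flank_len: int = 100
    frac_gc: float = 0.25
    frac_indel: float = 0.25
    frac_snp: float = 0.25
    frac_multimap: float = 0.0
    seed: int = 0
    gc_window: int = 50  # must match the filter's gc_flank
    indel_window: int = 30
    snp_window: int = 20
    uniq_k: int = 20

    def __post_init__(self) -> None:
        if self.flank_len < 50:
            raise ValueError("flank_len must be >= 50")
        total = self.frac_gc + self.frac_indel + self.frac_snp + self.frac_multimap
        if total > 1.0 + 1e-9:
            raise ValueError("planted fractions must sum to <= 1")


def _random_seq(rng, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, length, p=p))


def gen_flank_contexts(spec: FlankContextSpec):
    """Generate assay contexts with planted rule violations.

    Returns (contexts, truth, reference) where truth maps locus_id to the
    list of rules the context is built to violate (empty = designable)
    and ``reference`` is a small sequence dict in which multimap
    contexts' primer seeds occur twice and all others once.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_contexts
    counts = [
        int(round(spec.frac_gc * n)),
        int(round(spec.frac_indel * n)),
        int(round(spec.frac_snp * n)),
        int(round(spec.frac_multimap * n)),
    ]
    labels = (
        ["gc"] * counts[0] + ["indel30"] * counts[1] + ["snp20"] * counts[2]
        + ["multimap"] * counts[3]
    )
    labels += ["pass"] * (n - len(labels))
    rng.shuffle(labels)

    contexts: list[AssayContext] = []
    truth: dict[str, list[str]] = {}
    reference: dict[str, str] = {}
    extra_copies: list[str] = []
    L = 2 * spec.flank_len + 1
    target = spec.flank_len

    for i, label in enumerate(labels):
        lid = f"ctx{i + 1:04d}"
        while True:
            seq = _random_seq(rng, L, gc=0.8 if label == "gc" else 0.45)
            lo = max(0, target - spec.gc_window)
            hi = min(L, target + spec.gc_window + 1)
            window = seq[lo:hi]
            gcf = sum(b in "GC" for b in window) / len(window)
            if (label == "gc") == (gcf >= 0.65):
                break
        variants: list[tuple[int, str]] = []
        if label == "indel30":
            d = int(rng.integers(1, spec.indel_window + 1))
            variants.append((target + int(rng.choice([-d, d])), "indel"))
        elif label == "snp20":
            d = int(rng.integers(1, spec.snp_window + 1))
            variants.append((target + int(rng.choice([-d, d])), "snp"))
        else:
            # decoys just outside the windows exercise the boundaries
            if rng.random() < 0.5:
                d = int(rng.integers(spec.snp_window + 1, 2 * spec.snp_window))
                variants.append((target + int(rng.choice([-d, d])), "snp"))
            if rng.random() < 0.5:
                d = int(rng.integers(spec.indel_window + 1, min(2 * spec.indel_window, target)))
                variants.append((target + int(rng.choice([-d, d])), "indel"))
        ctx = AssayContext(lid, seq, target, variants)
        contexts.append(ctx)
        truth[lid] = [] if label == "pass" else [label]
        reference[f"ref_{lid}"] = seq
        if label == "multimap":
            extra_copies.append(seq[target - spec.uniq_k : target])

    if extra_copies:
        spacer = _random_seq(rng, 40)
        reference["ref_extra"] = spacer.join(extra_copies)
    return contexts, truth, reference


# ---------------------------------------------------------------------------
# End-to-end on-disk fixture
# ---------------------------------------------------------------------------

def gen_end_to_end(outdir: str | Path, seed: int = 0) -> dict:
    """Write a complete on-disk dataset exercising every pipeline stage.

    Produces, under ``outdir``: a breeding-range VCF + metadata CSV for
    the divergence scan, a BED of gene intervals, flank FASTA + variant
    TSV for the assay filter, a candidate-panel baseline + migrant CSV
    pair with metadata for PCA / timing / assignment, and a truth JSON.
    Deterministic: the same seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # breeding-range scan dataset: residents vs migrants with planted outliers
    scan_spec = BaselineSpec(
        n_pops=4,
        n_per_pop=30,
        n_loci=500,
        target_fst=0.03,
        n_outliers=20,
        outlier_delta=0.4,
        pop_names=["FL", "TX", "west", "east"],
        pop_groups=["resident", "resident", "migratory", "partial"],
        pop_latitude=[(28.0, 1.0), (31.0, 1.0), (45.0, 3.0), (45.0, 3.0)],
        seed=int(rng.integers(2**31 - 1)),
    )
    scan_gm, scan_meta, scan_truth = gen_baseline(scan_spec)
    annotations = []
    chrom_of = {}
    for j, lid in enumerate(scan_gm.locus_ids):
        chrom = f"chr{(j % 5) + 1}"
        pos = 1000 + 200 * (j // 5)
        chrom_of[lid] = (chrom, pos)
        annotations.append(LocusAnnotation(lid, chrom, pos, "A", "C"))
    cio.write_vcf(outdir / "breeding_scan.vcf", scan_gm, annotations)
    cio.write_metadata(outdir / "breeding_scan_meta.csv", scan_meta)
    with open(outdir / "genes.bed", "w") as fh:
        for g in range(40):
            chrom = f"chr{(g % 5) + 1}"
            start = 500 + 2500 * (g // 5)
            fh.write(f"{chrom}\t{start}\t{start + 2000}\tgene{g + 1:02d}\n")

    # assay-filter inputs
    flank_spec = FlankContextSpec(n_contexts=60, frac_multimap=0.1, seed=int(rng.integers(2**31 - 1)))
    contexts, flank_truth, reference = gen_flank_contexts(flank_spec)
    cio.write_flank_contexts(outdir / "flanks.fasta", outdir / "flank_variants.tsv", contexts)
    with open(outdir / "reference.fasta", "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n{seq}\n")

    # candidate-panel baseline + chronotype migrants
    panel_spec = chronotype_baseline_spec(seed=int(rng.integers(2**31 - 1)))
    panel_gm, panel_meta, panel_truth = gen_baseline(panel_spec)
    mig_spec = MigrationSeriesSpec(scenario="chronotype", seed=int(rng.integers(2**31 - 1)))
    mig_gm, mig_meta, mig_truth = gen_migration_series(mig_spec, panel_truth)
    cio.write_genotype_csv(outdir / "panel_baseline.csv", panel_gm)
    cio.write_metadata(outdir / "panel_baseline_meta.csv", panel_meta)
    cio.write_genotype_csv(outdir / "panel_migrants.csv", mig_gm)
    cio.write_metadata(outdir / "panel_migrants_meta.csv", mig_meta)

    truth = {
        "seed": seed,
        "scan": {k: v for k, v in scan_truth.items() if k != "pop_freqs"},
        "flanks": flank_truth,
        "panel": {k: v for k, v in panel_truth.items() if k != "pop_freqs"},
        "migrants": mig_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
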