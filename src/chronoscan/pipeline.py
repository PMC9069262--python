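"""End-to-end orchestration of the inference chain.

Two entry points:

* :func:`simulate_scenario` builds a matched breeding baseline and
  migration-station series under either the ``chronotype`` or the
  ``population_confound`` generator;
* :func:`run_chronotype_analysis` runs the analysis chain on any such
  dataset: mixture assignment of the migrants, ordinal PCA of the
  candidate (timing) loci across breeding + migrant samples, PC- and
  locus-level latitude associations among breeders, the minority
  temporal-spread check, and the final scenario verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronotype import (
    ALPHA_DEFAULT,
    MODAL_MIN_DEFAULT,
    ChronotypeReport,
    LatitudeTest,
    classify_scenario,
    latitude_association,
    minority_spread_test,
)
from .datatypes import GenotypeMatrix
from .gsi import CERTAINTY_DEFAULT, build_baseline, mixture_em
from .ordpca import PcaConfig, fit_ordinal_pca, fix_sign
from .simulate import (
    MigrationSeriesSpec,
    chronotype_baseline_spec,
    confound_baseline_spec,
    gen_baseline,
    gen_migration_series,
)

log = logging.getLogger(__name__)


@dataclass
class ScenarioDataset:
    baseline_gm: GenotypeMatrix
    baseline_meta: pd.DataFrame
    baseline_truth: dict
    migrant_gm: GenotypeMatrix
    migrant_meta: pd.DataFrame
    migrant_truth: dict

    @property
    def timing_loci(self) -> list[str]:
        return self.migrant_truth["timing_loci"]


def simulate_scenario(scenario: str, seed: int = 0, **series_overrides) -> ScenarioDataset:
    """Simulate one full dataset under a named scenario.

    ``chronotype``: one panmictic source, additive timing effects at the
    candidate loci.  ``population_confound``: two sources differing in
    mean passage date, candidate-locus frequency and breeding latitude.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = int(rng.integers(2**31 - 1)), int(rng.integers(2**31 - 1))
    if scenario == "chronotype":
        bspec = chronotype_baseline_spec(seed=s1)
        defaults = dict(scenario="chronotype", effect_days=-5.0)
    elif scenario == "population_confound":
        bspec = confound_baseline_spec(seed=s1)
        defaults = dict(scenario="population_confound", effect_days=0.0)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    defaults.update(series_overrides)
    gm, meta, truth = gen_baseline(bspec)
    mspec = MigrationSeriesSpec(seed=s2, **defaults)
    mgm, mmeta, mtruth = gen_migration_series(mspec, truth)
    return ScenarioDataset(gm, meta, truth, mgm, mmeta, mtruth)


def run_chronotype_analysis(
    ds: ScenarioDataset,
    candidate_loci: list[str] | None = None,
    certainty_threshold: float = CERTAINTY_DEFAULT,
    modal_min: float = MODAL_MIN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    latitude_subset: str = "all",
    pop_field: str = "site",
) -> ChronotypeReport:
    """Run assignment, ordinal PCA and the disambiguation tests.

    ``candidate_loci`` defaults to the dataset's timing loci (for
    simulated data) and must be given for real data.  ``latitude_subset``
    chooses the breeding samples entering the latitude tests: ``"all"``
    (default) or ``"modal"`` (only the modal cluster's breeding samples;
    note this blinds the test to a between-population cline).
    """
    if candidate_loci is None:
        candidate_loci = ds.timing_loci

    # 1. mixture assignment of migrants against the breeding baseline
    baseline = build_baseline(ds.baseline_gm, ds.baseline_meta, pop_field=pop_field)
    assignments = mixture_em(ds.migrant_gm, baseline, threshold=certainty_threshold)

    # 2. ordinal PCA of candidate-locus genotypes, breeding + migrants jointly
    cand_base = ds.baseline_gm.subset_loci(candidate_loci)
    cand_mig = ds.migrant_gm.subset_loci(candidate_loci)
    joint = GenotypeMatrix(
        list(cand_base.sample_ids) + list(cand_mig.sample_ids),
        candidate_loci,
        np.vstack([cand_base.codes, cand_mig.codes]),
        list(cand_base.counted_allele),
    )
    pca = fix_sign(fit_ordinal_pca(joint, PcaConfig(n_dim=min(2, len(candidate_loci) - 1))))
    pc1 = pd.Series(pca.object_scores[:, 0], index=pca.sample_ids)

    # 3. latitude associations among breeding samples
    breeders = ds.baseline_meta[ds.baseline_meta["latitude"].notna()]
    if latitude_subset == "modal":
        certain = assignments.certainty_flag
        labels = np.array(assignments.map_label)[certain]
        if labels.size:
            vals, counts = np.unique(labels, return_counts=True)
            modal_pop = str(vals[np.argmax(counts)])
            breeders = breeders[breeders[pop_field] == modal_pop]
    subset = breeders["sample_id"].tolist()

    lat_tests = []
    slope, p, n = latitude_association(pc1, ds.baseline_meta, subset)
    lat_tests.append(LatitudeTest("PC1", slope, p, n=n))
    base_idx = {s: i for i, s in enumerate(ds.baseline_gm.sample_ids)}
    for lid in candidate_loci:
        j = ds.baseline_gm.locus_index([lid])[0]
        codes = ds.baseline_gm.codes[:, j].astype(float)
        codes[codes < 0] = np.nan
        values = pd.Series(codes, index=ds.baseline_gm.sample_ids)
        slope, p, n = latitude_association(values, ds.baseline_meta, subset)
        lat_tests.append(LatitudeTest(lid, slope, p, n=n))

    # 4. minority temporal spread among confidently assigned migrants
    minority = minority_spread_test(assignments, ds.migrant_meta)

    # 5. verdict
    return classify_scenario(assignments, lat_tests, minority, modal_min=modal_min, alpha=alpha)
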