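"""Disambiguating chronotypes from population passage.

A seasonal shift in allele frequency at a migration station has two
competing explanations: early- and late-migrating *chronotypes* within a
single panmictic source, or genetically distinct populations passing
through at different times.  Three lines of evidence separate them:

1. assignment concentration — do confidently assigned migrants map
   overwhelmingly to a single (modal) source population?
2. latitude associations — do the PC score and the focal-locus genotypes
   correlate with breeding latitude (a population-passage signature)?
3. minority temporal spread — are the migrants assigned away from the
   modal population clustered in time (passage) or spread across the
   season (noise)?

The verdict rule here is an explicit formalisation with configurable
thresholds; the report always carries the raw statistics so the call can
be re-judged under different thresholds, and recomputing the verdict
from the recorded statistics reproduces it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsi import MixtureResult

log = logging.getLogger(__name__)

MODAL_MIN_DEFAULT = 0.9
ALPHA_DEFAULT = 0.05
MIN_MINORITY_FOR_TEST = 3


@dataclass
class LatitudeTest:
    name: str
    slope: float
    p_value: float
    p_holm: float = float("nan")
    n: int = 0


@dataclass
class MinoritySpread:
    status: str  # "tested" | "low_power" | "not_applicable"
    statistic: float = float("nan")  # Mann-Whitney U when tested
    p_value: float = float("nan")
    n_minority: int = 0
    n_modal: int = 0
    day_range_coverage: float = float("nan")  # low-power fallback


@dataclass
class ChronotypeReport:
    modal_population: str
    fraction_confident_modal: float
    n_confident: int
    latitude_tests: list[LatitudeTest]
    minority_spread: MinoritySpread
    verdict: str  # chronotype_consistent | population_passage_consistent | indeterminate
    modal_min: float = MODAL_MIN_DEFAULT
    alpha: float = ALPHA_DEFAULT

    def to_dict(self) -> dict:
        return {
            "modal_population": self.modal_population,
            "fraction_confident_modal": self.fraction_confident_modal,
            "n_confident": self.n_confident,
            "latitude_tests": [vars(t) for t in self.latitude_tests],
            "minority_spread": vars(self.minority_spread),
            "verdict": self.verdict,
            "thresholds": {"modal_min": self.modal_min, "alpha": self.alpha},
        }


def latitude_association(values: pd.Series, meta: pd.DataFrame, subset: list[str] | None = None):
    """OLS slope and two-sided p of a response on breeding latitude.

    ``values`` is indexed by sample_id (PC score or genotype code);
    ``subset`` optionally restricts to particular samples.  Requires >=
    10 samples with latitude and a non-constant latitude.
    """
    m = meta[meta["latitude"].notna()]
    if subset is not None:
        m = m[m["sample_id"].isin(subset)]
    m = m[m["sample_id"].isin(values.index)]
    y = values.loc[m["sample_id"]].to_numpy(dtype=float)
    lat = m["latitude"].to_numpy(dtype=float)
    ok = np.isfinite(y)
    y, lat = y[ok], lat[ok]
    if len(y) < 10:
        raise ValueError(f"need >= 10 samples with latitude, have {len(y)}")
    if np.std(lat) == 0:
        raise ValueError("latitude is constant in the subset")
    X = sm.add_constant(lat)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.pvalues[1]), len(y)


def minority_spread_test(assignments: MixtureResult, meta: pd.DataFrame) -> MinoritySpread:
    """Compare capture days of minority- vs modal-assigned migrants.

    Only confidently assigned migrants enter.  With >= 3 minority
    individuals a two-sided Mann-Whitney rank-sum test is run; with 1-2,
    the observed minority day range as a fraction of the confident
    migrants' season span is reported instead (low power); with none,
    the check is not applicable.
    """
    df = assignments.frame().merge(meta[["sample_id", "capture_day"]], on="sample_id")
    df = df[df["certain"] & df["capture_day"].notna()]
    if len(df) == 0:
        return MinoritySpread("not_applicable")
    modal = df["map_label"].mode().iloc[0]
    minority = df[df["map_label"] != modal]
    modal_days = df.loc[df["map_label"] == modal, "capture_day"].astype(float)
    min_days = minority["capture_day"].astype(float)
    if len(min_days) == 0:
        return MinoritySpread("not_applicable", n_modal=len(modal_days))
    if len(min_days) < MIN_MINORITY_FOR_TEST:
        span = df["capture_day"].max() - df["capture_day"].min()
        coverage = float((min_days.max() - min_days.min()) / span) if span > 0 else 0.0
        return MinoritySpread(
            "low_power",
            n_minority=len(min_days),
            n_modal=len(modal_days),
            day_range_coverage=coverage,
        )
    stat, p = stats.mannwhitneyu(min_days, modal_days, alternative="two-sided")
    return MinoritySpread("tested", float(stat), float(p), len(min_days), len(modal_days))


def classify_scenario(
    assignments: MixtureResult,
    latitude_tests: list[LatitudeTest],
    minority: MinoritySpread,
    modal_min: float = MODAL_MIN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> ChronotypeReport:
    """Combine the three lines of evidence into a verdict.

    chronotype_consistent: confident assignments concentrate on one
    population (fraction >= modal_min), no Holm-adjusted latitude test is
    significant at alpha, and the minority migrants are not temporally
    clustered (p >= alpha, or no testable minority).
    population_passage_consistent: at least one latitude association is
    significant and the minority migrants cluster in time.  Anything
    else: indeterminate.
    """
    certain = assignments.certainty_flag
    labels = np.array(assignments.map_label)
    if certain.sum() == 0:
        modal_pop, frac_modal = "", float("nan")
    else:
        conf_labels = labels[certain]
        vals, counts = np.unique(conf_labels, return_counts=True)
        modal_pop = str(vals[np.argmax(counts)])
        frac_modal = float(counts.max() / certain.sum())

    tests = [LatitudeTest(t.name, t.slope, t.p_value, n=t.n) for t in latitude_tests]
    if tests:
        adj = multipletests([t.p_value for t in tests], method="holm")[1]
        for t, p in zip(tests, adj):
            t.p_holm = float(p)
    any_lat_sig = any(t.p_holm < alpha for t in tests)
    all_lat_ns = all(t.p_holm >= alpha for t in tests) if tests else True

    clustered = minority.status == "tested" and minority.p_value < alpha
    not_clustered = minority.status != "tested" or minority.p_value >= alpha

    if (
        np.isfinite(frac_modal)
        and frac_modal >= modal_min
        and all_lat_ns
        and not_clustered
    ):
        verdict = "chronotype_consistent"
    elif any_lat_sig and clustered:
        verdict = "population_passage_consistent"
    else:
        verdict = "indeterminate"

    return ChronotypeReport(
        modal_population=modal_pop,
        fraction_confident_modal=frac_modal,
        n_confident=int(certain.sum()),
        latitude_tests=tests,
        minority_spread=minority,
        verdict=verdict,
        modal_min=modal_min,
        alpha=alpha,
    )
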