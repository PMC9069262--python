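"""Mixture assignment and the chronotype-vs-population verdict.

Runs the full disambiguation chain on both simulated scenarios.  In the
chronotype scenario all migrants come from one panmictic source, so
confident assignments concentrate on one cluster, candidate loci show no
latitude cline among breeders, and the few minority-assigned birds are
scattered through the season.  In the population-confound scenario two
sources with different breeding latitudes and passage dates mix at the
station, producing the opposite signature.
"""

import chronoscan as cs

for scenario in ("chronotype", "population_confound"):
    ds = cs.simulate_scenario(scenario, seed=4)
    report = cs.run_chronotype_analysis(ds)
    print(f"=== {scenario} scenario ===")
    print(f"modal population: {report.modal_population!r}; "
          f"{report.fraction_confident_modal:.2f} of {report.n_confident} confident "
          f"assignments are modal")
    for t in report.latitude_tests:
        print(f"  latitude test {t.name:8s} slope {t.slope:+.3f}  p {t.p_value:.3g} "
              f"(Holm {t.p_holm:.3g})")
    ms = report.minority_spread
    if ms.status == "tested":
        print(f"  minority temporal spread: U = {ms.statistic:.0f}, p = {ms.p_value:.3g} "
              f"({ms.n_minority} vs {ms.n_modal} birds)")
    else:
        print(f"  minority temporal spread: {ms.status}")
    print(f"verdict: {report.verdict}\n")

print("A chronotype polymorphism leaves assignment and latitude structure")
print("untouched; mixed populations with offset passage dates are flagged by")
print("the latitude cline and the temporal clustering of minority assignments.")
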