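"""Generate a synthetic metro-area scenario and inspect its inputs.

Builds a 10x10 grid of ZCTA-like units with a clustered PrEP-prescriber
process, homogeneous pharmacies and a lognormal incidence surface, writes
the three standard input files plus ground truth, and prints what was made.
"""

from pathlib import Path

from pfnr import ScenarioConfig, generate_scenario, write_scenario, FacilityKind

scenario = generate_scenario(ScenarioConfig(seed=42, suppression_prob=0.1))
paths = write_scenario(scenario, Path("scenario_out"))

n_prep = sum(1 for f in scenario.facilities if f.kind is FacilityKind.PREP_PRESCRIBER)
n_pharm = sum(1 for f in scenario.facilities if f.kind is FacilityKind.PHARMACY)
n_suppressed = sum(1 for r in scenario.need if r.suppressed)

print(f"units:                {len(scenario.units)} (one region, ZCTA level)")
print(f"prescriber points:    {n_prep} (clustered near the urban kernel)")
print(f"pharmacy points:      {n_pharm} (homogeneous Poisson, 8 expected per unit)")
print(f"suppressed need rows: {n_suppressed} of {len(scenario.need)}")
print(f"files written:        {sorted(p.name for p in paths.values())}")
# The prescriber/pharmacy imbalance mirrors real provider geography: few
# prescribing locations, concentrated downtown; pharmacies everywhere.
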