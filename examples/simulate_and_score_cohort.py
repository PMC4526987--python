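"""Generate a synthetic cohort and recover its planted structure.

Simulates 500 patients at the default regime and completeness mixtures,
scores every pathway, and compares the recovered completeness classes with
the generator's ground truth.
"""

from pathforge import Cohort, SimulationConfig, score_cohort, simulate_cohort

config = SimulationConfig(n_patients=500, seed=42)
master, truth = simulate_cohort(config)
cohort = Cohort.from_master(master)
scores = score_cohort(cohort)

planted = dict(zip(truth.Identifier, truth.ScoreClass))
agreement = sum(
    scores.records[pid].overall == planted[pid] for pid in planted
) / len(planted)

print(f"{len(master)} activities over {len(cohort)} patients")
print(scores.frequencies.to_string(index=False))
print(f"planted-class agreement: {agreement:.1%}")

# Each row gives one completeness level's share of the cohort and the mean
# number of distinct activity codes among its pathways; agreement of 100%
# means the scorer recovered exactly the class each patient was built to be.
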