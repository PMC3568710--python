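"""Operating characteristics of the validation probability by simulation.

100 synthetic expression experiments (1,000 genes, 300 differentially
expressed, two groups of 10) per scenario; every gene significant at each
FDR cutoff is validated exhaustively.
"""

from valprob import ExperimentConfig, ScenarioConfig, run_scenario

exp = ExperimentConfig(seed=123)
for scenario in ("errorless", "noisy_validation", "misspecified"):
    summary = run_scenario(ScenarioConfig(scenario=scenario), exp)
    print(f"scenario: {scenario} (uniform prior)")
    print(summary.to_frame().round(2).to_string(index=False))
    print()

print(
    "When validation should succeed (errorless / noisy assay) the median\n"
    "validation probability climbs with the FDR cutoff and hits 1.00 at 50%.\n"
    "When the original technology is wrong for a third of its signals\n"
    "(misspecified), probabilities collapse to ~0 at 5-10% and the posterior\n"
    "expected FDR overshoots the claim — the statistic flags the failure."
)
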