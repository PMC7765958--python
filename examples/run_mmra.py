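"""Run the four-step miRNA master-regulator analysis on a planted study.

The four filters (miRNA differential expression; consensus-target Fisher
enrichment in the gene signature; mutual-information network enrichment;
stepwise-AIC regression) progressively reduce the candidate miRNAs, and
the surviving (miRNA, gene) pairs are scored against the planted truth.
"""

from mirmaster import SimulationConfig, generate_study, generate_target_databases, run_mmra
from mirmaster.mmra import desk_scale_config

config = SimulationConfig(seed=1)
study = generate_study(config)
dbset = generate_target_databases(study.truth, config)

result = run_mmra(study, dbset, "HFepa_vs_reference", desk_scale_config(seed=1))

steps = ["DE miRNAs", "target-enriched", "network-enriched", "SLR-selected"]
for name, count in zip(steps, result.step_counts):
    print(f"step {steps.index(name) + 1} ({name:17s}): {count:3d} candidate miRNAs")

truth = study.truth.pairs
tp = result.pairs & truth
print(f"\nsurviving miRNA-gene pairs: {len(result.pairs)}")
print(f"recall    : {100 * len(tp) / len(truth):.0f}% of the {len(truth)} planted pairs")
print(f"precision : {100 * len(tp) / len(result.pairs):.0f}% of reported pairs are planted")

print("\nfirst rows of the result table (gene, signature side, regulator):")
print(result.to_table().head(5).to_string(index=False))
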