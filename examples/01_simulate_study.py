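"""Generate a study-shaped synthetic dataset with planted ground truth.

Builds the default two-treatment design (6 control vs 6 heat cultures;
17 elements, 120 metabolites, 163 volatiles with technical duplicates
and 5 water blanks) and prints what was planted: differential analytes,
correlation clusters, contaminants and treatment-unique volatiles.
"""

from chemomix import SyntheticConfig, generate_study

study = generate_study(SyntheticConfig(seed=1))

print("samples:", len(study.samples), "biological,",
      study.volatiles.n_samples, "volatile measurements,",
      study.blanks.n_samples, "water blanks")
print("elements:", study.elements.abundance.shape)
print("metabolites:", study.metabolites.abundance.shape)
print("volatiles (incl. contaminant rows):", study.volatiles.abundance.shape)

truth = study.truth
print()
print("planted differential analytes:", len(truth.differential))
print("planted clusters:",
      sorted((sum(1 for v in truth.cluster_membership.values() if v == k)
              for k in set(truth.cluster_membership.values())), reverse=True))
print("heat-only volatiles:", len(truth.unique_to_heat_ids),
      "| control-only:", len(truth.unique_to_control_ids),
      "| blank contaminants:", len(truth.contaminant_ids))
# The truth object is the oracle every downstream example is scored against.
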