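"""Clean a volatile peak table: internal standard, duplicates, blanks,
presence filter, per-cell scaling — then partition by treatment.

The printed Venn partition (heat-only / control-only / shared) is the
headline description of how heat stress reshapes the volatilome; the
class summary breaks the same partition down by chemical class.
"""

from chemomix import SyntheticConfig, generate_study, preprocess_volatiles
from chemomix.volatiles import class_summary, partition_by_treatment

study = generate_study(SyntheticConfig(seed=1))

clean = preprocess_volatiles(
    study.volatiles,
    study.blanks,
    study.volatile_is,
    blank_is_areas=study.blank_is,
    exclusion_list=study.known_artefacts,  # named artefacts (e.g. siloxanes)
)

print("volatiles in:", study.volatiles.n_analytes,
      "-> retained:", clean.n_analytes)
print("hygiene ladder:", " -> ".join(clean.ladder_steps()[1:]))

partition = partition_by_treatment(clean)
for name, ids in partition.items():
    print(f"{name}: {len(ids)}")

print()
print(class_summary(clean, partition).head(8))
# Rows are chemical classes; columns count analytes found only under
# heat, only in controls, or in both.
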