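"""Networks, 10-fold cross-validation and the stepwise 1-p screen.

Screens attributes by the one-way ANOVA F test (importance = 1 - p),
reduces the table to the 'important' attributes, and cross-validates a
small feed-forward network on it - the ten-row-plus-average accuracy table,
with per-class accuracies for the thermostable (F) and mesostable (T)
classes.
"""

import thermoprofile as tp
from thermoprofile.neural import NetTopology, TrainingConfig, mlp_factory

records = tp.generate_dataset(tp.default_thermo_config())
table = tp.featurize(records)
cleaned, _ = tp.clean(table)
normalized, _ = tp.normalize(cleaned)

screen = tp.stepwise_select(normalized)
important = screen.index[screen["label"] == "important"]
print(f"stepwise screen: {len(important)} of {normalized.n_attributes} "
      f"attributes labelled important (1 - p > 0.95)")
print("first few:", list(important[:6]))

reduced = normalized.select(list(important))
report = tp.cross_validate(
    reduced,
    mlp_factory(
        NetTopology([10, 5]),
        TrainingConfig(seed=0, epochs=200, learning_rate=0.1),
    ),
    k=10,
    seed=0,
)
print("\n10-fold cross-validation of a [10, 5] feed-forward network:")
print(report.to_frame().round(3).to_string())
print("""
accuracy_F / accuracy_T are the per-fold class accuracies for thermostable
and mesostable records; the Average row is the mean over folds. Training
runs on nine folds, testing on the held-out tenth.
""")
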