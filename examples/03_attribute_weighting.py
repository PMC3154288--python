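"""Eleven attribute-weighting algorithms and the vote tally.

Runs the full weighting suite on the default synthetic cohort (planted
effects: Gln depleted, Asn/Glu/Lys/Arg enriched in the thermostable class,
plus an Asn-Gln dipeptide excess), selects attributes with normalized
weight > 0.5 per method, and tallies how many methods picked each
attribute - the "how many weightings call this important" table.
"""

import thermoprofile as tp

records = tp.generate_dataset(tp.default_thermo_config())
table = tp.featurize(records)
cleaned, _ = tp.clean(table)
normalized, _ = tp.normalize(cleaned)

vectors, selections, failures = tp.weighting_suite(normalized)
print(f"{len(vectors)} weighting methods ran; failures: {failures or 'none'}\n")
for method, sel in selections.items():
    print(f"{method:<12} selected {len(sel.selected):>3} attributes")

votes = tp.votes_tally(selections, normalized.schema)
print("\ntop of the vote tally (attribute -> methods selecting it):")
print(votes.head(8).to_string())
print("""
The planted attributes (Gln percentage above all) win the tally, mirroring
how a majority of weighting algorithms single out Gln content and
hydrophilic-residue frequency as thermostability markers. rule_oner selects
almost everything by construction: the leave-one-feature-out OneR error
barely moves unless the single best attribute is removed.
""")
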