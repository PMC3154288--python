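"""Compute the per-sequence attribute vector for a few proteins.

Builds three labelled records, featurizes them and prints a handful of the
~888 numeric attributes: composition percentages, a dipeptide frequency and
the physicochemical indices. T = mesostable (optimum < 70 C), F =
thermostable (optimum > 70 C); the temperature header form derives the
label automatically.
"""

import thermoprofile as tp

records = [
    tp.ProteinRecord("lysozyme_like", "MKALIVLGLVLLSVTVQGKVFERCELARTLKRLGMDGYRGISLANWMCLAKWESGYNTRATNYNAGDRSTDYGIFQINSRYWCNDGKTPGAVNACHLSCSALLQDNIADAVACAKRVVRDPQGIRAWVAWRNRCQNRDVRQYVQGCGV", opt_temp=40),
    tp.ProteinRecord("thermo_candidate", "MEEKRKNAEENRKEAQRAKEEARERAENERKQREEAEKKAKEEQERKAQEEAEKARKEQEEAERKAREEQ", opt_temp=85),
    tp.ProteinRecord("unlabeled_fragment", "MQNQNQWDDEEKKHHGGPLVITA"),
]

table = tp.featurize(records)
print(f"{table.n_records} records x {table.n_attributes} numeric attributes\n")

show = ["pct_Q", "pct_E", "freq_hydrophilic", "freq_NQ",
        "mol_weight", "isoelectric_point", "aliphatic_index", "eps280_nonreduced"]
print(table.values[show].round(3).to_string())
print("\nlabels:", dict(table.labels.fillna("?")))
print("""
pct_Q/pct_E are Gln/Glu percentages of the standard residues;
freq_hydrophilic is the fraction of Kyte-Doolittle-hydrophilic residues;
freq_NQ is the overlapping Asn-Gln dipeptide frequency; the last four are
ProtParam-style physicochemical descriptors (Da, pH, dimensionless, 1/(M cm)).
""")
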