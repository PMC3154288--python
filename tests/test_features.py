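import json
from importlib import resources

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import thermoprofile as tp
from thermoprofile.alphabet import STANDARD_AA
from thermoprofile.features import feature_vector

sequences = st.text(alphabet=STANDARD_AA, min_size=1, max_size=80)
sequences_with_ambiguous = st.text(
    alphabet=STANDARD_AA + "BZXUOJ", min_size=1, max_size=80
)


class TestComposition:
    def test_single_residue_sequence(self):
        c = tp.composition_counts("QQQQ")
        assert c["count_Q"] == 4 and c["freq_Q"] == 1.0 and c["pct_Q"] == 100.0

    def test_two_denominators(self):
        c = tp.composition_counts("ACDX")
        assert c["count_other"] == 1 and c["freq_other"] == 0.25
        assert c["pct_A"] == pytest.approx(100 / 3)
        assert c["freq_A"] == 0.25

    def test_uniform_composition(self):
        c = tp.composition_counts(STANDARD_AA)
        assert all(c[f"freq_{aa}"] == 0.05 for aa in STANDARD_AA)

    @given(sequences_with_ambiguous)
    def test_count_conservation_and_freq_sum(self, seq):
        c = tp.composition_counts(seq)
        total = sum(c[f"count_{aa}"] for aa in STANDARD_AA) + c["count_other"]
        assert total == len(seq)
        fsum = sum(c[f"freq_{aa}"] for aa in STANDARD_AA) + c["freq_other"]
        assert fsum == pytest.approx(1.0, abs=1e-9)

    def test_empty_errors(self):
        for fn in (tp.composition_counts, tp.dipeptide_counts, tp.molecular_weight,
                   tp.element_composition, tp.aliphatic_index):
            with pytest.raises(ValueError):
                fn("")


class TestDipeptides:
    def test_overlapping_windows(self):
        d = tp.dipeptide_counts("QNQN")
        assert d["count_QN"] == 2 and d["count_NQ"] == 1
        assert d["freq_QN"] == pytest.approx(2 / 3)

    def test_pair(self):
        d = tp.dipeptide_counts("AA")
        assert d["count_AA"] == 1 and d["freq_AA"] == 1.0

    def test_nonstandard_voids_windows(self):
        d = tp.dipeptide_counts("AXA")
        assert sum(v for k, v in d.items() if k.startswith("count_")) == 0

    @given(sequences.filter(lambda s: len(s) >= 2))
    def test_freq_sums_to_one(self, seq):
        d = tp.dipeptide_counts(seq)
        fsum = sum(v for k, v in d.items() if k.startswith("freq_"))
        assert fsum == pytest.approx(1.0, abs=1e-9)


class TestElements:
    def test_glycine_formula(self):
        e = tp.element_composition("G")
        assert (e["count_elem_C"], e["count_elem_H"], e["count_elem_N"],
                e["count_elem_O"], e["count_elem_S"]) == (2, 5, 1, 2, 0)

    def test_diglycine_formula(self):
        e = tp.element_composition("GG")
        assert (e["count_elem_C"], e["count_elem_H"], e["count_elem_N"],
                e["count_elem_O"]) == (4, 8, 2, 3)

    @given(sequences)
    def test_frequencies_normalised(self, seq):
        e = tp.element_composition(seq)
        assert sum(v for k, v in e.items() if k.startswith("freq_")) == pytest.approx(1.0)


class TestMolecularWeight:
    def test_glycine(self):
        assert tp.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_additivity_step(self):
        assert tp.molecular_weight("GG") == pytest.approx(
            tp.molecular_weight("G") + 57.05, abs=0.01
        )

    @given(sequences, sequences)
    def test_additivity(self, s1, s2):
        assert tp.molecular_weight(s1 + s2) == pytest.approx(
            tp.molecular_weight(s1) + tp.molecular_weight(s2) - 18.01524, abs=1e-6
        )

    def test_biopython_agrees_on_average_mass_scale(self):
        # external sanity check; Biopython's average-mass table differs in
        # the third decimal per residue, hence the loose bound
        from Bio.SeqUtils import molecular_weight as bio_mw

        for seq in ["G", "MKVLY", "ACDEFGHIKLMNPQRSTVWY"]:
            assert tp.molecular_weight(seq) == pytest.approx(
                bio_mw(seq, "protein"), abs=0.05
            )


def _reference_pi(seq: str) -> float:
    """Independent pI: same pinned pKa table, different root finder."""
    with resources.files("thermoprofile.data").joinpath("pka.json").open() as fh:
        pka = json.load(fh)

    def charge(ph):
        groups = [(pka["n_terminus"], +1), (pka["c_terminus"], -1)]
        groups += [(v, +1) for aa, v in pka["positive"].items() for _ in range(seq.count(aa))]
        groups += [(v, -1) for aa, v in pka["negative"].items() for _ in range(seq.count(aa))]
        total = 0.0
        for pk, sign in groups:
            frac = 1.0 / (1.0 + 10.0 ** (sign * (ph - pk)))
            total += sign * frac
        return total

    return brentq(charge, 0.0, 14.0, xtol=1e-6)


class TestIsoelectricPoint:
    def test_zero_charge_at_pi(self):
        for seq in ["MKVLY", "DDKK", "GGG"]:
            assert abs(tp.net_charge(seq, tp.isoelectric_point(seq))) < 1e-3

    def test_charge_ordering(self):
        assert tp.isoelectric_point("KKKKK") > tp.isoelectric_point("DDDDD")

    def test_against_independent_root_finder(self):
        assert tp.isoelectric_point("DDDDD") == pytest.approx(
            _reference_pi("DDDDD"), abs=0.01
        )

    @given(sequences)
    def test_net_charge_strictly_decreasing(self, seq):
        grid = np.linspace(0, 14, 30)
        charges = [tp.net_charge(seq, ph) for ph in grid]
        assert all(a > b for a, b in zip(charges, charges[1:]))


class TestAliphaticIndex:
    @pytest.mark.parametrize(
        "seq,expected", [("AAAA", 100.0), ("AV", 195.0), ("GGGG", 0.0)]
    )
    def test_examples(self, seq, expected):
        assert tp.aliphatic_index(seq) == pytest.approx(expected)


class TestExtinction280:
    def test_tryptophan(self):
        assert tp.extinction_280("W")[0] == 5500.0

    def test_unpaired_cysteine(self):
        assert tp.extinction_280("C", reduced=False)[0] == 0.0

    def test_cystine_pair(self):
        assert tp.extinction_280("CC", reduced=False)[0] == 125.0
        assert tp.extinction_280("CC", reduced=True)[0] == 0.0

    def test_matches_biopython_exactly(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list(STANDARD_AA), size=rng.integers(5, 40)))
            reduced, oxidized = ProteinAnalysis(seq).molar_extinction_coefficient()
            assert tp.extinction_280(seq, reduced=True)[0] == reduced
            assert tp.extinction_280(seq, reduced=False)[0] == oxidized


class TestClassComposition:
    def test_positive(self):
        c = tp.class_composition("RKH")
        assert c["count_positive"] == 3 and c["freq_positive"] == 1.0

    def test_hydrophobic(self):
        c = tp.class_composition("AVLIMFC")
        assert c["freq_hydrophobic"] == 1.0 and c["freq_hydrophilic"] == 0.0

    @given(sequences)
    def test_hydropathy_partition(self, seq):
        c = tp.class_composition(seq)
        assert c["freq_hydrophilic"] + c["freq_hydrophobic"] == pytest.approx(1.0)


class TestFeaturize:
    def test_shape_and_labels(self):
        records = [
            tp.ProteinRecord("a", "MKVLYQQN", label="T"),
            tp.ProteinRecord("b", "MAACDE", label="F"),
        ]
        table = tp.featurize(records)
        assert table.n_records == 2
        assert table.n_attributes == len(tp.DEFAULT_SCHEMA.numeric_names)
        assert list(table.labels) == ["T", "F"]
        assert list(table.nterm) == ["M", "M"]

    def test_deterministic(self):
        records = [tp.ProteinRecord("a", "MKVLYQQN", label="T")]
        t1, t2 = tp.featurize(records), tp.featurize(records)
        assert t1.values.equals(t2.values)

    def test_error_names_record(self):
        class Broken:
            id = "bad_rec"
            sequence = ""
            label = None

        with pytest.raises(ValueError, match="bad_rec"):
            tp.featurize([Broken()])

    @given(st.lists(sequences_with_ambiguous, min_size=1, max_size=4))
    def test_pct_freq_relation(self, seqs):
        records = [tp.ProteinRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        table = tp.featurize(records)
        for i, rec in enumerate(records):
            row = table.values.iloc[i]
            n_std = len(rec.sequence) - row["count_other"]
            for aa in "AQW":
                if n_std:
                    assert row[f"pct_{aa}"] == pytest.approx(
                        100 * row[f"count_{aa}"] / n_std
                    )


def test_schema_family_inventory():
    counts = {}
    for entry in tp.DEFAULT_SCHEMA.entries:
        counts[entry.family] = counts.get(entry.family, 0) + 1
    assert counts["aa_count"] == counts["aa_freq"] == counts["aa_pct"] == 20
    assert counts["dipep_count"] == counts["dipep_freq"] == 400
    assert counts["element_count"] == counts["element_freq"] == 5
    assert counts["class_count"] == counts["class_freq"] == 4
    assert counts["physchem"] == 8
    assert counts["nterm"] == 1
    assert len(tp.DEFAULT_SCHEMA.categorical_names) == 1
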