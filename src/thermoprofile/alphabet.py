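"""Residue alphabets and pinned residue classes.

The twenty standard one-letter codes are ordered alphabetically; this order
is the canonical attribute order used throughout the package (schema order
decides every downstream tie-break). Ambiguity/rare codes (B, Z, X, U, O, J)
are accepted on input but contribute only to the "other residues" counters.

Hydrophilic/hydrophobic membership is pinned to the sign of the
Kyte-Doolittle hydropathy index: residues with negative hydropathy are
hydrophilic, positive are hydrophobic; the two sets partition the standard 20.
"""

from __future__ import annotations

import json
from importlib import resources

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
NONSTANDARD_AA: str = "BZXUOJ"
ACCEPTED_AA: frozenset[str] = frozenset(STANDARD_AA) | frozenset(NONSTANDARD_AA)

# charge classes
POSITIVE: frozenset[str] = frozenset("RKH")
NEGATIVE: frozenset[str] = frozenset("DE")

# Kyte-Doolittle sign classes
HYDROPHILIC: frozenset[str] = frozenset("RKNDQEHPYWSTG")
HYDROPHOBIC: frozenset[str] = frozenset("ACFILMV")

ELEMENTS: str = "CHNOS"

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _load_json(name: str) -> dict:
    with resources.files("thermoprofile.data").joinpath(name).open() as fh:
        return json.load(fh)


def residue_masses() -> tuple[dict[str, float], float]:
    """Average residue masses (Da) and the mass of one water."""
    d = _load_json("residue_masses.json")
    return dict(d["masses"]), float(d["water"])


def residue_elements() -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Per-residue C/H/N/O/S atom counts and the water formula."""
    d = _load_json("residue_elements.json")
    return dict(d["residues"]), dict(d["water"])


def pka_table() -> dict:
    """Pinned ionisable-group pKa set (termini + side chains)."""
    return _load_json("pka.json")


def background_composition() -> dict[str, float]:
    """Background amino-acid frequencies, renormalised to sum to 1."""
    freqs = _load_json("base_composition.json")["frequencies"]
    total = sum(freqs.values())
    return {aa: v / total for aa, v in freqs.items()}
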