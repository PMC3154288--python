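"""Canonical feature schema.

Attribute families, in fixed order (the order is load-bearing: it decides
tie-breaks in correlation cleaning, split search and vote tallies):

1.  ``count_<aa>``     - residue counts, standard 20, alphabetical order
2.  ``freq_<aa>``      - counts / full sequence length L
3.  ``pct_<aa>``       - 100 * counts / number of standard residues
4.  ``count_other``, ``freq_other`` - nonstandard residues (B,Z,X,U,O,J)
5.  ``count_<xy>``     - 400 overlapping dipeptide counts (standard pairs)
6.  ``freq_<xy>``      - dipeptide counts / (L - 1)
7.  ``count_elem_<e>``, ``freq_elem_<e>`` - C,H,N,O,S atoms of the molecular
    formula (standard residues + one water); freq over total atoms
8.  ``count_/freq_{positive,negative,hydrophilic,hydrophobic}`` - residue
    class counts and full-length frequencies
9.  physicochemical: length, mol_weight, isoelectric_point, aliphatic_index,
    eps280_nonreduced, abs280_nonreduced, eps280_reduced, abs280_reduced
10. ``nterm`` - N-terminal residue, the single categorical attribute
    (excluded from all numeric downstream stages)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import ELEMENTS, STANDARD_AA

RESIDUE_CLASSES = ("positive", "negative", "hydrophilic", "hydrophobic")
PHYSCHEM = (
    "length",
    "mol_weight",
    "isoelectric_point",
    "aliphatic_index",
    "eps280_nonreduced",
    "abs280_nonreduced",
    "eps280_reduced",
    "abs280_reduced",
)


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    family: str
    kind: str  # "numeric" | "categorical"


@dataclass(frozen=True)
class FeatureSchema:
    entries: tuple[SchemaEntry, ...]
    _index: dict[str, int] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("schema attribute names must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def numeric_names(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "numeric"]

    @property
    def categorical_names(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "categorical"]

    def position(self, name: str) -> int:
        return self._index[name]

    def family(self, name: str) -> str:
        return self.entries[self._index[name]].family

    def sort_key(self, name: str) -> int:
        """Schema order for downstream deterministic tie-breaking."""
        return self._index[name]

    def to_manifest(self) -> list[dict]:
        return [
            {"name": e.name, "family": e.family, "kind": e.kind, "order": i}
            for i, e in enumerate(self.entries)
        ]


def build_schema() -> FeatureSchema:
    entries: list[SchemaEntry] = []

    def add(name: str, family: str, kind: str = "numeric") -> None:
        entries.append(SchemaEntry(name, family, kind))

    for aa in STANDARD_AA:
        add(f"count_{aa}", "aa_count")
    for aa in STANDARD_AA:
        add(f"freq_{aa}", "aa_freq")
    for aa in STANDARD_AA:
        add(f"pct_{aa}", "aa_pct")
    add("count_other", "other_count")
    add("freq_other", "other_freq")
    for x in STANDARD_AA:
        for y in STANDARD_AA:
            add(f"count_{x}{y}", "dipep_count")
    for x in STANDARD_AA:
        for y in STANDARD_AA:
            add(f"freq_{x}{y}", "dipep_freq")
    for e in ELEMENTS:
        add(f"count_elem_{e}", "element_count")
    for e in ELEMENTS:
        add(f"freq_elem_{e}", "element_freq")
    for cls in RESIDUE_CLASSES:
        add(f"count_{cls}", "class_count")
        add(f"freq_{cls}", "class_freq")
    for name in PHYSCHEM:
        add(name, "physchem")
    add("nterm", "nterm", kind="categorical")
    return FeatureSchema(tuple(entries))


#: module-level canonical schema (construction is cheap and pure)
DEFAULT_SCHEMA = build_schema()
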