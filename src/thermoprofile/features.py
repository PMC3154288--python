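"""Per-sequence attribute calculators and the featurize step.

Design conventions (documented once, applied everywhere):

* Nonstandard residues (B, Z, X, U, O, J) count only toward
  ``count_other``/``freq_other``. They are excluded from molecular weight,
  pI, the molecular formula, residue classes and dipeptides (a dipeptide
  window containing a nonstandard residue contributes to no pair).
* ``freq_*`` uses the full sequence length L as denominator; ``pct_*`` uses
  the number of standard residues (and is scaled by 100). The two families
  therefore coexist as distinct attributes rather than exact rescalings.
* Molecular formula = sum of residue formulas plus one water; molecular
  weight = sum of average residue masses plus 18.01524 Da.
* pI is the bisection root of the Henderson-Hasselbalch net charge over the
  pinned pKa table (termini + C, D, E, H, K, R, Y side chains); the charge is
  strictly decreasing in pH so the root is unique.
* Extinction at 280 nm: eps = 1490*nTyr + 5500*nTrp (+ 125 per complete
  cystine pair, floor(nCys/2), in the non-reduced state); absorbance is
  eps / molecular weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alphabet import (
    ELEMENTS,
    HYDROPHILIC,
    HYDROPHOBIC,
    NEGATIVE,
    POSITIVE,
    STANDARD_AA,
    pka_table,
    residue_elements,
    residue_masses,
)
from .records import ProteinRecord
from .schema import DEFAULT_SCHEMA
from .table import FeatureTable

_MASSES, _WATER_MASS = residue_masses()
_ELEM, _WATER_FORMULA = residue_elements()
_PKA = pka_table()

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def _require_nonempty(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper()


def composition_counts(sequence: str) -> dict[str, float]:
    """Amino-acid counts, full-length frequencies, standard-residue
    percentages, plus the other-residue count and frequency."""
    sequence = _require_nonempty(sequence)
    length = len(sequence)
    counts = np.zeros(20, dtype=int)
    for ch in sequence:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    n_std = int(counts.sum())
    out: dict[str, float] = {}
    for i, aa in enumerate(STANDARD_AA):
        out[f"count_{aa}"] = int(counts[i])
        out[f"freq_{aa}"] = counts[i] / length
        out[f"pct_{aa}"] = 100.0 * counts[i] / n_std if n_std else 0.0
    out["count_other"] = length - n_std
    out["freq_other"] = (length - n_std) / length
    return out


def dipeptide_counts(sequence: str) -> dict[str, float]:
    """Overlapping dipeptide counts and frequencies (denominator L-1).

    Windows containing a nonstandard residue contribute to no pair; for
    length-1 sequences all 400 counts and frequencies are zero.
    """
    sequence = _require_nonempty(sequence)
    length = len(sequence)
    counts: dict[str, int] = {}
    for i in range(length - 1):
        x, y = sequence[i], sequence[i + 1]
        if x in _AA_INDEX and y in _AA_INDEX:
            counts[x + y] = counts.get(x + y, 0) + 1
    denom = length - 1
    out: dict[str, float] = {}
    for x in STANDARD_AA:
        for y in STANDARD_AA:
            c = counts.get(x + y, 0)
            out[f"count_{x}{y}"] = c
            out[f"freq_{x}{y}"] = c / denom if denom else 0.0
    return out


def element_composition(sequence: str) -> dict[str, float]:
    """C/H/N/O/S atom counts of the molecular formula and their fractions.

    Formula = standard residues + one water; nonstandard residues excluded.
    """
    sequence = _require_nonempty(sequence)
    totals = dict(_WATER_FORMULA)
    for ch in sequence:
        formula = _ELEM.get(ch)
        if formula is not None:
            for e in ELEMENTS:
                totals[e] += formula[e]
    n_atoms = sum(totals.values())
    out: dict[str, float] = {}
    for e in ELEMENTS:
        out[f"count_elem_{e}"] = totals[e]
        out[f"freq_elem_{e}"] = totals[e] / n_atoms
    return out


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da (standard residues + one water)."""
    sequence = _require_nonempty(sequence)
    return sum(_MASSES.get(ch, 0.0) for ch in sequence) + _WATER_MASS


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Positive groups (N-terminus, K, R, H): +1 / (1 + 10^(pH - pKa));
    negative groups (C-terminus, D, E, C, Y): -1 / (1 + 10^(pKa - pH)).
    """
    sequence = _require_nonempty(sequence)
    charge = 1.0 / (1.0 + 10.0 ** (ph - _PKA["n_terminus"]))
    charge -= 1.0 / (1.0 + 10.0 ** (_PKA["c_terminus"] - ph))
    for aa, pka in _PKA["positive"].items():
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in _PKA["negative"].items():
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH in [0, 14] at which the net charge vanishes, by bisection."""
    sequence = _require_nonempty(sequence)
    lo, hi = 0.0, 14.0
    # net charge is strictly decreasing in pH; clamp if no sign change
    if net_charge(sequence, lo) < 0:
        return lo
    if net_charge(sequence, hi) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9 X(Val) + 3.9 (X(Ile)+X(Leu)),
    X in mole percent of standard residues."""
    sequence = _require_nonempty(sequence)
    n_std = sum(1 for ch in sequence if ch in _AA_INDEX)
    if n_std == 0:
        return 0.0
    x = {aa: 100.0 * sequence.count(aa) / n_std for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def extinction_280(sequence: str, reduced: bool = False) -> tuple[float, float]:
    """Molar extinction coefficient at 280 nm (1/(M*cm)) and the
    mass-normalised absorbance eps / MW.

    Non-reduced state adds 125 per complete cystine pair (floor(nCys/2));
    the reduced state counts no cystines.
    """
    sequence = _require_nonempty(sequence)
    eps = 1490.0 * sequence.count("Y") + 5500.0 * sequence.count("W")
    if not reduced:
        eps += 125.0 * (sequence.count("C") // 2)
    return eps, eps / molecular_weight(sequence)


def class_composition(sequence: str) -> dict[str, float]:
    """Counts/full-length frequencies of positively charged (R,K,H),
    negatively charged (D,E), hydrophilic and hydrophobic residues."""
    sequence = _require_nonempty(sequence)
    length = len(sequence)
    sets = {
        "positive": POSITIVE,
        "negative": NEGATIVE,
        "hydrophilic": HYDROPHILIC,
        "hydrophobic": HYDROPHOBIC,
    }
    out: dict[str, float] = {}
    for name, members in sets.items():
        c = sum(1 for ch in sequence if ch in members)
        out[f"count_{name}"] = c
        out[f"freq_{name}"] = c / length
    return out


def feature_vector(sequence: str) -> tuple[dict[str, float], str]:
    """All numeric attributes for one sequence, plus the categorical nterm."""
    sequence = _require_nonempty(sequence)
    vec: dict[str, float] = {}
    vec.update(composition_counts(sequence))
    vec.update(dipeptide_counts(sequence))
    vec.update(element_composition(sequence))
    vec.update(class_composition(sequence))
    mw = molecular_weight(sequence)
    eps_nr, abs_nr = extinction_280(sequence, reduced=False)
    eps_r, abs_r = extinction_280(sequence, reduced=True)
    vec.update(
        {
            "length": len(sequence),
            "mol_weight": mw,
            "isoelectric_point": isoelectric_point(sequence),
            "aliphatic_index": aliphatic_index(sequence),
            "eps280_nonreduced": eps_nr,
            "abs280_nonreduced": abs_nr,
            "eps280_reduced": eps_r,
            "abs280_reduced": abs_r,
        }
    )
    return vec, sequence[0]


def featurize(records: list[ProteinRecord]) -> FeatureTable:
    """Assemble the full FeatureTable for a list of records.

    Deterministic; any per-record failure aborts naming the record id.
    """
    if not records:
        raise ValueError("no records to featurize")
    schema = DEFAULT_SCHEMA
    numeric_names = schema.numeric_names
    rows: list[list[float]] = []
    nterms: list[str] = []
    ids: list[str] = []
    labels: list[str | None] = []
    for rec in records:
        try:
            vec, nterm = feature_vector(rec.sequence)
        except Exception as exc:
            raise ValueError(f"featurization failed for record {rec.id!r}: {exc}") from exc
        rows.append([vec[name] for name in numeric_names])
        nterms.append(nterm)
        ids.append(rec.id)
        labels.append(rec.label)
    values = pd.DataFrame(
        np.asarray(rows, dtype=float), index=pd.Index(ids, name="id"), columns=numeric_names
    )
    label_series = pd.Series(labels, index=values.index, dtype=object)
    if label_series.isna().all():
        label_series = None
    return FeatureTable(
        values, label_series, pd.Series(nterms, index=values.index), schema
    )
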