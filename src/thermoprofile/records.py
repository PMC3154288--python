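"""Protein records and FASTA input.

A :class:`ProteinRecord` carries a sequence plus an optional optimum growth
temperature and/or a binary stability label: ``T`` (mesostable, optimum below
70 °C) or ``F`` (thermostable, optimum above 70 °C). The 70 °C boundary value
itself is unlabelable and such records are reported, not silently dropped.

Labels come from the FASTA header (``>id|T``, ``>id|F`` or ``>id|temp=85``)
or from a two-column id/label TSV sidecar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .alphabet import ACCEPTED_AA

LABEL_BOUNDARY_C = 70.0


class FastaParseError(ValueError):
    pass


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    opt_temp: float | None = None
    label: str | None = None  # "T" | "F" | None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - ACCEPTED_AA)
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {''.join(bad)!r}"
            )
        if self.label is None and self.opt_temp is not None:
            self.label = label_from_temperature(self.opt_temp)
        if self.label not in (None, "T", "F"):
            raise ValueError(f"record {self.id!r}: label must be T or F")


def label_from_temperature(opt_temp: float) -> str | None:
    """T below 70 °C, F above; exactly 70 °C is unlabelable (None)."""
    if opt_temp < LABEL_BOUNDARY_C:
        return "T"
    if opt_temp > LABEL_BOUNDARY_C:
        return "F"
    return None


def _parse_header(header: str) -> tuple[str, float | None, str | None]:
    """Split ``id|T``, ``id|F``, ``id|temp=85`` or bare ``id``."""
    if "|" not in header:
        return header, None, None
    rid, _, tag = header.partition("|")
    tag = tag.strip()
    if tag in ("T", "F"):
        return rid, None, tag
    if tag.startswith("temp="):
        try:
            return rid, float(tag[5:]), None
        except ValueError as exc:
            raise FastaParseError(
                f"header {header!r}: unparseable temperature tag {tag!r}"
            ) from exc
    raise FastaParseError(f"header {header!r}: unrecognised label tag {tag!r}")


def _check_fasta_structure(path: Path) -> None:
    """Pre-scan for structural problems so errors can name the line."""
    saw_header = False
    saw_residues = False
    n_nonblank = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            n_nonblank += 1
            if line.startswith(">"):
                if saw_header and not saw_residues:
                    raise FastaParseError(
                        f"{path}: line {lineno}: header with no preceding sequence"
                    )
                saw_header, saw_residues = True, False
            else:
                if not saw_header:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before first '>' header"
                    )
                saw_residues = True
    if n_nonblank == 0:
        raise FastaParseError(f"{path}: empty FASTA file")
    if saw_header and not saw_residues:
        raise FastaParseError(f"{path}: final record has no sequence")


def read_label_sidecar(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, label T/F) mapping record ids to labels."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("T", "F"):
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>T|F'")
            labels[parts[0]] = parts[1]
    return labels


def read_fasta(
    path: str | Path,
    sidecar: str | Path | None = None,
) -> list[ProteinRecord]:
    """Read FASTA into labelled records (file order, sequences upper-cased).

    Records whose header carries no resolvable label (no tag, or the boundary
    temperature 70 °C) are kept with ``label=None`` and reported via a
    UserWarning so they are never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_structure(path)
    side = read_label_sidecar(sidecar) if sidecar is not None else {}

    records: list[ProteinRecord] = []
    unlabeled: list[str] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        rid, temp, label = _parse_header(seq_rec.description.strip())
        if label is None and rid in side:
            label = side[rid]
        rec = ProteinRecord(rid, str(seq_rec.seq), opt_temp=temp, label=label)
        if rec.label is None:
            unlabeled.append(rid)
        records.append(rec)
    if unlabeled:
        warnings.warn(
            f"{path}: {len(unlabeled)} record(s) without a resolvable T/F label: "
            + ", ".join(unlabeled[:10]),
            UserWarning,
            stacklevel=2,
        )
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records with ``id|T`` / ``id|F`` / bare-id headers."""
    with open(path, "w") as fh:
        for rec in records:
            tag = f"|{rec.label}" if rec.label else ""
            fh.write(f">{rec.id}{tag}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
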