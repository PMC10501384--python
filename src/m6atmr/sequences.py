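"""RNA sequence records and FASTA input.

A dataset is a list of fixed-length :class:`RnaSequence` windows over the
RNA alphabet {A, C, G, U}, each centered on a candidate adenosine and
optionally carrying a binary label (1 = methylated central A).  DNA-alphabet
FASTA is accepted: T is mapped to U and lowercase is uppercased.  Labels come
either from a ``label=0|1`` token in the FASTA header or from a two-column
(id, label) TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

__all__ = ["RnaSequence", "read_fasta", "write_fasta", "SequenceError"]


class SequenceError(ValueError):
    """Raised for malformed records, invalid symbols or mixed lengths."""


@dataclass(frozen=True)
class RnaSequence:
    """One fixed-length RNA window with an optional binary label."""

    id: str
    residues: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise SequenceError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


def normalize_residues(raw: str, record_id: str, on_invalid: str = "error") -> str | None:
    """Uppercase, map T->U, and validate against the RNA alphabet.

    ``on_invalid``: ``"error"`` raises; ``"drop"`` returns None so the caller
    can skip the record.
    """
    residues = raw.upper().replace("T", "U")
    bad = set(residues) - RNA_ALPHABET
    if bad:
        if on_invalid == "drop":
            return None
        raise SequenceError(
            f"record {record_id!r} contains invalid symbol(s) {sorted(bad)}; "
            "only A/C/G/U (T accepted) are allowed")
    return residues


_LABEL_RE = re.compile(r"\blabel=([01])\b")


def _label_from_header(description: str) -> int | None:
    m = _LABEL_RE.search(description)
    return int(m.group(1)) if m else None


def read_fasta(path: str | Path, labels: str | Path | None = None,
               on_invalid: str = "error") -> list[RnaSequence]:
    """Read a FASTA file of equal-length RNA windows, in file order.

    Parameters
    ----------
    path : FASTA file (wrapped or single-line).
    labels : optional two-column TSV (id, label); overrides header tags.
    on_invalid : "error" (default) or "drop" for records with symbols
        outside {A,C,G,U,T}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map: dict[str, int] | None = None
    if labels is not None:
        tab = pd.read_csv(labels, sep="\t", header=None, names=["id", "label"],
                          dtype={"id": str})
        label_map = dict(zip(tab["id"], tab["label"].astype(int)))

    records: list[RnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq), rec.id, on_invalid)
        if residues is None:
            continue
        if label_map is not None:
            label = label_map.get(rec.id)
        else:
            label = _label_from_header(rec.description)
        records.append(RnaSequence(id=rec.id, residues=residues, label=label))
    if not records:
        raise SequenceError(f"no parseable records in {path}")

    lengths = sorted({len(r) for r in records})
    if len(lengths) > 1:
        raise SequenceError(
            f"all sequences must share one length; found lengths {lengths}")
    return records


def write_fasta(records: list[RnaSequence], path: str | Path,
                labels_path: str | Path | None = None) -> None:
    """Write records with ``label=`` header tags, plus an optional labels TSV."""
    with open(path, "w") as fh:
        for r in records:
            tag = f" label={r.label}" if r.label is not None else ""
            fh.write(f">{r.id}{tag}\n{r.residues}\n")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for r in records:
                fh.write(f"{r.id}\t{r.label if r.label is not None else ''}\n")
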