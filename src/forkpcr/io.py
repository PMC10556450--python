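"""FASTA / TSV / JSON readers and writers.

FASTA goes through Biopython's SeqIO; sequences are normalized to
uppercase and validated against the strict ACGT alphabet, with errors
reporting the record id and offending offset.  Primer sheets are TSV with
columns ``set``, ``role``, ``name``, ``sequence``.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .oligos import Oligo, ForkPrimerSet, decompose_fork

__all__ = [
    "FastaError",
    "read_fasta",
    "write_fasta",
    "read_primer_tsv",
    "write_primer_tsv",
    "primer_records",
    "write_json",
]

log = logging.getLogger("forkpcr")


class FastaError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA as [(id, uppercase ACGT sequence), ...].

    Lowercase input is normalized with a logged note; characters outside
    ACGT raise :class:`FastaError` naming the record and offset.  An empty
    file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # malformed header/structure
        raise FastaError(f"{path}: {exc}") from exc
    for rec in parsed:
        raw = str(rec.seq)
        if raw != raw.upper():
            log.info("record %s: lowercase bases normalized to uppercase", rec.id)
        seq = raw.upper()
        for off, ch in enumerate(seq):
            if ch not in "ACGT":
                raise FastaError(
                    f"{path}: record {rec.id!r} has non-ACGT character {ch!r} "
                    f"at offset {off}"
                )
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} is empty")
        records.append((rec.id, seq))
    if not records:
        log.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write records as wrapped FASTA (70 columns)."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)


def primer_records(
    fork_sets: list[ForkPrimerSet], extra: list[Oligo] | None = None
) -> list[dict]:
    """Flatten fork sets (+ optional NSPs) into primer-sheet rows."""
    rows = []
    for fs in fork_sets:
        for o in fs.oligos:
            rows.append(
                {"set": fs.set_id, "role": o.role, "name": o.name, "sequence": o.seq}
            )
    for o in extra or []:
        rows.append({"set": "nsp", "role": o.role, "name": o.name, "sequence": o.seq})
    # the BP is universal: keep its first occurrence only
    seen: set[str] = set()
    out = []
    for r in rows:
        key = f"{r['role']}:{r['sequence']}"
        if r["role"] == "BP" and key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def write_primer_tsv(rows: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["set", "role", "name", "sequence"], delimiter="\t"
        )
        w.writeheader()
        w.writerows(rows)


def read_primer_tsv(path: str | Path) -> list[Oligo]:
    """Read a primer sheet back into oligos."""
    oligos = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            oligos.append(Oligo(row["name"], row["sequence"], row["role"]))
    return oligos


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
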