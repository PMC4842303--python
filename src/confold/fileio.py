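"""File input/output: FASTA with inline constraints, result writers.

The FASTA dialect used by constraint-aware folding tools allows a record
to carry a third "line" of pseudo-dot-bracket constraint characters after
the sequence; standard FASTA readers would merge it into the sequence, so
a small dedicated parser is used.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from . import __version__
from .energy_model import Sequence
from .structure import dotbracket_to_pairs, pairs_to_dotbracket

_CONSTRAINT_CHARS = set("<>.|()x")
_SEQ_CHARS = set("ACGUTacgut")


@dataclass
class FastaRecord:
    id: str
    seq: Sequence
    constraint: str | None = None


def read_fasta(source: str | TextIO) -> list[FastaRecord]:
    """Read FASTA records; T -> U, lowercase uppercased.

    A trailing non-sequence line made of pseudo-dot-bracket characters is
    captured as the record's inline constraint string.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_fasta(fh)
    records: list[FastaRecord] = []
    rec_id: str | None = None
    seq_parts: list[str] = []
    constraint: str | None = None

    def flush() -> None:
        nonlocal rec_id, seq_parts, constraint
        if rec_id is None:
            return
        if not seq_parts:
            raise ValueError(f"record {rec_id!r}: no sequence")
        try:
            seq = Sequence("".join(seq_parts))
        except ValueError as exc:
            raise ValueError(f"record {rec_id!r}: {exc}") from exc
        if constraint is not None and len(constraint) != len(seq):
            raise ValueError(
                f"record {rec_id!r}: constraint length {len(constraint)} != "
                f"sequence length {len(seq)}"
            )
        records.append(FastaRecord(rec_id, seq, constraint))
        rec_id, seq_parts, constraint = None, [], None

    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rec_id = line[1:].split()[0] if len(line) > 1 else ""
        elif rec_id is None:
            raise ValueError("sequence data before first FASTA header")
        elif set(line) <= _SEQ_CHARS and constraint is None:
            seq_parts.append(line)
        elif set(line) <= _CONSTRAINT_CHARS:
            if constraint is not None:
                raise ValueError(f"record {rec_id!r}: multiple constraint lines")
            constraint = line
        else:
            bad = sorted(set(line) - _SEQ_CHARS)
            raise ValueError(f"record {rec_id!r}: invalid characters {bad}")
    flush()
    return records


def constraint_digest(*parts: str | None) -> str:
    """Short stable digest of all constraint inputs, for output headers."""
    h = hashlib.sha256()
    for p in parts:
        h.update((p or "").encode())
        h.update(b"\x00")
    return h.hexdigest()[:12]


def result_header(seed: int | None, digest: str) -> str:
    return (f"# confold {__version__} seed={'-' if seed is None else seed} "
            f"constraints={digest}")


def write_mfe(out: TextIO, rec: FastaRecord, structure: str, energy: float,
              seed: int | None, digest: str) -> None:
    out.write(result_header(seed, digest) + "\n")
    out.write(f">{rec.id}\n{rec.seq}\n{structure} {energy:.2f}\n")


def write_pf(out: TextIO, rec: FastaRecord, free_energy: float, bpp,
             seed: int | None, digest: str, min_p: float = 1e-6) -> None:
    """Ensemble free energy -RT ln Z plus a plain-text bpp table."""
    out.write(result_header(seed, digest) + "\n")
    out.write(f">{rec.id}\n{rec.seq}\n")
    out.write(f"ensemble_free_energy {free_energy:.6f}\n")
    n = len(rec.seq)
    out.write("i j p_ij\n")
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            p = float(bpp[i, j])
            if p >= min_p:
                out.write(f"{i} {j} {p:.6g}\n")


def write_samples(out: TextIO, rec: FastaRecord, samples: Iterable[str],
                  seed: int | None, digest: str) -> None:
    out.write(result_header(seed, digest) + "\n")
    out.write(f">{rec.id}\n{rec.seq}\n")
    for s in samples:
        out.write(s + "\n")


def write_count(out: TextIO, rec: FastaRecord, count: int,
                seed: int | None, digest: str) -> None:
    out.write(result_header(seed, digest) + "\n")
    out.write(f">{rec.id}\n{rec.seq}\n{count}\n")
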