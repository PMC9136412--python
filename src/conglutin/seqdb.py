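"""Protein search-space construction: FASTA I/O, six-frame ORF prediction, deduplication.

The database builder is intentionally small: it takes transcript and/or
protein FASTA files, predicts ORFs above a length cutoff, and removes
exact-sequence duplicates.  Appending external repositories is left to
upstream concatenation of FASTA files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio.Seq import Seq

_AA_RE = re.compile(r"^[A-Z*]+$")
_NT_RE = re.compile(r"^[ACGTN]+$")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One nucleotide transcript over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for transcript {self.id!r}")
        if not _NT_RE.match(self.sequence.upper()):
            bad = sorted(set(self.sequence.upper()) - set("ACGTN"))
            raise ValueError(
                f"transcript {self.id!r} contains non-nucleotide characters: {bad}"
            )


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Tolerates wrapped or unwrapped sequence lines and Windows line endings;
    residues are normalised to uppercase.  A sequence line appearing before
    the first header raises :class:`FastaParseError` with its line number.
    """
    records: list[ProteinRecord] = []
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def flush(line_number: int) -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {cur_id!r} has no sequence", line_number)
        records.append(ProteinRecord(cur_id, seq.upper(), cur_desc))

    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        "sequence data before first '>' header", lineno
                    )
                chunks.append(line.strip())
        flush(lineno if records or cur_id else 0)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


class OrfCandidate(NamedTuple):
    strand: str
    frame: int  # 1-based frame index on the given strand
    start_nt: int  # 1-based position of the ATG on the strand scanned
    coding_nt: int  # coding length excluding the stop codon


def predict_orfs(
    transcript: TranscriptRecord,
    min_nt: int = 150,
    longest_per_stop: bool = True,
) -> list[ProteinRecord]:
    """Predict ATG-to-stop ORFs in all six reading frames.

    The coding length is counted on the coding sequence *excluding* the stop
    codon and compared against ``min_nt``.  By default only the longest ORF
    per stop codon per frame (the first ATG after the previous stop) is
    reported; set ``longest_per_stop=False`` to emit every internal ATG.
    ORFs containing ``N`` are skipped.
    """
    seq = transcript.sequence.upper()
    out: list[ProteinRecord] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            starts: list[int] = []  # codon indices of pending ATGs
            for ci, codon in enumerate(codons):
                if codon == "ATG":
                    starts.append(ci)
                elif codon in STOP_CODONS:
                    chosen = starts[:1] if longest_per_stop else starts
                    for start_ci in chosen:
                        coding = codons[start_ci:ci]
                        coding_nt = 3 * len(coding)
                        if coding_nt < min_nt:
                            continue
                        cds = "".join(coding)
                        if "N" in cds:
                            continue
                        aa = str(Seq(cds).translate())
                        start_nt = frame + 3 * start_ci + 1
                        rid = f"{transcript.id}|{strand}{frame + 1}|{start_nt}"
                        desc = (
                            f"strand={strand} frame={frame + 1} "
                            f"start_nt={start_nt} coding_nt={coding_nt}"
                        )
                        out.append(ProteinRecord(rid, aa, desc))
                    starts = []
    return out


@dataclass
class DedupeResult:
    records: list[ProteinRecord]
    n_removed: int
    removed_ids: list[str] = field(default_factory=list)


def dedupe(records: Iterable[ProteinRecord]) -> DedupeResult:
    """Remove exact-sequence duplicates, keeping the first-seen id.

    The key is the exact residue string; no alignment is attempted.
    """
    seen: set[str] = set()
    kept: list[ProteinRecord] = []
    removed: list[str] = []
    for rec in records:
        if rec.sequence in seen:
            removed.append(rec.id)
        else:
            seen.add(rec.sequence)
            kept.append(rec)
    return DedupeResult(kept, len(removed), removed)
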