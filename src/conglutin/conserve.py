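"""Discovery-peptide filtering, cross-accession presence and conservation mapping.

Observation tables are tab-separated with columns
``accession, peptide, modifications, confidence, protein_id``; the
modifications cell is a semicolon-separated list of ``Name(site)`` entries
(empty for an unmodified peptide).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

OBSERVATION_COLUMNS = ["accession", "peptide", "modifications", "confidence", "protein_id"]

#: modifications that do not disqualify a peptide
ALLOWED_MODIFICATIONS = frozenset(
    {"Carbamidomethyl(C)", "Oxidation(M)", "Gln->pyro-Glu(N-term)"}
)

_MOD_RE = re.compile(r"^[A-Za-z0-9><\- ]+\([A-Za-z\-]+\)$")

#: identification-frequency classes over 46 accessions.  The published
#: "26-35" / "35-40" pair overlaps at 35; the partition used here corrects
#: the second bin to 36-40 so the classes are disjoint.
DEFAULT_FREQUENCY_CLASSES: tuple[tuple[int, int], ...] = (
    (1, 5),
    (6, 15),
    (16, 25),
    (26, 35),
    (36, 40),
    (41, 46),
)


@dataclass(frozen=True)
class FrequencyClass:
    low: int
    high: int

    @property
    def label(self) -> str:
        return f"{self.low}-{self.high}"

    def __contains__(self, count: int) -> bool:
        return self.low <= count <= self.high


def frequency_classes(
    bounds: tuple[tuple[int, int], ...] = DEFAULT_FREQUENCY_CLASSES,
    n_accessions: int = 46,
) -> list[FrequencyClass]:
    classes = [FrequencyClass(lo, hi) for lo, hi in bounds]
    prev_hi = 0
    for fc in classes:
        if fc.low != prev_hi + 1:
            raise ValueError("frequency classes must partition 1..n without gaps")
        prev_hi = fc.high
    if prev_hi != n_accessions:
        raise ValueError("last class must end at n_accessions")
    return classes


def assign_frequency_class(count: int, n_accessions: int = 46) -> FrequencyClass:
    """Return the identification-frequency class containing ``count``."""
    if not 1 <= count <= n_accessions:
        raise ValueError(f"count must be in 1..{n_accessions}, got {count}")
    for fc in frequency_classes(n_accessions=n_accessions):
        if count in fc:
            return fc
    raise AssertionError("unreachable: classes partition the range")


def parse_modifications(cell: str) -> list[str]:
    """Split a modifications cell into normalised ``Name(site)`` entries.

    Raises ``ValueError`` on entries that do not look like ``Name(site)``.
    """
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    cell = str(cell).strip()
    if not cell:
        return []
    mods = []
    for entry in cell.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        if not _MOD_RE.match(entry):
            raise ValueError(f"unparseable modification entry {entry!r}")
        mods.append(entry)
    return mods


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_disallowed_modification: int
    n_low_confidence: int
    n_bad_syntax: int


def filter_observations(
    obs: pd.DataFrame,
    allowed_mods: frozenset[str] = ALLOWED_MODIFICATIONS,
    min_confidence: float = 0.99,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows with disallowed modifications or low confidence.

    ``min_confidence`` defaults to 0.99, the row-level stand-in for a 1%
    identification FDR; if the table carries an ``fdr`` column an explicit
    upstream filter can be applied by the caller instead.  Rows whose
    modification cell cannot be parsed are rejected with a warning.
    """
    keep = []
    n_mod = n_conf = n_syntax = 0
    for idx, row in obs.iterrows():
        try:
            mods = parse_modifications(row["modifications"])
        except ValueError as exc:
            warnings.warn(f"rejecting row {idx}: {exc}")
            n_syntax += 1
            continue
        if any(m not in allowed_mods for m in mods):
            n_mod += 1
            continue
        if float(row["confidence"]) < min_confidence:
            n_conf += 1
            continue
        keep.append(idx)
    out = obs.loc[keep].copy()
    return out, FilterReport(len(obs), len(out), n_mod, n_conf, n_syntax)


def is_fully_tryptic(peptide: str, parent: str) -> bool:
    """True iff the peptide occurs in the parent bounded by tryptic sites.

    N-terminal rule: protein start, or preceded by K/R with the peptide not
    starting with P.  C-terminal rule: protein end, or the peptide ends in
    K/R and the following parent residue is not P.  Any qualifying
    occurrence suffices.
    """
    if not peptide:
        return False
    start = parent.find(peptide)
    while start != -1:
        end = start + len(peptide)
        n_ok = start == 0 or (parent[start - 1] in "KR" and peptide[0] != "P")
        c_ok = end == len(parent) or (peptide[-1] in "KR" and parent[end] != "P")
        if n_ok and c_ok:
            return True
        start = parent.find(peptide, start + 1)
    return False


def presence_matrix(obs: pd.DataFrame, accessions: list[str]) -> pd.DataFrame:
    """Peptide x accession boolean matrix (modifications collapsed)."""
    unknown = set(obs["accession"]) - set(accessions)
    if unknown:
        raise ValueError(f"observations reference accessions outside the panel: {sorted(unknown)}")
    peptides = sorted(set(obs["peptide"]))
    mat = pd.DataFrame(False, index=peptides, columns=list(accessions))
    for _, row in obs.iterrows():
        mat.at[row["peptide"], row["accession"]] = True
    return mat


def class_counts(presence: pd.DataFrame, n_accessions: int | None = None) -> pd.Series:
    """Count detected peptides per identification-frequency class."""
    n = n_accessions or presence.shape[1]
    labels = [fc.label for fc in frequency_classes(n_accessions=n)]
    counts = pd.Series(0, index=labels, dtype=int)
    for _, row in presence.iterrows():
        c = int(row.sum())
        if c == 0:
            continue
        counts[assign_frequency_class(c, n).label] += 1
    return counts


def class_percentages(counts: pd.Series | dict[str, int]) -> pd.Series:
    """Percent of detected peptides per class, rounded to the nearest integer."""
    s = pd.Series(counts, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("no detected peptides")
    return (100.0 * s / total).round(0).astype(int)


@dataclass(frozen=True)
class CoverageInterval:
    reference: str
    start: int  # 1-based inclusive
    end: int
    peptide: str
    frequency_class: str


def map_to_references(
    peptides: dict[str, str],
    refs: list,
) -> list[CoverageInterval]:
    """Map peptides (sequence -> class label) onto reference sequences by
    exact substring identity; all occurrences in all references reported."""
    out: list[CoverageInterval] = []
    for ref in refs:
        seq = ref.sequence
        for pep, label in sorted(peptides.items()):
            start = seq.find(pep)
            while start != -1:
                out.append(
                    CoverageInterval(ref.id, start + 1, start + len(pep), pep, label)
                )
                start = seq.find(pep, start + 1)
    return out


def coverage_to_bed(intervals: list[CoverageInterval]) -> pd.DataFrame:
    """BED-like export: 0-based half-open start, 1-based end."""
    return pd.DataFrame(
        [
            {
                "reference": iv.reference,
                "start": iv.start - 1,
                "end": iv.end,
                "peptide": iv.peptide,
                "class": iv.frequency_class,
            }
            for iv in intervals
        ],
        columns=["reference", "start", "end", "peptide", "class"],
    )


def residue_coverage(intervals: list[CoverageInterval], ref_lengths: dict[str, int]) -> pd.Series:
    """Fraction of residues of each reference covered by >=1 mapped peptide."""
    cov = {}
    for ref_id, length in ref_lengths.items():
        mask = [False] * length
        for iv in intervals:
            if iv.reference == ref_id:
                for i in range(iv.start - 1, iv.end):
                    mask[i] = True
        cov[ref_id] = sum(mask) / length
    return pd.Series(cov)
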