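"""In-silico tryptic digestion, peptide specificity and MRM marker selection.

Marker peptides pass five gates, in order: (1) specific to a target protein
or protein group against the background proteome; (2) fully tryptic;
(3) identification confidence >= threshold; (4) only permitted
modifications; (5) signal-to-noise > threshold.  Survivors are ranked per
target by technical CV (ascending) then median intensity (descending).
Fragment-ion m/z values are out of scope: transitions are labelled
channels supplied with the marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .conserve import ALLOWED_MODIFICATIONS, is_fully_tryptic
from .seqdb import ProteinRecord


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    parent_id: str
    start: int  # 1-based inclusive
    end: int
    missed_cleavages: int


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1
    (after K/R, suppressed before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord | str,
    max_missed: int = 1,
    min_len: int = 8,
    max_len: int = 30,
) -> list[DigestPeptide]:
    """Tryptic digestion with missed cleavages and a length window."""
    if isinstance(protein, str):
        if not protein:
            return []
        protein = ProteinRecord("protein", protein)
    seq = protein.sequence
    cuts = cleavage_sites(seq)
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    frags = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    out: list[DigestPeptide] = []
    for i in range(len(frags)):
        for mc in range(max_missed + 1):
            j = i + mc
            if j >= len(frags):
                break
            start, end = frags[i][0], frags[j][1]
            if min_len <= end - start <= max_len:
                out.append(
                    DigestPeptide(seq[start:end], protein.id, start + 1, end, mc)
                )
    return out


# ---------------------------------------------------------------------------
# specificity against a background proteome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecificityResult:
    status: str  # "unique" | "group" | "nonspecific" | "absent"
    proteins: tuple[str, ...]  # background proteins carrying the peptide

    @property
    def target_label(self) -> str:
        if self.status == "unique":
            return self.proteins[0]
        if self.status == "group":
            return "+".join(self.proteins)
        return ""


def peptide_specificity(
    peptide: str,
    background: Iterable[ProteinRecord],
    targets: set[str],
) -> SpecificityResult:
    """Classify a peptide against the background proteome.

    A peptide maps to every background protein containing it as a fully
    tryptic substring.  One target parent -> unique; several parents, all
    targets -> protein group; any non-target parent -> nonspecific; no
    parent -> absent.
    """
    parents = tuple(
        sorted(
            rec.id
            for rec in background
            if peptide in rec.sequence and is_fully_tryptic(peptide, rec.sequence)
        )
    )
    if not parents:
        return SpecificityResult("absent", ())
    if any(p not in targets for p in parents):
        return SpecificityResult("nonspecific", parents)
    if len(parents) == 1:
        return SpecificityResult("unique", parents)
    return SpecificityResult("group", parents)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

#: candidate table columns expected by :func:`select_markers`
CANDIDATE_COLUMNS = [
    "peptide",
    "target",          # protein id or '+'-joined protein group; '' if nonspecific
    "specific",        # bool: gate 1
    "fully_tryptic",   # bool: gate 2
    "confidence",      # float: gate 3
    "mods_allowed",    # bool: gate 4
    "s2n",             # float: gate 5
    "median_intensity",
    "cv_percent",
]


@dataclass(frozen=True)
class MarkerPeptide:
    sequence: str
    target: str
    median_intensity: float
    cv_percent: float
    s2n: float
    n_transitions: int = 3

    def __post_init__(self) -> None:
        if self.n_transitions < 3:
            raise ValueError("marker peptides need at least 3 transitions")
        if not self.target:
            raise ValueError("marker target must be non-empty")


@dataclass
class SelectionReport:
    markers: list[MarkerPeptide]
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (peptide, reason)
    empty_targets: list[str] = field(default_factory=list)

    def per_target_counts(self) -> pd.Series:
        return pd.Series([m.target for m in self.markers]).value_counts().sort_index()

    def high_cv_peptides(self, cv_threshold: float = 13.0) -> list[str]:
        """Markers whose technical CV exceeds the threshold (report only)."""
        return [m.sequence for m in self.markers if m.cv_percent >= cv_threshold]


def select_markers(
    candidates: pd.DataFrame,
    s2n_min: float = 5.0,
    confidence_min: float = 0.95,
    cv_max: float = 20.0,
    top_k: int = 8,
) -> SelectionReport:
    """Apply the five marker gates in order, then rank per target.

    Survivors of the gates are sorted per target by CV ascending, then
    median intensity descending, and the ``top_k`` best are retained.
    Every rejection is logged with the first gate that failed.
    """
    missing = [c for c in CANDIDATE_COLUMNS if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    rejections: list[tuple[str, str]] = []
    survivors: list[dict] = []
    for _, row in candidates.iterrows():
        pep = row["peptide"]
        if not bool(row["specific"]) or not row["target"]:
            rejections.append((pep, "gate1: not specific to a target or group"))
        elif not bool(row["fully_tryptic"]):
            rejections.append((pep, "gate2: not fully tryptic"))
        elif float(row["confidence"]) < confidence_min:
            rejections.append((pep, f"gate3: confidence < {confidence_min}"))
        elif not bool(row["mods_allowed"]):
            rejections.append((pep, "gate4: disallowed modification"))
        elif float(row["s2n"]) <= s2n_min:
            rejections.append((pep, f"gate5: S/N <= {s2n_min}"))
        elif float(row["cv_percent"]) > cv_max:
            rejections.append((pep, f"cv: technical CV > {cv_max}%"))
        else:
            survivors.append(row.to_dict())

    markers: list[MarkerPeptide] = []
    empty: list[str] = []
    by_target: dict[str, list[dict]] = {}
    for row in survivors:
        by_target.setdefault(row["target"], []).append(row)
    for target in sorted(set(candidates["target"]) - {""}):
        rows = by_target.get(target, [])
        if not rows:
            empty.append(target)
            continue
        rows.sort(key=lambda r: (float(r["cv_percent"]), -float(r["median_intensity"])))
        for row in rows[:top_k]:
            markers.append(
                MarkerPeptide(
                    row["peptide"],
                    row["target"],
                    float(row["median_intensity"]),
                    float(row["cv_percent"]),
                    float(row["s2n"]),
                    int(row.get("n_transitions", 3)),
                )
            )
        for row in rows[top_k:]:
            rejections.append((row["peptide"], f"rank: beyond top {top_k} for {target}"))
    return SelectionReport(markers, rejections, empty)


def total_marker_count(per_family_counts: dict[str, int] | pd.Series) -> int:
    """Sum of per-family marker counts (selection-report aggregation)."""
    return int(sum(per_family_counts.values()) if isinstance(per_family_counts, dict) else per_family_counts.sum())


# ---------------------------------------------------------------------------
# transition-list export
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = [
    "peptide",
    "target",
    "transition",
    "rt_min",
    "window_start_min",
    "window_end_min",
]


def build_transition_table(
    markers: Sequence[MarkerPeptide],
    transitions: dict[str, tuple[float, list[str]]],
    min_transitions: int = 3,
    schedule_window_s: float = 60.0,
) -> tuple[pd.DataFrame, list[str]]:
    """One row per monitored transition, scheduled around the expected RT.

    ``transitions`` maps peptide sequence -> (retention time in minutes,
    transition labels).  Markers with fewer than ``min_transitions``
    channels are excluded and returned in the second element.
    """
    rows = []
    excluded: list[str] = []
    half = schedule_window_s / 60.0 / 2.0
    for m in markers:
        if m.sequence not in transitions:
            excluded.append(m.sequence)
            continue
        rt, labels = transitions[m.sequence]
        if len(labels) < min_transitions:
            excluded.append(m.sequence)
            continue
        for lab in labels:
            rows.append(
                {
                    "peptide": m.sequence,
                    "target": m.target,
                    "transition": lab,
                    "rt_min": rt,
                    "window_start_min": rt - half,
                    "window_end_min": rt + half,
                }
            )
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS), excluded
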