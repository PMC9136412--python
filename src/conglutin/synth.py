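"""Synthetic input generators with known ground truth.

Every input the pipeline consumes can be generated here: a 16-member
reference set with the family-diagnostic structural features, candidate
databases with planted variants / decoys / duplicates, per-accession
identification tables with controlled presence frequencies, and MRM-style
abundance matrices with genotype effects, a two-batch offset, injection
order drift and replicate noise at a target CV.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import (
    FAMILY_DOMAIN_WINDOWS,
    SUBFAMILY_COUNTS,
    DomainWindow,
    ReferenceConglutin,
    family_of,
)
from .assay import digest
from .conserve import frequency_classes
from .quant import AbundanceMatrix
from .seqdb import ProteinRecord

# residue alphabet without cysteine; cysteines are planted explicitly so
# that each family's skeleton is exact
_ALPHABET = "ADEFGHIKLMNPQRSTVWY"
# rough globular-protein residue weights (K/R kept high enough that tryptic
# fragments in the 8-30 aa window are plentiful)
_WEIGHTS = np.array(
    [8.3, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 9.7, 2.4, 4.1, 2.9, 4.0, 5.3, 5.6, 6.6, 5.4, 6.9, 1.1, 3.0]
)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

REFERENCE_LENGTHS = {"alpha": 560, "beta": 560, "delta": 150, "gamma": 450}

#: planted cysteine positions (1-based) satisfying each family's skeleton
_CYS_POSITIONS = {
    "alpha": (220, 231, 370, 379),  # two CXnC pairs between the cupin windows
    "beta": (),
    # gaps 5,7,0,6,1,7,9,7 -> satisfies [>=1,>=1,=0,>=1,=1,>=1,>=1,>=1]
    "delta": (30, 36, 44, 45, 52, 54, 62, 72, 80),
    "gamma": (15, 20, 30, 38),  # cystine-rich region before TAXi_N at 62
}

_DELTA2_DOMAIN = ("tryp_alpha_amyl", 20, 130)


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    idx = rng.choice(len(_ALPHABET), size=length, p=_WEIGHTS)
    return [_ALPHABET[i] for i in idx]


def _domain_windows_for(subfamily: str) -> tuple[DomainWindow, ...]:
    fam = family_of(subfamily)
    wins = [DomainWindow(n, s, e) for n, s, e in FAMILY_DOMAIN_WINDOWS.get(fam, [])]
    if subfamily == "delta2":
        wins.append(DomainWindow(*_DELTA2_DOMAIN))
    return tuple(wins)


def generate_reference_set(seed: int) -> tuple[list[ReferenceConglutin], pd.DataFrame]:
    """Sixteen synthetic reference conglutins (3 alpha, 7 beta, 4 delta,
    2 gamma) plus their domain-annotation table.

    Alpha and gamma references carry CXnC cysteine pairs, beta references
    contain no cysteine at all, and delta references carry the 9-cysteine
    prolamin-type skeleton.
    """
    rng = np.random.default_rng(seed)
    refs: list[ReferenceConglutin] = []
    rows = []
    for fam in ("alpha", "beta", "delta", "gamma"):
        for i in range(1, SUBFAMILY_COUNTS[fam] + 1):
            sub = f"{fam}{i}"
            seq = _random_sequence(rng, REFERENCE_LENGTHS[fam])
            for pos in _CYS_POSITIONS[fam]:
                seq[pos - 1] = "C"
            domains = _domain_windows_for(sub)
            refs.append(ReferenceConglutin(sub, "".join(seq), domains))
            for dom in domains:
                rows.append(
                    {"subfamily": sub, "domain": dom.name, "start": dom.start, "end": dom.end}
                )
    return refs, pd.DataFrame(rows, columns=["subfamily", "domain", "start", "end"])


def references_as_records(refs: list[ReferenceConglutin]) -> list[ProteinRecord]:
    return [ProteinRecord(r.subfamily, r.sequence, f"family={r.family}") for r in refs]


@dataclass
class SyntheticTruth:
    """Ground truth shared by the generators.

    ``family_assignments`` maps planted-candidate id to (family, subfamily);
    ``planted_identity`` records the requested percent identity to the
    source reference; ``suppressed_subfamilies`` maps (accession, subfamily)
    to the suppression factor (fraction of baseline abundance).
    """

    family_assignments: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_identity: dict[str, float] = field(default_factory=dict)
    decoy_ids: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    suppressed_subfamilies: dict[tuple[str, str], float] = field(default_factory=dict)
    batch_offsets: dict[str, float] = field(default_factory=dict)
    replicate_cv: float = 0.0
    presence_matrix: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for key, f in self.suppressed_subfamilies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"suppression factor out of [0,1] for {key}: {f}")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass
class CandidateDB:
    records: list[ProteinRecord]
    domains: dict[str, list[DomainWindow]]
    truth: SyntheticTruth


def generate_candidate_db(
    refs: list[ReferenceConglutin],
    n_variants: int = 16,
    n_decoys: int = 8,
    n_duplicates: int = 2,
    seed: int = 0,
    identity: float = 90.0,
) -> CandidateDB:
    """Candidate database of planted variants, decoys and exact duplicates.

    Variants are point-mutated reference copies at the requested identity;
    positions outside cysteines and outside domain windows are mutated
    first so structural features survive.  Decoys are residue-frequency
    matched random sequences rejection-sampled below 70% identity to every
    reference.  Duplicates are exact copies of already-emitted entries.
    """
    from .align import pairwise_identity  # local import to avoid cycles

    if not 0.0 <= identity <= 100.0:
        raise ValueError("identity must be in [0, 100]")
    if min(n_variants, n_decoys, n_duplicates) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    records: list[ProteinRecord] = []
    domains: dict[str, list[DomainWindow]] = {}

    for v in range(n_variants):
        ref = refs[v % len(refs)]
        seq = list(ref.sequence)
        L = len(seq)
        k = int(round(L * (1.0 - identity / 100.0)))
        in_window = np.zeros(L, dtype=bool)
        for dom in ref.domains:
            in_window[dom.start - 1 : dom.end] = True
        cys = np.array([c == "C" for c in seq])
        outside = np.flatnonzero(~in_window & ~cys)
        inside = np.flatnonzero(in_window & ~cys)
        picks = list(rng.permutation(outside)[:k])
        if len(picks) < k:
            picks += list(rng.permutation(inside)[: k - len(picks)])
        for pos in picks:
            old = seq[pos]
            choices = [c for c in _ALPHABET if c != old]
            seq[pos] = choices[rng.integers(len(choices))]
        vid = f"var{v + 1}_{ref.subfamily}"
        records.append(ProteinRecord(vid, "".join(seq), f"variant of {ref.subfamily}"))
        domains[vid] = list(ref.domains)
        truth.family_assignments[vid] = (ref.family, ref.subfamily)
        truth.planted_identity[vid] = identity

    # residue frequencies pooled over the references, for decoy composition
    pooled = "".join(r.sequence for r in refs)
    letters = sorted(set(pooled))
    freqs = np.array([pooled.count(c) for c in letters], dtype=float)
    freqs /= freqs.sum()
    for dnum in range(n_decoys):
        ref = refs[int(rng.integers(len(refs)))]
        for _ in range(100):
            idx = rng.choice(len(letters), size=len(ref.sequence), p=freqs)
            seq = "".join(letters[i] for i in idx)
            if max(pairwise_identity(seq, r.sequence) for r in refs) < 70.0:
                break
        else:  # pragma: no cover - effectively unreachable
            raise RuntimeError("could not sample a decoy below 70% identity")
        did = f"decoy{dnum + 1}"
        records.append(ProteinRecord(did, seq, "decoy"))
        truth.decoy_ids.append(did)

    base = list(records)
    for dup in range(n_duplicates):
        src = base[int(rng.integers(len(base)))] if base else None
        if src is None:
            break
        did = f"dup{dup + 1}_of_{src.id}"
        records.append(ProteinRecord(did, src.sequence, f"duplicate of {src.id}"))
        truth.duplicate_ids.append(did)
        if src.id in domains:
            domains[did] = list(domains[src.id])
    return CandidateDB(records, domains, truth)


# ---------------------------------------------------------------------------
# identification tables
# ---------------------------------------------------------------------------


def accession_panel(n_domesticated: int = 15, n_wild: int = 31) -> list[str]:
    """Default panel of 46 accession ids (15 domesticated + 31 wild)."""
    return [f"D{i}" for i in range(1, n_domesticated + 1)] + [
        f"W{i}" for i in range(1, n_wild + 1)
    ]


def design_peptide_classes(
    refs: list[ReferenceConglutin],
    n_per_class: int,
    seed: int,
    n_accessions: int = 46,
) -> dict[str, str]:
    """Sample distinct reference tryptic peptides and assign each a target
    identification-frequency class, ``n_per_class`` peptides per class."""
    rng = np.random.default_rng(seed)
    pool = sorted(
        {
            p.sequence
            for ref in refs
            for p in digest(ProteinRecord(ref.subfamily, ref.sequence), max_missed=0)
        }
    )
    labels = [fc.label for fc in frequency_classes(n_accessions=n_accessions)]
    need = n_per_class * len(labels)
    if need > len(pool):
        raise ValueError(f"only {len(pool)} distinct tryptic peptides available, need {need}")
    chosen = rng.permutation(len(pool))[:need]
    design: dict[str, str] = {}
    for i, pidx in enumerate(chosen):
        design[pool[pidx]] = labels[i // n_per_class]
    return design


def generate_identification_tables(
    refs: list[ReferenceConglutin],
    accessions: list[str],
    class_design: dict[str, str],
    seed: int,
    n_low_confidence: int = 5,
    n_bad_modification: int = 5,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-accession identification tables with controlled presence.

    Each designed peptide appears in a number of accessions drawn
    uniformly from its class interval, with passing confidence and allowed
    modifications.  Extra junk rows carry confidences below 0.95 or a
    disallowed ``Phospho(S)`` modification, so downstream filters are
    exercised.
    """
    rng = np.random.default_rng(seed)
    parent_of = {}
    for pep in class_design:
        parent_of[pep] = next(
            (r.subfamily for r in refs if pep in r.sequence), "unknown"
        )
    presence = pd.DataFrame(False, index=sorted(class_design), columns=list(accessions))
    rows: list[dict] = []
    for pep in sorted(class_design):
        lo, hi = (int(x) for x in class_design[pep].split("-"))
        hi = min(hi, len(accessions))
        n_present = int(rng.integers(lo, hi + 1))
        where = rng.choice(len(accessions), size=n_present, replace=False)
        for ai in sorted(where):
            acc = accessions[ai]
            presence.at[pep, acc] = True
            mod = ""
            if "M" in pep and rng.random() < 0.2:
                mod = "Oxidation(M)"
            rows.append(
                {
                    "accession": acc,
                    "peptide": pep,
                    "modifications": mod,
                    "confidence": float(np.round(rng.uniform(0.99, 1.0), 4)),
                    "protein_id": parent_of[pep],
                }
            )
    # junk rows that the filters must remove
    junk_pool = sorted(class_design)
    for j in range(n_low_confidence):
        pep = junk_pool[int(rng.integers(len(junk_pool)))]
        acc = accessions[int(rng.integers(len(accessions)))]
        rows.append(
            {
                "accession": acc,
                "peptide": pep,
                "modifications": "",
                "confidence": float(np.round(rng.uniform(0.80, 0.945), 4)),
                "protein_id": parent_of[pep],
            }
        )
    for j in range(n_bad_modification):
        pep = junk_pool[int(rng.integers(len(junk_pool)))]
        acc = accessions[int(rng.integers(len(accessions)))]
        rows.append(
            {
                "accession": acc,
                "peptide": pep,
                "modifications": "Phospho(S)",
                "confidence": float(np.round(rng.uniform(0.99, 1.0), 4)),
                "protein_id": parent_of[pep],
            }
        )
    table = pd.DataFrame(rows)
    tables = {
        acc: table[table["accession"] == acc].reset_index(drop=True)
        for acc in accessions
    }
    truth = SyntheticTruth(presence_matrix=presence)
    return tables, truth


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------


def _label_subfamilies(label: str) -> list[str]:
    """Expand a subfamily or group label: 'beta4+6' -> ['beta4', 'beta6']."""
    parts = label.split("+")
    fam = family_of(parts[0])
    out = [parts[0]]
    for extra in parts[1:]:
        out.append(extra if extra.startswith(fam) else fam + extra)
    return out


def sigma_ln_for_cv(cv_percent: float) -> float:
    """Log-normal sigma giving a linear-scale CV of ``cv_percent``."""
    cv = cv_percent / 100.0
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_abundance_matrix(
    marker_map: dict[str, str],
    accessions: list[str],
    seed: int,
    replicate_cv: float = 10.0,
    batch_offsets: tuple[float, float] = (0.0, 0.3),
    drift_per_run: float = 0.0,
    suppression: dict[tuple[str, str], float] | None = None,
    n_replicates: int = 3,
    baseline_range: tuple[float, float] = (5.0, 7.0),
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """MRM-style peak-area matrix with a planted design.

    log10(area) = peptide baseline + suppression + batch offset + linear
    injection-order drift + replicate noise; noise is multiplicative
    log-normal with sigma chosen so the linear-scale CV equals
    ``replicate_cv``.  Suppressed (accession, subfamily) pairs have their
    linear baseline scaled by the suppression factor.
    """
    if suppression is None:
        suppression = {}
    rng = np.random.default_rng(seed)
    peptides = sorted(marker_map)
    baselines = {p: rng.uniform(*baseline_range) for p in peptides}
    batches = ["B1", "B2"]
    half = (len(accessions) + 1) // 2
    batch_of = {a: batches[0] if i < half else batches[1] for i, a in enumerate(accessions)}
    offsets = dict(zip(batches, batch_offsets))

    runs = [(a, r) for a in accessions for r in range(1, n_replicates + 1)]
    inj = rng.permutation(len(runs)) + 1
    sigma = sigma_ln_for_cv(replicate_cv)

    rows = []
    for (acc, rep), order in zip(runs, inj):
        batch = batch_of[acc]
        for pep in peptides:
            logv = baselines[pep]
            for sub in _label_subfamilies(marker_map[pep]):
                factor = suppression.get((acc, sub))
                if factor is not None:
                    logv += np.log10(factor) if factor > 0 else -12.0
                    break
            logv += offsets[batch] + drift_per_run * order
            noise = rng.normal(0.0, sigma) / np.log(10.0) if sigma > 0 else 0.0
            rows.append(
                {
                    "peptide": pep,
                    "accession": acc,
                    "replicate": rep,
                    "batch": batch,
                    "injection_order": int(order),
                    "area": 10.0 ** (logv + noise),
                }
            )
    matrix = AbundanceMatrix.from_long(pd.DataFrame(rows))
    truth = SyntheticTruth(
        suppressed_subfamilies=dict(suppression),
        batch_offsets=offsets,
        replicate_cv=replicate_cv,
    )
    return matrix, truth


def default_marker_map(
    refs: list[ReferenceConglutin], per_subfamily: int = 2, seed: int = 0
) -> dict[str, str]:
    """A simple marker panel: ``per_subfamily`` unique tryptic peptides per
    reference subfamily, keyed by peptide sequence."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    counts: dict[str, int] = {}
    for ref in refs:
        for p in digest(ProteinRecord(ref.subfamily, ref.sequence), max_missed=0):
            counts[p.sequence] = counts.get(p.sequence, 0) + 1
    marker_map: dict[str, str] = {}
    for ref in refs:
        peps = sorted(
            {
                p.sequence
                for p in digest(ProteinRecord(ref.subfamily, ref.sequence), max_missed=0)
                if counts[p.sequence] == 1 and p.sequence not in seen
            }
        )
        picks = rng.permutation(len(peps))[:per_subfamily]
        for i in picks:
            marker_map[peps[i]] = ref.subfamily
            seen.add(peps[i])
    return marker_map
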