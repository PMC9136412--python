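"""Conglutin isoform discovery and structural classification.

Candidates are screened by best percent identity against the 16 reference
conglutins and then validated by family-specific structural rules:
cysteine-skeleton patterns and the positions of annotated Pfam-style
domains relative to the published family windows.  Domain calls are an
*input* (annotation table); this module only checks their positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .align import pairwise_identity
from .seqdb import ProteinRecord

FAMILIES = ("alpha", "beta", "delta", "gamma")

#: number of subfamilies per family (16 in total)
SUBFAMILY_COUNTS = {"alpha": 3, "beta": 7, "delta": 4, "gamma": 2}

SUBFAMILIES = tuple(
    f"{fam}{i}" for fam in FAMILIES for i in range(1, SUBFAMILY_COUNTS[fam] + 1)
)

#: published domain windows (1-based inclusive residue coordinates)
FAMILY_DOMAIN_WINDOWS: dict[str, list[tuple[str, int, int]]] = {
    "alpha": [("cupin_1", 36, 201), ("cupin_1", 405, 552)],
    "beta": [("cupin_1", 180, 330), ("cupin_1", 390, 551)],
    "gamma": [("TAXi_N", 62, 237), ("TAXi_C", 269, 430)],
}


def family_of(subfamily: str) -> str:
    for fam in FAMILIES:
        if subfamily.startswith(fam):
            return fam
    raise ValueError(f"unknown subfamily {subfamily!r}")


@dataclass(frozen=True)
class DomainWindow:
    """An annotated domain placement on a protein."""

    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain window {self.start}-{self.end}")

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start) + 1)


# ---------------------------------------------------------------------------
# cysteine-skeleton patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CysPattern:
    """An ordered cysteine skeleton expressed as inter-cysteine gap constraints.

    ``gap_constraints[k]`` bounds the number of non-cysteine residues between
    the k-th and (k+1)-th cysteine of a run as ``(min, max)``; ``max=None``
    means unbounded.  Adjacent C's have constraint ``(0, 0)``, ``X`` means
    exactly one residue and ``Xn`` one or more.
    """

    gap_constraints: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        if len(self.gap_constraints) < 1:
            raise ValueError("pattern needs at least 2 cysteines")

    @property
    def n_cys(self) -> int:
        return len(self.gap_constraints) + 1

    @classmethod
    def from_string(cls, pattern: str) -> "CysPattern":
        """Parse patterns such as ``CXnCXnCCXnCXCXnCXnCXnC``."""
        tokens: list[str] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "C":
                tokens.append("C")
                i += 1
            elif ch == "X":
                if i + 1 < len(pattern) and pattern[i + 1] == "n":
                    tokens.append("Xn")
                    i += 2
                else:
                    tokens.append("X")
                    i += 1
            else:
                raise ValueError(f"unexpected character {ch!r} in cysteine pattern")
        if tokens.count("C") < 2 or tokens[0] != "C" or tokens[-1] != "C":
            raise ValueError("pattern must start and end with C and contain >=2 C")
        constraints: list[tuple[int, int | None]] = []
        gap_min, unbounded, seen_gap = 0, False, False
        for tok in tokens[1:]:
            if tok == "C":
                constraints.append((gap_min, None if unbounded else gap_min))
                gap_min, unbounded, seen_gap = 0, False, False
            elif tok == "X":
                gap_min += 1
                seen_gap = True
            else:  # Xn
                gap_min += 1
                unbounded = True
                seen_gap = True
        del seen_gap
        return cls(tuple(constraints))

    def to_regex(self, exact: bool = False) -> str:
        """Equivalent regular expression over the plain sequence alphabet."""
        parts = ["C"]
        for lo, hi in self.gap_constraints:
            if hi is None:
                parts.append("[^C]{%d,}" % lo)
            elif hi == 0:
                pass
            else:
                parts.append("[^C]{%d}" % lo)
            parts.append("C")
        core = "".join(parts)
        if exact:
            return r"\A[^C]*" + core + r"[^C]*\Z"
        return core


DELTA_PATTERN = CysPattern.from_string("CXnCXnCCXnCXCXnCXnCXnC")
ALPHA_CYS_PAIR = CysPattern.from_string("CXnC")


@dataclass(frozen=True)
class PatternMatch:
    matched: bool
    positions: tuple[int, ...] = ()  # 1-based cysteine positions of the match


def match_cys_pattern(
    sequence: str, pattern: CysPattern, windowed: bool = True
) -> PatternMatch:
    """Match a cysteine skeleton against a sequence.

    The sequence's cysteine positions are reduced to an inter-cysteine gap
    vector.  In windowed mode (default) a match is reported if *any*
    contiguous run of cysteines satisfies the pattern's gap constraints;
    exact mode requires the full skeleton of the sequence to match.
    """
    cpos = [i for i, ch in enumerate(sequence) if ch == "C"]
    k = pattern.n_cys
    if len(cpos) < k:
        return PatternMatch(False)
    gaps = [cpos[i + 1] - cpos[i] - 1 for i in range(len(cpos) - 1)]

    def run_ok(offset: int) -> bool:
        for (lo, hi), gap in zip(pattern.gap_constraints, gaps[offset : offset + k - 1]):
            if gap < lo or (hi is not None and gap > hi):
                return False
        return True

    if windowed:
        for off in range(len(cpos) - k + 1):
            if run_ok(off):
                return PatternMatch(True, tuple(p + 1 for p in cpos[off : off + k]))
        return PatternMatch(False)
    if len(cpos) != k:
        return PatternMatch(False)
    if run_ok(0):
        return PatternMatch(True, tuple(p + 1 for p in cpos))
    return PatternMatch(False)


# ---------------------------------------------------------------------------
# sequence motifs in the same gap-token grammar (annotation only)
# ---------------------------------------------------------------------------

#: semi-conserved vicilin-like motifs, reported as annotations, never gating
BETA_MOTIFS = ("HYXnR", "QQDEQEXnYXnLS")


def motif_to_regex(motif: str) -> str:
    """Translate a motif in the gap-token grammar (X = any one residue,
    Xn = one or more residues, other letters literal) into a regex."""
    out: list[str] = []
    i = 0
    while i < len(motif):
        if motif[i] == "X":
            if i + 1 < len(motif) and motif[i + 1] == "n":
                out.append(".+")
                i += 2
            else:
                out.append(".")
                i += 1
        else:
            out.append(re.escape(motif[i]))
            i += 1
    return "".join(out)


def annotate_motifs(sequence: str, motifs=BETA_MOTIFS) -> dict[str, bool]:
    return {m: re.search(motif_to_regex(m), sequence) is not None for m in motifs}


# ---------------------------------------------------------------------------
# reference set, screening and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceConglutin:
    """One of the 16 reference conglutin subfamily sequences."""

    subfamily: str
    sequence: str
    domains: tuple[DomainWindow, ...] = ()

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")

    @property
    def family(self) -> str:
        return family_of(self.subfamily)

    @property
    def id(self) -> str:
        return self.subfamily


@dataclass(frozen=True)
class ScreenHit:
    candidate_id: str
    best_subfamily: str
    best_family: str
    identity: float


def screen_candidates(
    db: list[ProteinRecord],
    refs: list[ReferenceConglutin],
    threshold: float = 75.0,
) -> list[ScreenHit]:
    """Retain database sequences whose best identity to any reference
    meets the threshold, annotated with the best-identity reference."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    hits: list[ScreenHit] = []
    ordered = sorted(refs, key=lambda r: r.subfamily)
    for rec in db:
        best_id, best_ref = -1.0, None
        for ref in ordered:
            ident = pairwise_identity(rec.sequence, ref.sequence)
            if ident > best_id:
                best_id, best_ref = ident, ref
        if best_ref is not None and best_id >= threshold:
            hits.append(ScreenHit(rec.id, best_ref.subfamily, best_ref.family, best_id))
    return hits


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    passed: bool
    detail: str = ""


@dataclass
class StructureCheck:
    passed: bool
    trace: list[RuleCheck] = field(default_factory=list)


def _window_rule(
    domains: list[DomainWindow],
    name: str,
    start: int,
    end: int,
    min_overlap_frac: float,
) -> RuleCheck:
    need = min_overlap_frac * (end - start + 1)
    for dom in domains:
        if dom.name == name and dom.overlap(start, end) >= need:
            return RuleCheck(f"{name} window {start}-{end}", True, f"found {dom.start}-{dom.end}")
    return RuleCheck(f"{name} window {start}-{end}", False, "no sufficient overlap")


def check_structure(
    candidate: ProteinRecord,
    family: str,
    domains: list[DomainWindow],
    best_subfamily: str | None = None,
    min_overlap_frac: float = 0.5,
    gamma_min_nterm_cys: int = 2,
) -> StructureCheck:
    """Apply the family-specific structural validation rules.

    alpha: >=1 CXnC cysteine pair and both published cupin_1 windows;
    beta: zero cysteines and both published cupin_1 windows;
    delta: the 9-cysteine skeleton (plus tryp_alpha_amyl when the best
    reference is delta2); gamma: TAXi_N and TAXi_C windows and at least
    ``gamma_min_nterm_cys`` cysteines before the TAXi_N start.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    seq = candidate.sequence
    trace: list[RuleCheck] = []
    if family == "alpha":
        pm = match_cys_pattern(seq, ALPHA_CYS_PAIR, windowed=True)
        trace.append(RuleCheck("alpha CXnC pair", pm.matched))
        for name, s, e in FAMILY_DOMAIN_WINDOWS["alpha"]:
            trace.append(_window_rule(domains, name, s, e, min_overlap_frac))
    elif family == "beta":
        n_cys = seq.count("C")
        trace.append(RuleCheck("beta zero-cysteine rule", n_cys == 0, f"{n_cys} cysteines"))
        for name, s, e in FAMILY_DOMAIN_WINDOWS["beta"]:
            trace.append(_window_rule(domains, name, s, e, min_overlap_frac))
    elif family == "delta":
        pm = match_cys_pattern(seq, DELTA_PATTERN, windowed=True)
        trace.append(RuleCheck("delta cysteine skeleton", pm.matched))
        if best_subfamily == "delta2":
            present = any(d.name == "tryp_alpha_amyl" for d in domains)
            trace.append(RuleCheck("delta2 tryp_alpha_amyl domain", present))
    else:  # gamma
        for name, s, e in FAMILY_DOMAIN_WINDOWS["gamma"]:
            trace.append(_window_rule(domains, name, s, e, min_overlap_frac))
        taxi_n = [d for d in domains if d.name == "TAXi_N"]
        nterm_end = taxi_n[0].start if taxi_n else FAMILY_DOMAIN_WINDOWS["gamma"][0][1]
        n_cys_nterm = seq[: nterm_end - 1].count("C")
        trace.append(
            RuleCheck(
                f"gamma >= {gamma_min_nterm_cys} Cys before TAXi_N",
                n_cys_nterm >= gamma_min_nterm_cys,
                f"{n_cys_nterm} cysteines",
            )
        )
    return StructureCheck(all(c.passed for c in trace), trace)


@dataclass
class ClassificationResult:
    candidate_id: str
    status: str  # "classified" | "rejected"
    family: str
    subfamily: str
    identity: float
    rule_trace: list[RuleCheck] = field(default_factory=list)


def classify(
    db: list[ProteinRecord],
    refs: list[ReferenceConglutin],
    threshold: float = 75.0,
    domains: dict[str, list[DomainWindow]] | None = None,
) -> list[ClassificationResult]:
    """Screen by identity then validate structure; one result per screened
    candidate, with the full rule trace retained."""
    domains = domains or {}
    by_id = {rec.id: rec for rec in db}
    results: list[ClassificationResult] = []
    for hit in screen_candidates(db, refs, threshold):
        cand = by_id[hit.candidate_id]
        chk = check_structure(
            cand, hit.best_family, domains.get(hit.candidate_id, []), hit.best_subfamily
        )
        results.append(
            ClassificationResult(
                hit.candidate_id,
                "classified" if chk.passed else "rejected",
                hit.best_family,
                hit.best_subfamily,
                hit.identity,
                chk.trace,
            )
        )
    return results


# ---------------------------------------------------------------------------
# neighbor-joining tree on the identity distance
# ---------------------------------------------------------------------------


def identity_distance_matrix(named_seqs: list[tuple[str, str]]) -> dict[tuple[str, str], float]:
    d: dict[tuple[str, str], float] = {}
    for i, (ni, si) in enumerate(named_seqs):
        for nj, sj in named_seqs[i + 1 :]:
            dist = 1.0 - pairwise_identity(si, sj) / 100.0
            d[(ni, nj)] = d[(nj, ni)] = dist
    return d


def nj_tree(named_seqs: list[tuple[str, str]]) -> str:
    """Neighbor-joining tree (newick) on d = 1 - identity/100."""
    if len(named_seqs) < 3:
        raise ValueError("nj_tree requires at least 3 sequences")
    names = [n for n, _ in named_seqs]
    return neighbor_joining(names, identity_distance_matrix(named_seqs))


def neighbor_joining(names: list[str], dist: dict[tuple[str, str], float]) -> str:
    """Neighbor-joining on a precomputed distance matrix, in newick form.

    Ties in pair selection are broken by the lexicographically smallest
    (leaf-representative) pair, so the output is deterministic.  Negative
    branch lengths arising from non-additive noise are clamped to zero.
    """
    if len(names) < 3:
        raise ValueError("neighbor_joining requires at least 3 taxa")
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence ids")
    dist = dict(dist)
    # node -> (newick fragment, representative leaf for tie-breaking)
    nodes: dict[str, tuple[str, str]] = {n: (n, n) for n in names}
    active = list(names)

    def d(a: str, b: str) -> float:
        return dist[(a, b)]

    while len(active) > 2:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * d(a, b) - r[a] - r[b]
                rep = tuple(sorted((nodes[a][1], nodes[b][1])))
                key = (q, rep)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"__node{len(nodes)}"
        nodes[new] = (
            f"({nodes[a][0]}:{la:.6f},{nodes[b][0]}:{lb:.6f})",
            min(nodes[a][1], nodes[b][1]),
        )
        for c in active:
            if c in (a, b):
                continue
            duc = (d(a, c) + d(b, c) - dab) / 2.0
            dist[(new, c)] = dist[(c, new)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [new]
    a, b = sorted(active, key=lambda x: nodes[x][1])
    half = d(a, b) / 2.0
    return f"({nodes[a][0]}:{half:.6f},{nodes[b][0]}:{half:.6f});"


# ---------------------------------------------------------------------------
# epitope scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpitopeHit:
    sequence_id: str
    epitope: str
    start: int  # 1-based


def scan_epitopes(
    sequences: list[ProteinRecord], epitopes: list[str]
) -> list[EpitopeHit]:
    """Exact-substring epitope scan; every occurrence is reported,
    including overlapping ones."""
    hits: list[EpitopeHit] = []
    for epi in epitopes:
        if not epi:
            raise ValueError("empty epitope string")
    for rec in sequences:
        for epi in epitopes:
            start = rec.sequence.find(epi)
            while start != -1:
                hits.append(EpitopeHit(rec.id, epi, start + 1))
                start = rec.sequence.find(epi, start + 1)
    return hits
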