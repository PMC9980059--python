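"""Degenerate active-site motif grammar, scanning and cGLR curation.

cGLR (cGAS-like receptor) enzymes are recognized by a conserved
nucleotidyltransferase active-site motif written in a small degenerate
mini-language::

    h[QT]GS [X8-20] [DE]h [DE]h [X50-90] h[DE]h

where uppercase letters are fixed residues, ``[..]`` encloses a residue
class, lowercase letters refer to named classes declared alongside the
pattern (``h`` = hydrophobic), and ``[Xm-n]`` is a variable-length spacer of
m..n residues strictly between the flanking anchors.

This module parses that language, enumerates every placement of a pattern
on a protein sequence, applies the three-part curation procedure (active
site + activation loop + catalytic triad motifs, plus two externally
supplied homology flags), and removes redundant sequences by greedy
centroid clustering at an identity/coverage threshold.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import Align

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic class used by the curation motifs (configurable in
#: data/patterns.yaml): the Kyte-Doolittle-positive residues.
DEFAULT_CLASSES: dict[str, frozenset[str]] = {"h": frozenset("ACFILMVWY")}


class MotifError(ValueError):
    """Raised for malformed patterns or inconsistent curation inputs."""


# ---------------------------------------------------------------------------
# Pattern types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueClass:
    """A named set of amino-acid residues matched by one pattern position."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise MotifError(f"residue class {self.label!r} is empty")
        bad = set(self.members) - STANDARD_AA
        if bad:
            raise MotifError(
                f"residue class {self.label!r} contains non-standard codes: {sorted(bad)}"
            )


@dataclass(frozen=True)
class MotifElement:
    """One token of a pattern: a fixed residue, a residue class, or a spacer.

    Fixed and class elements have implicit length 1; gap elements span
    ``min_len..max_len`` residues (inclusive bounds on the residues strictly
    between the flanking anchors).
    """

    kind: str  # "fixed" | "class" | "gap"
    residue: str | None = None
    class_ref: str | None = None
    members: frozenset[str] | None = None
    min_len: int = 0
    max_len: int = 0

    def allows(self, ch: str) -> bool:
        """Whether a single character satisfies this (non-gap) element.

        Non-standard residue codes (B, J, O, U, X, Z, *) never satisfy fixed
        or class elements; they only count toward gap lengths.
        """
        if ch not in STANDARD_AA:
            return False
        if self.kind == "fixed":
            return ch == self.residue
        return ch in self.members  # type: ignore[operator]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[MotifElement, ...]
    alphabet: Mapping[str, ResidueClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(e.kind != "gap" for e in self.elements):
            raise MotifError(f"pattern {self.name!r} contains only gaps")
        for a, b in zip(self.elements, self.elements[1:]):
            if a.kind == "gap" and b.kind == "gap":
                raise MotifError("consecutive gap elements must be merged")

    @property
    def min_length(self) -> int:
        return sum(e.min_len if e.kind == "gap" else 1 for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_len if e.kind == "gap" else 1 for e in self.elements)

    def render(self) -> str:
        """Canonical text rendering; ``parse_pattern`` round-trips it."""
        parts = []
        for e in self.elements:
            if e.kind == "gap":
                parts.append(f"[X{e.min_len}-{e.max_len}]")
            elif e.kind == "fixed":
                parts.append(e.residue)
            elif e.class_ref is not None:
                parts.append(e.class_ref)
            else:
                parts.append("[" + "".join(sorted(e.members)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    """A placement of a pattern: one (start, end) span per non-gap element."""

    sequence_id: str
    anchor_spans: tuple[tuple[int, int], ...]
    full_span: tuple[int, int]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_GAP_RE = re.compile(r"X(\d+)[-–](\d+)")


def parse_pattern(
    text: str,
    class_definitions: Mapping[str, Iterable[str]] | None = None,
    name: str = "",
) -> MotifPattern:
    """Parse a motif mini-language string into a :class:`MotifPattern`.

    Tokens: bare uppercase letters (fixed residues), ``[ABC]`` / ``[A/B]``
    (inline classes), declared lowercase class letters, and ``[Xm-n]`` or
    ``Xm-n`` spacers (en-dash accepted). Whitespace is ignored; adjacent
    gaps are merged by summing their bounds.
    """
    classes = dict(DEFAULT_CLASSES)
    if class_definitions is not None:
        classes = {k: frozenset(v) for k, v in class_definitions.items()}
    alphabet = {k: ResidueClass(k, frozenset(v)) for k, v in classes.items()}

    src = "".join(text.split())
    elements: list[MotifElement] = []

    def push_gap(lo: int, hi: int) -> None:
        if lo > hi:
            raise MotifError(f"gap with min>max in {text!r}: X{lo}-{hi}")
        if elements and elements[-1].kind == "gap":
            prev = elements.pop()
            lo, hi = prev.min_len + lo, prev.max_len + hi
        elements.append(MotifElement("gap", min_len=lo, max_len=hi))

    i = 0
    while i < len(src):
        ch = src[i]
        if ch == "[":
            j = src.find("]", i)
            if j < 0:
                raise MotifError(f"unclosed '[' in {text!r}")
            body = src[i + 1 : j]
            m = _GAP_RE.fullmatch(body)
            if m:
                push_gap(int(m.group(1)), int(m.group(2)))
            else:
                members: set[str] = set()
                for c in body.replace("/", ""):
                    if c in classes:
                        members |= set(classes[c])
                    elif c in STANDARD_AA:
                        members.add(c)
                    else:
                        raise MotifError(f"unknown symbol {c!r} in class [{body}]")
                if not members:
                    raise MotifError(f"empty class in {text!r}")
                elements.append(
                    MotifElement("class", members=frozenset(members))
                )
            i = j + 1
        elif ch == "X" and (m := _GAP_RE.match(src, i)):
            push_gap(int(m.group(1)), int(m.group(2)))
            i = m.end()
        elif ch in classes:
            cls = alphabet[ch]
            elements.append(
                MotifElement("class", class_ref=ch, members=cls.members)
            )
            i += 1
        elif ch in STANDARD_AA:
            elements.append(MotifElement("fixed", residue=ch))
            i += 1
        else:
            raise MotifError(f"unknown token {ch!r} at position {i} in {text!r}")

    return MotifPattern(name=name or src, elements=tuple(elements), alphabet=alphabet)


def load_default_patterns() -> dict[str, MotifPattern]:
    """The three curation patterns shipped in ``data/patterns.yaml``."""
    with resources.files("cglrkit.data").joinpath("patterns.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return load_patterns_config(cfg)


def load_patterns_config(cfg: Mapping) -> dict[str, MotifPattern]:
    classes = {k: frozenset(v) for k, v in cfg.get("classes", {}).items()}
    return {
        pname: parse_pattern(ptext, classes or None, name=pname)
        for pname, ptext in cfg["patterns"].items()
    }


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan(sequence: str, pattern: MotifPattern, mode: str = "all") -> list[MotifMatch]:
    """All distinct anchor placements of ``pattern`` on ``sequence``.

    Two placements are distinct iff any anchor span differs; gap-length
    combinations that move no anchor collapse to one match. Results are
    sorted by full-span start, then lexicographically by anchor starts.
    ``mode="first"`` returns only the leftmost placement.

    Gap positions accept any character (non-standard codes included); fixed
    and class anchors accept only the 20 standard codes.
    """
    if mode not in ("all", "first"):
        raise ValueError(f"mode must be 'all' or 'first', got {mode!r}")
    if not sequence:
        raise ValueError("sequence must be nonempty")
    seq_id = getattr(sequence, "id", "")
    seq = str(sequence)
    n = len(seq)
    elements = pattern.elements
    found: set[tuple[tuple[int, int], ...]] = set()

    def rec(pos: int, idx: int, anchors: list[tuple[int, int]]) -> None:
        if idx == len(elements):
            found.add(tuple(anchors))
            return
        el = elements[idx]
        if el.kind == "gap":
            for gap in range(el.min_len, el.max_len + 1):
                if pos + gap > n:
                    break
                rec(pos + gap, idx + 1, anchors)
        else:
            if pos < n and el.allows(seq[pos]):
                anchors.append((pos, pos + 1))
                rec(pos + 1, idx + 1, anchors)
                anchors.pop()

    for start in range(n):
        rec(start, 0, [])

    matches = [
        MotifMatch(
            sequence_id=seq_id,
            anchor_spans=spans,
            full_span=(spans[0][0], spans[-1][1]),
        )
        for spans in found
    ]
    matches.sort(key=lambda m: (m.full_span[0], m.anchor_spans))
    if mode == "first":
        return matches[:1]
    return matches


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

#: Externally computed curation criteria consumed as boolean columns:
#: shared NTase-core/helix-bundle homology and predicted structural homology.
REQUIRED_FLAGS = ("ntase_helix_bundle_homology", "structural_homology")
DEFAULT_REQUIRED_MOTIFS = ("active_site", "activation_loop", "catalytic_triad")


@dataclass
class CurationRecord:
    sequence_id: str
    species: str
    sequence: str
    external_flags: dict[str, bool]
    decision: str  # "retained" | "excluded"
    reasons: list[str]
    matches: list[MotifMatch]


def curate(
    records: Sequence[tuple[str, str, str, Mapping[str, bool]]],
    patterns: Mapping[str, MotifPattern],
    required_motifs: Sequence[str] = DEFAULT_REQUIRED_MOTIFS,
) -> list[CurationRecord]:
    """Apply the three-part curation procedure to candidate sequences.

    A record is retained iff every required motif has at least one placement
    and both external homology flags are true. ``required_motifs`` may be
    relaxed to a subset when the activation loop and catalytic triad are
    treated as part of the active-site criterion rather than separate ones.

    Each ``records`` item is ``(id, species, sequence, external_flags)``.
    Missing flags raise :class:`MotifError` naming the record — external
    evidence is never silently defaulted.
    """
    for motif_name in required_motifs:
        if motif_name not in patterns:
            raise MotifError(f"no pattern supplied for required motif {motif_name!r}")

    out: list[CurationRecord] = []
    for seq_id, species, sequence, flags in records:
        for flag in REQUIRED_FLAGS:
            if flag not in flags:
                raise MotifError(
                    f"record {seq_id!r} is missing external flag {flag!r}"
                )
        reasons: list[str] = []
        active_matches: list[MotifMatch] = []
        for motif_name in required_motifs:
            hits = scan(sequence, patterns[motif_name], mode="all")
            hits = [
                MotifMatch(seq_id, m.anchor_spans, m.full_span) for m in hits
            ]
            if motif_name == "active_site":
                active_matches = hits
            if not hits:
                reasons.append(f"{motif_name.replace('_', ' ')} absent")
        for flag in REQUIRED_FLAGS:
            if not flags[flag]:
                reasons.append(f"{flag} flag false")
        out.append(
            CurationRecord(
                sequence_id=seq_id,
                species=species,
                sequence=sequence,
                external_flags=dict(flags),
                decision="retained" if not reasons else "excluded",
                reasons=reasons,
                matches=active_matches,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Redundancy removal
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cluster_id: int
    representative_id: str
    member_ids: list[str]


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def alignment_identity(
    a: str, b: str, gap_open: float = 5.0, gap_extend: float = 1.0
) -> float:
    """Global-alignment identity: exact matches / alignment columns.

    Unit match score, zero mismatch, affine gap penalties (defaults
    open=5, extend=1).
    """
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def dedupe_cluster(
    sequences: Sequence[tuple[str, str]],
    min_identity: float = 0.95,
    min_coverage: float = 1.0,
    gap_open: float = 5.0,
    gap_extend: float = 1.0,
) -> list[Cluster]:
    """Greedy centroid clustering for redundancy removal.

    Sequences are sorted by descending length (ties: ascending id); each one
    joins the first existing representative with identity >= ``min_identity``
    and mutual coverage >= ``min_coverage``, else founds its own cluster.
    Mutual coverage of a pair is min(len)/max(len) — a global alignment spans
    both sequences, so at the default ``min_coverage=1`` members must be
    length-identical to their representative. Deterministic.
    """
    if not 0.0 < min_identity <= 1.0 or not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_identity and min_coverage must be in (0, 1]")
    aligner = _make_aligner(gap_open, gap_extend)
    order = sorted(sequences, key=lambda t: (-len(t[1]), t[0]))
    clusters: list[Cluster] = []
    reps: list[str] = []
    eps = 1e-12
    for seq_id, seq in order:
        placed = False
        for cluster, rep_seq in zip(clusters, reps):
            cov = min(len(seq), len(rep_seq)) / max(len(seq), len(rep_seq))
            if cov + eps < min_coverage:
                continue
            alignment = aligner.align(rep_seq, seq)[0]
            identity = alignment.counts().identities / alignment.length
            if identity + eps >= min_identity:
                cluster.member_ids.append(seq_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(len(clusters), seq_id, [seq_id]))
            reps.append(seq)
    return clusters
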