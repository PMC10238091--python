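"""Protein and transcript sequence features.

Four independent primitives live here:

* residue-class short-linear-motif scanning (the F/YXF-class pattern that
  predicts binding to the conserved essential surface of SA proteins),
* exon-exon junction enumeration and percent-spliced-in (PSI) from
  junction read counts, with the minimum-read support rule,
* reading-frame translation and reconstruction of alternatively spliced
  exon peptides from paired paralog nucleotide sequences,
* peptide isoelectric point by bisection of the Henderson-Hasselbalch
  net-charge function with a Bjellqvist-style pKa table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: F/YXF-class motif predicting binding to the SA conserved essential surface,
#: in residue-class syntax: [PFCAVIYL][FY][GDEN]F.{0,1}[DANE].{0,1}[DE]
FYXF_PATTERN_STRING = "[PFCAVIYL][FY][GDEN]F.{0,1}[DANE].{0,1}[DE]"


@dataclass(frozen=True)
class MotifPosition:
    """One position class of a motif: an allowed-residue set (None = wildcard)
    and whether the position may be absent."""

    allowed: frozenset | None
    optional: bool = False

    def accepts(self, residue: str) -> bool:
        return self.allowed is None or residue in self.allowed


@dataclass(frozen=True)
class MotifPattern:
    positions: tuple[MotifPosition, ...]

    def __post_init__(self):
        if all(p.optional for p in self.positions):
            raise ValueError("motif pattern needs at least one non-optional position")
        for p in self.positions:
            if p.allowed is not None and not p.allowed <= AMINO_ACIDS:
                bad = sorted(p.allowed - AMINO_ACIDS)
                raise ValueError(f"non-amino-acid residues in class: {bad}")

    @property
    def min_length(self) -> int:
        return sum(1 for p in self.positions if not p.optional)

    @property
    def max_length(self) -> int:
        return len(self.positions)

    def expansions(self) -> list[tuple[MotifPosition, ...]]:
        """All fixed-length patterns obtained by taking each optional position
        as present or absent (order preserved)."""
        optional_idx = [i for i, p in enumerate(self.positions) if p.optional]
        out = []
        for keep in itertools.product((True, False), repeat=len(optional_idx)):
            drop = {i for i, k in zip(optional_idx, keep) if not k}
            out.append(tuple(p for i, p in enumerate(self.positions) if i not in drop))
        return out


def parse_pattern(text: str) -> MotifPattern:
    """Parse residue-class syntax: ``[ABC]`` classes, ``.`` wildcards, single
    letters, each optionally followed by ``{0,1}``."""
    positions: list[MotifPosition] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.index("]", i)
            allowed = frozenset(text[i + 1 : j])
            i = j + 1
        elif ch == ".":
            allowed = None
            i += 1
        elif ch in AMINO_ACIDS:
            allowed = frozenset(ch)
            i += 1
        else:
            raise ValueError(f"cannot parse pattern at position {i}: {text[i:]!r}")
        optional = text.startswith("{0,1}", i)
        if optional:
            i += 5
        positions.append(MotifPosition(allowed, optional))
    return MotifPattern(tuple(positions))


FYXF_PATTERN = parse_pattern(FYXF_PATTERN_STRING)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based
    length: int
    match: str


def scan_motif(sequence: str, pattern: MotifPattern = FYXF_PATTERN,
               sequence_id: str = "") -> list[MotifHit]:
    """All spans of ``sequence`` matching ``pattern``.

    Optional positions are expanded explicitly to fixed-length patterns
    (window lengths ``min_length`` .. ``max_length``), so every reported span
    is exact; overlapping hits and multiple window lengths per start are all
    reported, with exact duplicate spans removed.
    """
    for pos, residue in enumerate(sequence):
        if residue not in AMINO_ACIDS:
            raise ValueError(
                f"invalid residue {residue!r} at position {pos}"
                + (f" of {sequence_id}" if sequence_id else "")
            )
    spans: set[tuple[int, int]] = set()
    expansions = pattern.expansions()
    for start in range(len(sequence)):
        for exp in expansions:
            end = start + len(exp)
            if end > len(sequence):
                continue
            if all(p.accepts(sequence[start + k]) for k, p in enumerate(exp)):
                spans.add((start, len(exp)))
    return [
        MotifHit(sequence_id, s, ln, sequence[s : s + ln])
        for s, ln in sorted(spans)
    ]


# ---------------------------------------------------------------------------
# Splicing: junction enumeration and PSI


def enumerate_eej(donors: list[int], acceptors: list[int]) -> list[tuple[int, int]]:
    """All hypothetical exon-exon junctions: (donor, acceptor) pairs with the
    donor coordinate strictly upstream of the acceptor."""
    return [(d, a) for d in donors for a in acceptors if d < a]


@dataclass(frozen=True)
class PsiEvent:
    """A cassette-exon splicing event quantified from junction reads.

    PSI (percent spliced in) is the ratio between reads that include and
    exclude the exon: inclusion reads are normalised by the two inclusion
    junctions, exclusion reads by the single skipping junction.
    """

    inclusion_counts: tuple[int, ...]
    exclusion_count: int
    psi: float | None
    supported: bool
    n_inclusion_junctions: int = 2
    n_exclusion_junctions: int = 1
    min_reads: int = 50


def compute_psi(inclusion_counts, exclusion_count: float,
                min_reads: int = 50) -> PsiEvent:
    """PSI = 100 * inc_norm / (inc_norm + exc_norm), where inc_norm averages
    the inclusion junctions and exc_norm the exclusion junction; undefined
    (None) when no junction reads exist. ``supported`` requires at least
    ``min_reads`` total junction reads."""
    inclusion_counts = tuple(inclusion_counts)
    if any(c < 0 for c in inclusion_counts) or exclusion_count < 0:
        raise ValueError("junction counts must be non-negative")
    n_inc = len(inclusion_counts)
    inc_norm = sum(inclusion_counts) / n_inc if n_inc else 0.0
    exc_norm = float(exclusion_count)
    total = sum(inclusion_counts) + exclusion_count
    psi = None if inc_norm + exc_norm == 0 else 100.0 * inc_norm / (inc_norm + exc_norm)
    return PsiEvent(
        inclusion_counts=inclusion_counts,
        exclusion_count=exclusion_count,
        psi=psi,
        supported=total >= min_reads,
        n_inclusion_junctions=n_inc,
        min_reads=min_reads,
    )


# ---------------------------------------------------------------------------
# Translation and exon peptides


@dataclass(frozen=True)
class Peptide:
    sequence: str
    offset: int
    internal_stop: bool


def translate(nt_sequence: str, offset: int = 0) -> Peptide:
    """Translate from ``offset`` with the standard codon table; trailing
    partial codons are dropped, internal stops are kept as '*' and flagged."""
    nt_sequence = nt_sequence.upper().replace(" ", "").replace("\n", "")
    bad = set(nt_sequence) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in nucleotide sequence: {sorted(bad)}")
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    if offset >= len(nt_sequence):
        raise ValueError("offset beyond sequence end")
    framed = nt_sequence[offset:]
    framed = framed[: len(framed) - len(framed) % 3]
    aa = str(Seq(framed).translate())
    return Peptide(sequence=aa, offset=offset, internal_stop="*" in aa)


def stop_free_offsets(nt_sequence: str) -> list[int]:
    return [off for off in (0, 1, 2) if not translate(nt_sequence, off).internal_stop]


def reconstruct_exon_peptides(nt_sequences: list[str]) -> list[Peptide]:
    """Translate paired paralog exon sequences at the unique reading offset
    that is internal-stop-free for every sequence in the set.

    The rule needs no external frame annotation: for the SA1 exon-31 / SA2
    exon-32 pair the SA2 sequence has internal stops in two of its three
    frames, which pins the shared frame down uniquely.
    """
    if not nt_sequences:
        raise ValueError("need at least one nucleotide sequence")
    per_seq = [stop_free_offsets(s) for s in nt_sequences]
    common = set(per_seq[0]).intersection(*per_seq[1:])
    if len(common) != 1:
        raise ValueError(
            f"no unique common stop-free offset: common={sorted(common)}, "
            f"per-sequence stop-free offsets={per_seq}"
        )
    (offset,) = common
    return [translate(s, offset) for s in nt_sequences]


# ---------------------------------------------------------------------------
# Isoelectric point

#: Bjellqvist-style pKa set. Positively ionizable groups: N-terminus
#: (residue-specific), K, R, H side chains; negatively ionizable: C-terminus,
#: D, E, C, Y side chains.
BJELLQVIST_PKA = {
    "positive_side": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative_side": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "c_term": {"D": 4.55, "E": 4.75},
    "c_term_default": 3.55,
    "n_term": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
               "V": 7.44, "E": 7.7},
    "n_term_default": 7.5,
}


def net_charge(peptide: str, ph: float, pka_table: dict = BJELLQVIST_PKA) -> float:
    """Henderson-Hasselbalch net charge at ``ph``:
    Z = sum over positive groups 1/(1+10^(pH-pKa))
      - sum over negative groups 1/(1+10^(pKa-pH))."""
    pos = pka_table["positive_side"]
    neg = pka_table["negative_side"]
    n_term_pka = pka_table["n_term"].get(peptide[0], pka_table["n_term_default"])
    c_term_pka = pka_table["c_term"].get(peptide[-1], pka_table["c_term_default"])
    z = 1.0 / (1.0 + 10.0 ** (ph - n_term_pka))
    z -= 1.0 / (1.0 + 10.0 ** (c_term_pka - ph))
    for residue in peptide:
        if residue in pos:
            z += 1.0 / (1.0 + 10.0 ** (ph - pos[residue]))
        elif residue in neg:
            z -= 1.0 / (1.0 + 10.0 ** (neg[residue] - ph))
    return z


def isoelectric_point(peptide: Peptide | str, pka_table: dict = BJELLQVIST_PKA,
                      tol: float = 1e-4) -> float:
    """pI = the unique root of the net-charge function, by bisection on
    [0, 14]. Z(pH) is strictly decreasing in pH (every Henderson-Hasselbalch
    term is), so the root is unique; free termini guarantee at least one
    positive and one negative group.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if isinstance(peptide, Peptide) and peptide.internal_stop:
        raise ValueError("cannot compute pI of a peptide with internal stops")
    if not seq:
        raise ValueError("empty peptide")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
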