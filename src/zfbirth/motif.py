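"""Residue-class motif patterns and six-frame DNA scanning.

The C2H2 zinc-finger motif is described here as a hard pattern over residue
classes with bounded gap repeats::

    Ø-X-C-X{2,4,5}-C-X3-Ø-X5-Ø-X2-H-X{3,4}-H

where ``C``/``H`` are literal cysteine/histidine, ``X`` is any amino acid and
``Ø`` is a hydrophobic residue.  A match is a contiguous peptide span in one of
the six translated reading frames of a DNA sequence; spans never cross a stop
(``*``) or an ambiguous (``X``) residue.  For each distinct (frame, start)
admitting any expansion of the variable gaps, the leftmost-shortest expansion
fixes the reported match length, so the default pattern yields matches of
23–27 aa.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default hydrophobic (Ø) residue set; configurable on every public entry point.
DEFAULT_HYDROPHOBIC = frozenset("ACFILMVWY")

FRAMES = (1, 2, 3, -1, -2, -3)

_VALID_DNA = re.compile(r"[ACGTN]*\Z")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case-normalised)."""
    return dna.upper().translate(_COMPLEMENT)[::-1]


def _build_codon_table() -> dict[str, str]:
    table = {}
    for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
        table[codon] = str(Seq(codon).translate())
    return table


_CODON_TABLE = _build_codon_table()


def validate_dna(dna: str) -> str:
    """Upper-case ``dna`` and reject non-IUPAC characters (A/C/G/T/N only)."""
    seq = dna.upper()
    if not _VALID_DNA.match(seq):
        for i, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise ValueError(
                    f"invalid nucleotide {ch!r} at position {i} (0-based)"
                )
    return seq


def _translate(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        # any codon containing N is rendered as the ambiguous residue X
        aas.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def translate_six_frames(dna: str) -> dict[int, str]:
    """Translate ``dna`` in all six reading frames.

    Frames +1/+2/+3 read the forward strand with offsets 0/1/2; frames
    −1/−2/−3 read the reverse complement the same way.  Stop codons are
    rendered ``*``, codons containing N as ``X``; trailing partial codons are
    dropped.

    Returns a mapping ``{+1: peptide, ..., -3: peptide}``.
    """
    seq = validate_dna(dna)
    rc = reverse_complement(seq)
    return {
        1: _translate(seq),
        2: _translate(seq[1:]),
        3: _translate(seq[2:]),
        -1: _translate(rc),
        -2: _translate(rc[1:]),
        -3: _translate(rc[2:]),
    }


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: an allowed residue set with allowed repeat counts."""

    residues: frozenset
    repeats: tuple

    def __post_init__(self):
        if not self.repeats:
            raise ValueError("allowed_repeat_counts must be non-empty")
        if any(r < 0 for r in self.repeats):
            raise ValueError("repeat counts must be non-negative")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"residue class contains non-amino-acid symbols: {bad}")


@dataclass(frozen=True)
class MotifPattern:
    """An ordered sequence of residue-class elements with bounded gap repeats.

    ``min_length``/``max_length`` are the sums of the per-element minimum and
    maximum repeat counts.  Matching never admits ``*`` or ``X``: a motif
    interrupted by a stop or an ambiguous codon cannot be a coding motif, so
    no residue class — including the any-residue class — contains them.
    """

    elements: tuple

    # sorted (total_length, counts) expansions, computed once
    _expansions: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        combos = []
        for counts in itertools.product(*(e.repeats for e in self.elements)):
            combos.append((sum(counts), counts))
        combos.sort()
        object.__setattr__(self, "_expansions", tuple(combos))

    @property
    def min_length(self) -> int:
        return self._expansions[0][0]

    @property
    def max_length(self) -> int:
        return self._expansions[-1][0]

    def expansions(self):
        """All gap expansions as (total_length, per-element counts), sorted
        leftmost-shortest: by total length, then lexicographically."""
        return self._expansions

    @classmethod
    def c2h2(cls, hydrophobic: Iterable[str] = DEFAULT_HYDROPHOBIC) -> "MotifPattern":
        """The C2H2 zinc-finger pattern Ø-X-C-X{2,4,5}-C-X3-Ø-X5-Ø-X2-H-X{3,4}-H."""
        hyd = frozenset(hydrophobic)
        any_ = frozenset(AMINO_ACIDS)
        C = frozenset("C")
        H = frozenset("H")
        one = (1,)
        spec = [
            (hyd, one),
            (any_, one),
            (C, one),
            (any_, (2, 4, 5)),
            (C, one),
            (any_, (3,)),
            (hyd, one),
            (any_, (5,)),
            (hyd, one),
            (any_, (2,)),
            (H, one),
            (any_, (3, 4)),
            (H, one),
        ]
        return cls(tuple(PatternElement(r, c) for r, c in spec))

    @classmethod
    def from_string(
        cls, text: str, hydrophobic: Iterable[str] = DEFAULT_HYDROPHOBIC
    ) -> "MotifPattern":
        """Parse a dash-separated pattern string.

        Tokens: ``O`` or ``Ø`` (hydrophobic), ``X`` (any), a single amino acid
        letter (literal), or ``[ACD]`` (a set); each optionally followed by a
        repeat spec ``{2,4,5}`` or a bare count/count list like ``3`` / ``3,4``.
        Example: ``"O-X-C-X{2,4,5}-C-X3-O-X5-O-X2-H-X{3,4}-H"``.
        """
        hyd = frozenset(hydrophobic)
        any_ = frozenset(AMINO_ACIDS)
        elements = []
        for token in text.replace("Ø", "O").split("-"):
            token = token.strip()
            m = re.fullmatch(r"(\[[A-Z]+\]|[A-Z])(?:\{([\d,]+)\}|([\d,]+))?", token)
            if not m:
                raise ValueError(f"cannot parse pattern token {token!r}")
            cls_tok, braced, bare = m.groups()
            if cls_tok == "O":
                residues = hyd
            elif cls_tok == "X":
                residues = any_
            elif cls_tok.startswith("["):
                residues = frozenset(cls_tok[1:-1])
            else:
                residues = frozenset(cls_tok)
            counts_tok = braced or bare
            counts = (
                tuple(int(c) for c in counts_tok.split(",")) if counts_tok else (1,)
            )
            elements.append(PatternElement(residues, counts))
        return cls(tuple(elements))


@dataclass(frozen=True)
class MotifMatch:
    """A motif occurrence in one reading frame.

    ``aa_start`` is 0-based in that frame's peptide; ``dna_start``/``dna_end``
    are 0-based half-open coordinates on the forward strand of the scanned
    sequence, so ``dna_end - dna_start == 3 * aa_length`` in every frame.
    """

    frame: int
    aa_start: int
    aa_length: int
    dna_start: int
    dna_end: int


def match_at(peptide: str, start: int, pattern: MotifPattern):
    """Length of the leftmost-shortest pattern expansion matching at ``start``,
    or ``None``.  Expansions are tried in (total length, counts) order."""
    n = len(peptide)
    for total, counts in pattern.expansions():
        if start + total > n:
            continue
        pos = start
        ok = True
        for element, count in zip(pattern.elements, counts):
            residues = element.residues
            for _ in range(count):
                if peptide[pos] not in residues:
                    ok = False
                    break
                pos += 1
            if not ok:
                break
        if ok:
            return total
    return None


def _frame_to_dna(frame: int, aa_start: int, aa_length: int, dna_len: int):
    offset = abs(frame) - 1
    if frame > 0:
        dna_start = offset + 3 * aa_start
        return dna_start, dna_start + 3 * aa_length
    rc_start = offset + 3 * aa_start
    dna_end = dna_len - rc_start
    return dna_end - 3 * aa_length, dna_end


def scan_peptide(peptide: str, pattern: MotifPattern):
    """All (aa_start, aa_length) matches in one peptide, one per start."""
    hits = []
    last = len(peptide) - pattern.min_length
    # cheap prefilter: elements with fixed offsets before the first variable gap
    prefix = []
    off = 0
    for element in pattern.elements:
        if len(element.repeats) != 1:
            break
        prefix.append((off, element.residues))
        off += element.repeats[0]
    for start in range(last + 1):
        if any(peptide[start + o] not in res for o, res in prefix):
            continue
        length = match_at(peptide, start, pattern)
        if length is not None:
            hits.append((start, length))
    return hits


def scan_dna(dna: str, pattern: MotifPattern):
    """Find all motif matches in the six translated reading frames of ``dna``.

    One :class:`MotifMatch` is reported per distinct (frame, aa_start) that
    admits any gap expansion; the leftmost-shortest expansion fixes the
    length.  Matches never span ``*`` or ``X`` residues.
    """
    seq = validate_dna(dna)
    matches = []
    for frame, peptide in translate_six_frames(seq).items():
        for aa_start, aa_length in scan_peptide(peptide, pattern):
            dna_start, dna_end = _frame_to_dna(frame, aa_start, aa_length, len(seq))
            matches.append(MotifMatch(frame, aa_start, aa_length, dna_start, dna_end))
    return matches


def excise_motifs(protein: str, pattern: MotifPattern):
    """Split a peptide into its motif spans and the remainder.

    Non-overlapping matches are taken greedily left to right, each with the
    leftmost-shortest expansion (the convention used for building motif-only
    and motif-free sequence sets before clustering).  Returns
    ``(motif_only, motif_free)``; their concatenation is a permutation of the
    input residues.
    """
    bad = set(protein) - set(AMINO_ACIDS + "*X")
    if bad:
        raise ValueError(f"invalid peptide symbols: {sorted(bad)}")
    motif_parts = []
    free_parts = []
    i = 0
    n = len(protein)
    last_cut = 0
    while i <= n - pattern.min_length:
        length = match_at(protein, i, pattern)
        if length is not None:
            free_parts.append(protein[last_cut:i])
            motif_parts.append(protein[i : i + length])
            i += length
            last_cut = i
        else:
            i += 1
    free_parts.append(protein[last_cut:])
    return "".join(motif_parts), "".join(free_parts)


# ---------------------------------------------------------------------------
# Vectorised batch counting (used by the Monte Carlo campaign)
# ---------------------------------------------------------------------------

_BASE_CODES = {b: i for i, b in enumerate("ACGT")}
_N_AA = len(AMINO_ACIDS)
_STOP_CODE = _N_AA  # amino-acid code for '*'
_AA_CODES = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_CODES["*"] = _STOP_CODE


@lru_cache(maxsize=None)
def _codon_aa_codes() -> np.ndarray:
    """Map codon index 16*b0 + 4*b1 + b2 (A=0,C=1,G=2,T=3) to amino-acid code."""
    out = np.empty(64, dtype=np.uint8)
    for i, codon in enumerate("".join(c) for c in itertools.product("ACGT", repeat=3)):
        out[i] = _AA_CODES[_CODON_TABLE[codon]]
    return out


def _class_lut(residues: frozenset) -> np.ndarray:
    lut = np.zeros(_N_AA + 1, dtype=bool)
    for aa in residues:
        lut[_AA_CODES[aa]] = True
    return lut  # stop code stays False for every class


def _translate_batch(bases: np.ndarray, offset: int) -> np.ndarray:
    usable = (bases.shape[1] - offset) // 3
    window = bases[:, offset : offset + 3 * usable]
    codons = (
        16 * window[:, 0::3].astype(np.int16)
        + 4 * window[:, 1::3].astype(np.int16)
        + window[:, 2::3].astype(np.int16)
    )
    return _codon_aa_codes()[codons]


def _codon_indices(bases: np.ndarray) -> np.ndarray:
    # codon index at every offset; values <= 63 so uint8 arithmetic is exact
    return bases[:, :-2] * 16 + bases[:, 1:-1] * 4 + bases[:, 2:]


def count_matches_batch(bases: np.ndarray, pattern: MotifPattern) -> np.ndarray:
    """Motif match counts for many equal-length sequences at once.

    ``bases`` is an (n_seqs, seq_len) uint8 array with A=0, C=1, G=2, T=3
    (no ambiguity codes).  Returns the per-sequence number of distinct
    (frame, aa_start) matches — the same counting convention as
    :func:`scan_dna`, which this function must (and is tested to) agree with.
    """
    if bases.ndim != 2:
        raise ValueError("bases must be 2-D (n_seqs, seq_len)")
    n = bases.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    luts = {}
    # per-expansion absolute positions: (position_in_window, class lut)
    expansion_layouts = []
    for total, combo in pattern.expansions():
        layout = []
        pos = 0
        for element, count in zip(pattern.elements, combo):
            key = element.residues
            if key not in luts:
                luts[key] = _class_lut(key)
            for _ in range(count):
                layout.append((pos, luts[key]))
                pos += 1
        expansion_layouts.append((total, layout))

    # vectorised prefilter over the fixed-offset prefix (elements before the
    # first variable gap); surviving (row, start) candidates — rare for any
    # selective pattern — are verified expansion-by-expansion.
    prefix = []
    off = 0
    for element in pattern.elements:
        if len(element.repeats) != 1:
            break
        key = element.residues
        if key not in luts:
            luts[key] = _class_lut(key)
        for _ in range(element.repeats[0]):
            prefix.append((off, luts[key]))
            off += 1

    aa_of_codon = _codon_aa_codes()
    rc = 3 - bases[:, ::-1]
    for strand in (bases, rc):
        codons = _codon_indices(strand)
        for offset in range(3):
            pep = aa_of_codon[codons[:, offset::3]]
            length = pep.shape[1]
            n_starts = length - pattern.min_length + 1
            if n_starts <= 0:
                continue
            cand = np.ones((n, n_starts), dtype=bool)
            for pos, lut in prefix:
                cand &= lut[pep[:, pos : pos + n_starts]]
            rows, starts = np.nonzero(cand)
            if rows.size == 0:
                continue
            matched = np.zeros(rows.size, dtype=bool)
            for total, layout in expansion_layouts:
                fits = ~matched & (starts + total <= length)
                idx = np.nonzero(fits)[0]
                if idx.size == 0:
                    continue
                ok = np.ones(idx.size, dtype=bool)
                r, s = rows[idx], starts[idx]
                for pos, lut in layout:
                    ok &= lut[pep[r, s + pos]]
                matched[idx[ok]] = True
            np.add.at(counts, rows[matched], 1)
    return counts


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length A/C/G/T strings as the uint8 matrix used by
    :func:`count_matches_batch`."""
    arr = np.frombuffer("".join(s.upper() for s in seqs).encode(), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODES.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        raise ValueError("sequences must contain only A/C/G/T")
    return out
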