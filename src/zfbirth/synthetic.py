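"""Synthetic-data generators: composition-matched random DNA, motif-implanted
fixtures, neutral coalescent population samples and spectrum-skewed alignments,
and mutated CDS pairs.

Everything downstream of the generators consumes ordinary sequences, so
infinite-sites mutations are materialised as concrete A/C/G/T alignment
columns (ancestral base A, derived base drawn from {C,G,T}) rather than 0/1
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .motif import (
    MotifPattern,
    match_at,
    reverse_complement,
    validate_dna,
)
from .neutrality import PopAlignment

BASES = "ACGT"

# reverse codon table: aa -> codons, built from the forward table in motif
from .motif import _CODON_TABLE  # noqa: E402

_SYNONYMOUS: dict = {}
for _codon, _aa in _CODON_TABLE.items():
    _SYNONYMOUS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class BaseComposition:
    """Mononucleotide frequencies estimated from sequence, N bases skipped."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float
    n_counted: int = 0
    n_skipped: int = 0

    def as_tuple(self):
        return (self.freq_A, self.freq_C, self.freq_G, self.freq_T)

    def __post_init__(self):
        if self.n_counted > 0 and abs(sum(self.as_tuple()) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)


def base_composition(seqs: Iterable) -> BaseComposition:
    """A/C/G/T frequencies over all records (strings or SeqRecords),
    case-insensitive; N bases are skipped and tallied."""
    counts = dict.fromkeys(BASES, 0)
    skipped = 0
    for rec in seqs:
        seq = validate_dna(str(getattr(rec, "seq", rec)))
        for base in BASES:
            counts[base] += seq.count(base)
        skipped += seq.count("N")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in input")
    return BaseComposition(
        *(counts[b] / total for b in BASES), n_counted=total, n_skipped=skipped
    )


def random_sequences(
    comp: BaseComposition, length: int, count: int, rng_seed: int
) -> list:
    """``count`` i.i.d. sequences of ``length`` bases drawn from ``comp``."""
    if length < 1 or count < 1:
        raise ValueError("length and count must be >= 1")
    rng = np.random.default_rng(rng_seed)
    codes = rng.choice(4, size=(count, length), p=np.asarray(comp.as_tuple()))
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in codes]


def random_base_matrix(
    comp: BaseComposition, length: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uint8 base-code matrix (A=0..T=3) for the vectorised scanner."""
    p = np.asarray(comp.as_tuple())
    if np.allclose(p, 0.25):
        return rng.integers(0, 4, size=(count, length), dtype=np.uint8)
    return rng.choice(4, size=(count, length), p=p).astype(np.uint8)


def implant_motif(
    seq: str,
    peptide: str,
    frame: int,
    aa_pos: int,
    rng_seed: int,
    pattern: Optional[MotifPattern] = None,
) -> str:
    """Back-translate ``peptide`` with random synonymous codons and splice it
    into ``seq`` at the given frame and peptide position.

    The peptide must itself match ``pattern`` (default C2H2) so the returned
    sequence is guaranteed to contain a scannable motif at the implant site.
    """
    seq = validate_dna(seq)
    if not peptide:
        raise ValueError("peptide must be non-empty")
    pattern = pattern or MotifPattern.c2h2()
    if match_at(peptide, 0, pattern) != len(peptide):
        raise ValueError("peptide does not match the motif pattern end-to-end")
    rng = np.random.default_rng(rng_seed)
    dna = "".join(
        _SYNONYMOUS[aa][rng.integers(len(_SYNONYMOUS[aa]))] for aa in peptide
    )
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError("frame must be one of +-1, +-2, +-3")
    work = seq if frame > 0 else reverse_complement(seq)
    offset = abs(frame) - 1
    start = offset + 3 * aa_pos
    end = start + len(dna)
    if aa_pos < 0 or end > len(work):
        raise ValueError("implant does not fit in the sequence at this frame/position")
    work = work[:start] + dna + work[end:]
    return work if frame > 0 else reverse_complement(work)


# ---------------------------------------------------------------------------
# Neutral coalescent machinery
# ---------------------------------------------------------------------------


def coalescent_branches(n: int, rng: np.random.Generator):
    """Simulate one Kingman coalescent genealogy for ``n`` samples.

    Returns ``(lengths, leafsets)`` for the 2n−2 non-root branches: waiting
    times are exponential with rate C(k,2) while k lineages remain, each pair
    equally likely to coalesce.
    """
    lengths = []
    leafsets = []
    active = [(frozenset([i]), 0.0) for i in range(n)]
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(1.0 / (k * (k - 1) / 2))
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        (set_j, birth_j) = active.pop(j)
        (set_i, birth_i) = active.pop(i)
        for s, birth in ((set_i, birth_i), (set_j, birth_j)):
            lengths.append(t - birth)
            leafsets.append(s)
        active.append((set_i | set_j, t))
        k -= 1
    return np.asarray(lengths), leafsets


def coalescent_sfs_counts(
    n: int, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Derived-allele counts of ``S`` infinite-sites mutations on one neutral
    genealogy, mutations placed on branches proportional to branch length.

    This is the fixed-S device used for simulation-based neutrality p-values;
    only the site-frequency information is returned (no sequences are built).
    """
    lengths, leafsets = coalescent_branches(n, rng)
    sizes = np.fromiter((len(s) for s in leafsets), dtype=np.int64)
    branch = rng.choice(len(lengths), size=S, p=lengths / lengths.sum())
    return sizes[branch]


def _materialize(
    n: int,
    carrier_sets: Sequence[frozenset],
    outgroup_divergence_mutations: int,
    rng: np.random.Generator,
) -> PopAlignment:
    """Build concrete sequences from per-column carrier sets (ancestral A,
    derived base drawn uniformly from C/G/T), appending private outgroup
    columns."""
    S = len(carrier_sets)
    extra = outgroup_divergence_mutations
    L = S + extra
    sample = np.full((n, L), "A", dtype="U1")
    outgroup = np.full(L, "A", dtype="U1")
    derived = rng.choice(list("CGT"), size=L)
    for col, carriers in enumerate(carrier_sets):
        for leaf in carriers:
            sample[leaf, col] = derived[col]
    for col in range(S, L):
        outgroup[col] = derived[col]
    names = [f"sample_{i}" for i in range(n)]
    return PopAlignment(
        names=names,
        seqs=["".join(row) for row in sample],
        outgroups={"outgroup": "".join(outgroup)},
    )


def coalescent_sample(
    n: int,
    theta: float,
    rng_seed,
    outgroup_divergence_mutations: int = 0,
    condition_on_S: Optional[int] = None,
) -> PopAlignment:
    """A neutral infinite-sites coalescent sample as a concrete alignment.

    Mutations arrive as a Poisson process with rate θ/2 per unit branch
    length; with ``condition_on_S`` exactly that many mutations are placed on
    branches chosen proportional to length instead.  The outgroup carries the
    ancestral allele at every sample column plus
    ``outgroup_divergence_mutations`` private derived columns.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if condition_on_S is None and theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(rng_seed)
    lengths, leafsets = coalescent_branches(n, rng)
    total = lengths.sum()
    S = (
        condition_on_S
        if condition_on_S is not None
        else rng.poisson(theta / 2.0 * total)
    )
    if S:
        branch = rng.choice(len(lengths), size=S, p=lengths / total)
        carriers = [leafsets[b] for b in branch]
    else:
        carriers = []
    return _materialize(n, carriers, outgroup_divergence_mutations, rng)


def skewed_sample(
    n: int,
    S: int,
    allele_count_weights: Mapping[int, float],
    rng_seed,
) -> PopAlignment:
    """An alignment with a distorted site-frequency spectrum.

    Each of the ``S`` biallelic columns draws its derived-allele count from
    ``allele_count_weights`` (over 1..n−1) and its carriers uniformly; the
    outgroup is the all-ancestral sequence, so polarisation recovers the
    planted spectrum exactly.
    """
    counts = sorted(allele_count_weights)
    if not counts or any(c < 1 or c > n - 1 for c in counts):
        raise ValueError("weights must cover derived counts within 1..n-1")
    w = np.asarray([allele_count_weights[c] for c in counts], dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("weights must be non-negative and not all zero")
    rng = np.random.default_rng(rng_seed)
    drawn = rng.choice(len(counts), size=S, p=w / w.sum())
    carriers = [
        frozenset(rng.choice(n, size=counts[d], replace=False).tolist())
        for d in drawn
    ]
    return _materialize(n, carriers, 0, rng)


# ---------------------------------------------------------------------------
# CDS mutagenesis (fixtures for the degeneration classifier)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one synthetic mutation.

    ``ref_start`` follows the event-table convention: for substitutions and
    deletions, the 1-based reference coordinate of the (first) affected base;
    for insertions, the 1-based coordinate of the reference base immediately
    after the insertion point.
    """

    kind: str  # substitution | insertion | deletion
    ref_start: int
    length: int
    frame_effect: str  # in_frame | frameshift | n/a


def mutate_cds(
    ref: str,
    k: int,
    rng_seed,
    max_indel: int = 6,
    min_spacing: int = 12,
    kinds: Sequence[str] = ("substitution", "insertion", "deletion"),
):
    """Plant ``k`` non-overlapping mutations in a CDS; returns
    ``(query, planted_events)`` with events sorted by reference position.

    Indels are placed so that they are not left-shiftable (the flanking base
    differs from the relevant indel edge), making the left-aligned coordinate
    reported by the classifier coincide with the planted one.
    """
    ref = validate_dna(ref)
    rng = np.random.default_rng(rng_seed)
    L = len(ref)
    planted = []  # (PlantedEvent, insertion segment or None, (lo, hi) interval)

    def free(lo, hi):
        return all(
            hi + min_spacing <= a or b + min_spacing <= lo for _, _, (a, b) in planted
        )

    attempts = 0
    while len(planted) < k:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place all mutations; sequence too short")
        kind = kinds[rng.integers(len(kinds))]
        if kind == "substitution":
            pos = int(rng.integers(3, L - 3))
            if not free(pos, pos + 1):
                continue
            planted.append(
                (PlantedEvent("substitution", pos + 1, 1, "n/a"), None, (pos, pos + 1))
            )
        elif kind == "deletion":
            length = int(rng.integers(1, max_indel + 1))
            pos = int(rng.integers(3, L - 3 - length))
            # not shiftable: flanking bases differ from the run's edges
            if ref[pos - 1] == ref[pos + length - 1] or ref[pos] == ref[pos + length]:
                continue
            if not free(pos - 1, pos + length + 1):
                continue
            fe = "in_frame" if length % 3 == 0 else "frameshift"
            planted.append(
                (
                    PlantedEvent("deletion", pos + 1, length, fe),
                    None,
                    (pos, pos + length),
                )
            )
        else:
            length = int(rng.integers(1, max_indel + 1))
            pos = int(rng.integers(3, L - 3))  # insert before ref base `pos`
            if not free(pos - 1, pos + 1):
                continue
            # segment edges differ from the flanks: not shiftable either way
            # (first base != right flank blocks rightward rotation, last base
            # != left flank blocks leftward shift)
            first_ok = [b for b in BASES if b != ref[pos]]
            last_ok = [b for b in BASES if b != ref[pos - 1]]
            if length == 1:
                choices = [b for b in first_ok if b in last_ok]
                segment = choices[rng.integers(len(choices))]
            else:
                middle = rng.choice(list(BASES), size=length - 2).tolist()
                segment = (
                    first_ok[rng.integers(3)]
                    + "".join(middle)
                    + last_ok[rng.integers(3)]
                )
            fe = "in_frame" if length % 3 == 0 else "frameshift"
            planted.append(
                (PlantedEvent("insertion", pos + 1, length, fe), segment, (pos, pos))
            )

    # apply right-to-left so earlier coordinates stay valid
    qry = list(ref)
    for ev, segment, _ in sorted(planted, key=lambda t: -t[0].ref_start):
        pos = ev.ref_start - 1
        if ev.kind == "substitution":
            alt = [b for b in BASES if b != ref[pos]]
            qry[pos] = alt[rng.integers(3)]
        elif ev.kind == "deletion":
            del qry[pos : pos + ev.length]
        else:
            qry[pos:pos] = list(segment)
    events = sorted((ev for ev, _, _ in planted), key=lambda e: (e.ref_start, e.kind))
    return "".join(qry), events


def random_cds(n_codons: int, rng_seed) -> str:
    """A random open reading frame: ATG start, no internal stops, one stop."""
    rng = np.random.default_rng(rng_seed)
    sense = [c for c, aa in _CODON_TABLE.items() if aa != "*" and c != "ATG"]
    stops = [c for c, aa in _CODON_TABLE.items() if aa == "*"]
    body = [sense[i] for i in rng.integers(len(sense), size=n_codons - 2)]
    return "ATG" + "".join(body) + stops[rng.integers(len(stops))]
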