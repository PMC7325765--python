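"""Independent oracle implementations used only by the tests.

Each oracle is written from scratch against the published definitions, not by
calling the package internals, so agreement is a genuine cross-check:

* a second six-frame translator built directly on Biopython's codon table;
* a brute-force motif matcher that enumerates every (start, gap-combination)
  pair;
* exact-fractions transcriptions of the Tajima and Fu & Li variance
  coefficients;
* a brute-force pair/site counter for alignment summaries;
* a full-matrix affine-gap (Gotoh) dynamic program for alignment scores.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from Bio.Data.CodonTable import standard_dna_table

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_translate(dna: str) -> str:
    dna = dna.upper()
    out = []
    for i in range(len(dna) // 3):
        codon = dna[3 * i : 3 * i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in standard_dna_table.stop_codons:
            out.append("*")
        else:
            out.append(standard_dna_table.forward_table[codon])
    return "".join(out)


def oracle_six_frames(dna: str) -> dict:
    rc = "".join(COMPLEMENT[b] for b in reversed(dna.upper()))
    return {
        1: oracle_translate(dna),
        2: oracle_translate(dna[1:]),
        3: oracle_translate(dna[2:]),
        -1: oracle_translate(rc),
        -2: oracle_translate(rc[1:]),
        -3: oracle_translate(rc[2:]),
    }


def oracle_match_lengths(peptide: str, start: int, elements) -> list:
    """All gap expansions of ``elements`` matching ``peptide`` at ``start``,
    as a list of total lengths (duplicates removed, sorted)."""
    lengths = set()
    for combo in itertools.product(*(e.repeats for e in elements)):
        total = sum(combo)
        if start + total > len(peptide):
            continue
        pos = start
        ok = True
        for element, count in zip(elements, combo):
            for _ in range(count):
                if peptide[pos] not in element.residues:
                    ok = False
                    break
                pos += 1
            if not ok:
                break
        if ok:
            lengths.add(total)
    return sorted(lengths)


def oracle_scan(dna: str, pattern) -> list:
    """Brute-force (frame, aa_start, shortest length) triples for every frame
    peptide, enumerating all starts and all gap combinations."""
    hits = []
    for frame, pep in oracle_six_frames(dna).items():
        for start in range(len(pep)):
            lengths = oracle_match_lengths(pep, start, pattern.elements)
            if lengths:
                hits.append((frame, start, lengths[0]))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Exact coefficient transcriptions
# ---------------------------------------------------------------------------


def exact_tajima_coefficients(n: int) -> dict:
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def exact_fu_li_coefficients(n: int) -> dict:
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    an1 = a1 + Fraction(1, n)
    cn = Fraction(2, (n - 1) * (n - 2)) * (n * a1 - 2 * (n - 1))
    v_D = 1 + (a1**2 / (a2 + a1**2)) * (cn - Fraction(n + 1, n - 1))
    u_D = a1 - 1 - v_D
    v_F = (cn + Fraction(2 * (n * n + n + 3), 9 * n * (n - 1)) - Fraction(2, n - 1)) / (
        a1**2 + a2
    )
    u_F = (
        1
        + Fraction(n + 1, 3 * (n - 1))
        - 4 * Fraction(n + 1, (n - 1) ** 2) * (an1 - Fraction(2 * n, n + 1))
    ) / a1 - v_F
    return {"u_D": u_D, "v_D": v_D, "u_F": u_F, "v_F": v_F}


# ---------------------------------------------------------------------------
# Brute-force alignment summary
# ---------------------------------------------------------------------------


def oracle_site_summary(sample: list, outgroup: str | None = None) -> dict:
    """π, S, η, η_e by direct pairwise/sitewise counting under complete
    deletion."""
    n = len(sample)
    L = len(sample[0])
    keep = []
    for col in range(L):
        column = [s[col] for s in sample]
        if outgroup is not None:
            column = column + [outgroup[col]]
        if all(b in "ACGT" for b in column):
            keep.append(col)
    # pi: average pairwise differences over kept columns
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += sum(1 for col in keep if sample[i][col] != sample[j][col])
    pi = diffs / (n * (n - 1) / 2)
    S = eta = eta_e = 0
    for col in keep:
        alleles = {}
        for s in sample:
            alleles[s[col]] = alleles.get(s[col], 0) + 1
        if len(alleles) > 1:
            S += 1
            eta += len(alleles) - 1
            if outgroup is not None and len(alleles) == 2:
                ob = outgroup[col]
                if ob in alleles:
                    derived = next(b for b in alleles if b != ob)
                    if alleles[derived] == 1:
                        eta_e += 1
    return {"L_used": len(keep), "S": S, "eta": eta, "pi": pi,
            "eta_e": eta_e if outgroup is not None else None}


# ---------------------------------------------------------------------------
# Full-matrix affine alignment score (Gotoh)
# ---------------------------------------------------------------------------


def oracle_affine_score(
    a: str, b: str, match=5.0, mismatch=-4.0, open_=-10.0, extend=-0.5
) -> float:
    """Optimal global alignment score with affine gaps (gap of length L costs
    |open| + |extend|*(L-1)), by the three-matrix recurrence."""
    NEG = float("-inf")
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = open_ + extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = open_ + extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    return max(M[la][lb], X[la][lb], Y[la][lb])
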