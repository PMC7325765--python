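"""Ortholog CDS degeneration reports.

Given a reference CDS (an intact open reading frame) and a query ortholog,
produce an explicit event list — substitutions typed synonymous /
nonsynonymous / stop-gain, indels typed in-frame / frameshift — and an
overall ORF status verdict.  The rules a curator applies by eye are made
mechanical here:

* contiguous gap runs in the pairwise alignment are single indel events;
* an indel whose length is a multiple of 3 is in-frame, otherwise it shifts
  the downstream reading frame;
* substitutions are typed by translating the reference codon with and
  without the substituted base(s), but only while the running frame offset
  is a multiple of 3 — downstream of an uncompensated frameshift the codon
  correspondence is lost and substitutions are left unclassified;
* the verdict is ``frameshifted`` as soon as the running frame offset is
  ever nonzero (mod 3), else ``premature_stop`` if any in-frame codon gained
  a stop, else ``intact_with_inframe_indels`` / ``intact``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from Bio import Align

from .motif import _CODON_TABLE, validate_dna

GAP = "-"


@dataclass(frozen=True)
class CdsEvent:
    """One difference between query and reference.

    ``ref_start`` is 1-based on the ungapped reference CDS: the first affected
    base for substitutions/deletions, the base immediately after the insertion
    point for insertions.
    """

    kind: str  # substitution | insertion | deletion
    ref_start: int
    length: int
    frame_effect: str  # in_frame | frameshift | n/a
    coding_effect: str  # synonymous | nonsynonymous | stop_gain | unclassified
    ref_base: str = ""
    qry_base: str = ""


@dataclass
class CdsComparison:
    """Event list, per-category counts, and the ORF status verdict."""

    events: List[CdsEvent]
    status: str  # intact | frameshifted | premature_stop | intact_with_inframe_indels

    @property
    def counts(self) -> dict:
        c = {
            "substitutions": 0,
            "synonymous": 0,
            "nonsynonymous": 0,
            "stop_gain": 0,
            "unclassified": 0,
            "insertions": 0,
            "deletions": 0,
            "in_frame_indels": 0,
            "frameshift_indels": 0,
        }
        for e in self.events:
            if e.kind == "substitution":
                c["substitutions"] += 1
                c[e.coding_effect] += 1
            else:
                c[e.kind + "s"] += 1
                key = "in_frame_indels" if e.frame_effect == "in_frame" else "frameshift_indels"
                c[key] += 1
        return c

    def to_dict(self) -> dict:
        return {"status": self.status, "counts": self.counts}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_pair(ref_cds: str, qry_cds: str) -> Tuple[str, str]:
    """Global affine-gap alignment of two CDSs.

    Scores: match +5, mismatch −4, gap open −10, gap extend −0.5 (a length-L
    gap costs 10 + 0.5·(L−1)).  The optimal alignment is made canonical by
    shifting every gap run as far left as the flanking context allows, so
    event coordinates are deterministic.  Returns the two aligned strings
    (reference first).
    """
    ref = validate_dna(ref_cds)
    qry = validate_dna(qry_cds)
    if not ref or not qry:
        raise ValueError("both sequences must be non-empty")
    alignment = _make_aligner().align(ref, qry)[0]
    return normalize_gaps(str(alignment[0]), str(alignment[1]))


def alignment_score(ref_aln: str, qry_aln: str) -> float:
    """Score of an aligned pair under the align_pair scoring scheme."""
    score = 0.0
    prev_gap = None  # which row the open gap is in
    for a, b in zip(ref_aln, qry_aln):
        if a == GAP or b == GAP:
            row = 0 if a == GAP else 1
            score += -0.5 if prev_gap == row else -10.0
            prev_gap = row
        else:
            score += 5.0 if a == b else -4.0
            prev_gap = None
    return score


def normalize_gaps(ref_aln: str, qry_aln: str) -> Tuple[str, str]:
    """Shift each gap run leftward while the alignment score is unchanged.

    A run may move one column left when the preceding column is ungapped in
    both rows and the non-gapped row has equal bases at the run's two ends —
    the same canonicalisation as VCF indel left-alignment.
    """
    ref = list(ref_aln)
    qry = list(qry_aln)
    changed = True
    while changed:
        changed = False
        col = 0
        L = len(ref)
        while col < L:
            if ref[col] != GAP and qry[col] != GAP:
                col += 1
                continue
            gap_row, base_row = (ref, qry) if ref[col] == GAP else (qry, ref)
            run_start = col
            run_end = col
            while run_end < L and gap_row[run_end] == GAP and base_row[run_end] != GAP:
                run_end += 1
            while (
                run_start > 0
                and ref[run_start - 1] != GAP
                and qry[run_start - 1] != GAP
                and base_row[run_start - 1] == base_row[run_end - 1]
            ):
                # rotate: the base before the run moves to the run's end
                gap_row[run_end - 1] = gap_row[run_start - 1]
                gap_row[run_start - 1] = GAP
                run_start -= 1
                run_end -= 1
                changed = True
            col = max(run_end, col + 1)
    return "".join(ref), "".join(qry)


def _aligned_query_bases(ref_aln: str, qry_aln: str, ref_len: int) -> List[Optional[str]]:
    """For each ungapped reference position, the query base aligned to it
    (None where the query has a gap)."""
    out: List[Optional[str]] = []
    for a, b in zip(ref_aln, qry_aln):
        if a != GAP:
            out.append(None if b == GAP else b)
    assert len(out) == ref_len
    return out


def classify_events(
    ref_aln: str,
    qry_aln: str,
    ref_is_frame_1: bool = True,
    relax_length: bool = False,
) -> CdsComparison:
    """Turn an aligned reference/query pair into a degeneration report.

    The reference must be a complete CDS (length divisible by 3) unless
    ``relax_length``; ``ref_is_frame_1`` declares that codon 1 starts at
    reference base 1.
    """
    if len(ref_aln) != len(qry_aln):
        raise ValueError("aligned strings must have equal length")
    ref_seq = ref_aln.replace(GAP, "")
    if not ref_is_frame_1:
        raise NotImplementedError("only frame-1 references are supported")
    if len(ref_seq) % 3 and not relax_length:
        raise ValueError(
            "reference CDS length is not divisible by 3; pass relax_length=True "
            "to classify anyway"
        )

    events: List[CdsEvent] = []
    qry_at = _aligned_query_bases(ref_aln, qry_aln, len(ref_seq))

    # walk columns: collect indel runs and substitution columns with the
    # running frame offset in force where each event starts
    offset = 0
    ever_shifted = False
    ref_pos = 0  # 0-based position of the next reference base
    col = 0
    L = len(ref_aln)
    subs: List[Tuple[int, int]] = []  # (ref_pos 0-based, offset at that point)
    while col < L:
        a, b = ref_aln[col], qry_aln[col]
        if a == GAP and b == GAP:
            col += 1
            continue
        if a == GAP:  # insertion in query
            run = col
            while run < L and ref_aln[run] == GAP and qry_aln[run] != GAP:
                run += 1
            length = run - col
            fe = "in_frame" if length % 3 == 0 else "frameshift"
            events.append(
                CdsEvent("insertion", ref_pos + 1, length, fe, "unclassified")
            )
            offset += length
            if offset % 3:
                ever_shifted = True
            col = run
            continue
        if b == GAP:  # deletion in query
            run = col
            while run < L and qry_aln[run] == GAP and ref_aln[run] != GAP:
                run += 1
            length = run - col
            fe = "in_frame" if length % 3 == 0 else "frameshift"
            events.append(CdsEvent("deletion", ref_pos + 1, length, fe, "unclassified"))
            offset -= length
            if offset % 3:
                ever_shifted = True
            ref_pos += length
            col = run
            continue
        if a != b:
            subs.append((ref_pos, offset))
        ref_pos += 1
        col += 1

    # type the substitutions codon-wise
    for pos, off in subs:
        codon_i = pos // 3
        ref_codon = ref_seq[3 * codon_i : 3 * codon_i + 3]
        if off % 3 != 0 or len(ref_codon) < 3:
            effect = "unclassified"
        else:
            qry_codon = [
                qry_at[3 * codon_i + j] if 3 * codon_i + j < len(qry_at) else None
                for j in range(3)
            ]
            if any(b is None for b in qry_codon) or "N" in ref_codon or "N" in qry_codon:
                effect = "unclassified"
            else:
                ref_aa = _CODON_TABLE[ref_codon]
                qry_aa = _CODON_TABLE["".join(qry_codon)]
                if qry_aa == "*" and ref_aa != "*":
                    effect = "stop_gain"
                elif qry_aa == ref_aa:
                    effect = "synonymous"
                else:
                    effect = "nonsynonymous"
        events.append(
            CdsEvent(
                "substitution", pos + 1, 1, "n/a", effect,
                ref_base=ref_seq[pos],
                qry_base=qry_at[pos] or "",
            )
        )

    events.sort(key=lambda e: (e.ref_start, e.kind))

    if ever_shifted:
        status = "frameshifted"
    elif any(e.coding_effect == "stop_gain" for e in events):
        status = "premature_stop"
    elif any(e.kind in ("insertion", "deletion") for e in events):
        status = "intact_with_inframe_indels"
    else:
        status = "intact"
    return CdsComparison(events=events, status=status)


def compare_cds(
    ref_cds: str,
    qry_cds: str,
    aligned: bool = False,
    relax_length: bool = False,
) -> CdsComparison:
    """Align (unless ``aligned``) and classify in one call."""
    if aligned:
        ref_aln, qry_aln = normalize_gaps(ref_cds.upper(), qry_cds.upper())
    else:
        ref_aln, qry_aln = align_pair(ref_cds, qry_cds)
    return classify_events(ref_aln, qry_aln, relax_length=relax_length)
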