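"""Neutrality statistics on population alignments.

Implements the classical frequency-spectrum tests used to detect departures
from the standard neutral model on a sample of aligned sequences:

* Tajima's D — contrasts the mean pairwise difference π with the Watterson
  estimate S/a1; positive values indicate an excess of intermediate-frequency
  variants (e.g. after balancing selection or a soft sweep), negative values
  an excess of rare variants.
* Fu & Li's D and F (outgroup versions) — contrast the total mutation count η
  (D) or π (F) with the external-branch mutation count η_e, the number of
  derived singletons polarised against an outgroup.

Site handling is complete deletion: any column holding a gap or an N in any
sample sequence (or in the selected outgroup, when polarisation is requested)
is dropped before anything is counted.  Significance is assessed by neutral
coalescent simulation conditioned on the observed number of segregating
sites rather than by lookup tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

_VALID = set("ACGT")
_ALPHABET = set("ACGT-N")


@dataclass
class PopAlignment:
    """An aligned population sample plus zero or more labelled outgroups.

    All sequences (sample and outgroups) must have equal length over the
    alphabet {A,C,G,T,-,N}.  ``site_policy`` is fixed to complete deletion.
    """

    names: List[str]
    seqs: List[str]
    outgroups: Dict[str, str] = field(default_factory=dict)
    site_policy: str = "complete_deletion"

    def __post_init__(self):
        self.seqs = [s.upper() for s in self.seqs]
        self.outgroups = {k: v.upper() for k, v in self.outgroups.items()}
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs must be parallel")
        lengths = {len(s) for s in self.seqs} | {len(s) for s in self.outgroups.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.site_policy != "complete_deletion":
            raise ValueError("only complete_deletion is supported")
        for s in list(self.seqs) + list(self.outgroups.values()):
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"invalid alignment symbols: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @classmethod
    def from_fasta(cls, path, outgroup_labels: Sequence[str] = ()) -> "PopAlignment":
        """Read an aligned FASTA; records whose ids are in ``outgroup_labels``
        become outgroups, the rest the sample."""
        from Bio import SeqIO

        names, seqs, outgroups = [], [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in outgroup_labels:
                outgroups[rec.id] = str(rec.seq)
            else:
                names.append(rec.id)
                seqs.append(str(rec.seq))
        missing = set(outgroup_labels) - set(outgroups)
        if missing:
            raise ValueError(f"outgroup ids not found in FASTA: {sorted(missing)}")
        return cls(names=names, seqs=seqs, outgroups=outgroups)


@dataclass(frozen=True)
class SiteSummary:
    """Per-alignment site counts feeding the test statistics.

    η sums (alleles − 1) over retained sites; η_e counts outgroup-polarised
    derived singletons and is None when no outgroup was selected.
    """

    n: int
    L_used: int
    S: int
    eta: int
    pi: float
    eta_e: Optional[int] = None


def summarize(aln: PopAlignment, outgroup_label: Optional[str] = None) -> SiteSummary:
    """Site summary under complete deletion.

    A site enters η_e when it is biallelic in the sample, the outgroup allele
    is one of the two sample alleles, and the other allele occurs exactly
    once; sites where the outgroup carries a third allele are excluded from
    η_e but still counted in S, η and π.
    """
    n = aln.n
    if n < 2:
        raise ValueError("need at least 2 sample sequences")
    outseq = None
    if outgroup_label is not None:
        if outgroup_label not in aln.outgroups:
            raise ValueError(f"unknown outgroup label {outgroup_label!r}")
        outseq = aln.outgroups[outgroup_label]

    L = aln.length
    pairs = n * (n - 1) / 2
    L_used = S = eta = 0
    eta_e = 0 if outseq is not None else None
    pi_sum = 0.0
    for col in range(L):
        states = [s[col] for s in aln.seqs]
        if any(b not in _VALID for b in states):
            continue
        ob = outseq[col] if outseq is not None else None
        if outseq is not None and ob not in _VALID:
            continue  # complete deletion includes the selected outgroup
        L_used += 1
        counts = {}
        for b in states:
            counts[b] = counts.get(b, 0) + 1
        k = len(counts)
        if k == 1:
            continue
        S += 1
        eta += k - 1
        hom = sum(c * (c - 1) / 2 for c in counts.values())
        pi_sum += (pairs - hom) / pairs
        if eta_e is not None and k == 2 and ob in counts:
            other = next(b for b in counts if b != ob)
            if counts[other] == 1:
                eta_e += 1
    if L_used == 0:
        raise ValueError(
            "no sites survive complete deletion (every column has a gap or N)"
        )
    return SiteSummary(n=n, L_used=L_used, S=S, eta=eta, pi=pi_sum, eta_e=eta_e)


# ---------------------------------------------------------------------------
# Variance coefficients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoefficientSet:
    """Sample-size-only variance coefficients of the neutrality statistics:
    a1..e2 for Tajima's D, u/v for the outgroup Fu & Li D and F (with the
    Simonsen–Churchill–Aquadro-corrected F variance)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    u_D: float
    v_D: float
    u_F: float
    v_F: float


def coefficients(n: int) -> CoefficientSet:
    """All twelve coefficients for sample size ``n`` (n ≥ 4)."""
    if n < 4:
        raise ValueError("n must be >= 4 (statistics degenerate below that)")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)

    c_n = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_D = 1.0 + (a1**2 / (a2 + a1**2)) * (c_n - (n + 1) / (n - 1))
    u_D = a1 - 1.0 - v_D

    a1_np1 = a1 + 1.0 / n  # harmonic sum to n, i.e. a1 evaluated at n+1
    v_F = (c_n + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (
        a1**2 + a2
    )
    u_F = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * ((n + 1) / (n - 1) ** 2) * (a1_np1 - 2.0 * n / (n + 1))
    ) / a1 - v_F

    return CoefficientSet(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        u_D=u_D, v_D=v_D, u_F=u_F, v_F=v_F,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def tajimas_d(summary: SiteSummary) -> float:
    """Tajima's D = (π − S/a1) / sqrt(e1·S + e2·S·(S−1)); NaN when S = 0."""
    c = coefficients(summary.n)
    S = summary.S
    if S == 0:
        return math.nan
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (summary.pi - S / c.a1) / math.sqrt(var)


def fu_li_tests(summary: SiteSummary):
    """Outgroup Fu & Li statistics.

    D = (η − a1·η_e)/sqrt(u_D·η + v_D·η²) and
    F = (π − η_e)/sqrt(u_F·η + v_F·η²); both NaN when η = 0.
    Requires an outgroup-polarised summary (η_e set).
    """
    if summary.eta_e is None:
        raise ValueError(
            "Fu & Li's outgroup tests need a polarised summary; pass an "
            "outgroup to summarize() (the within-sample starred variants are "
            "not implemented)"
        )
    c = coefficients(summary.n)
    eta, eta_e = summary.eta, summary.eta_e
    if eta == 0:
        return math.nan, math.nan
    var_d = c.u_D * eta + c.v_D * eta**2
    var_f = c.u_F * eta + c.v_F * eta**2
    d = (eta - c.a1 * eta_e) / math.sqrt(var_d) if var_d > 0 else math.nan
    f = (summary.pi - eta_e) / math.sqrt(var_f) if var_f > 0 else math.nan
    return d, f


def _stat_from_counts(name: str, counts: np.ndarray, n: int, c: CoefficientSet):
    """Statistic value from a vector of derived-allele counts (infinite
    sites: every mutation is one biallelic column)."""
    S = len(counts)
    counts = np.asarray(counts)
    pi = float((counts * (n - counts)).sum() / (n * (n - 1) / 2))
    if name == "tajima_d":
        var = c.e1 * S + c.e2 * S * (S - 1)
        return (pi - S / c.a1) / math.sqrt(var)
    eta = S
    eta_e = int((counts == 1).sum())
    if name == "fuli_d":
        return (eta - c.a1 * eta_e) / math.sqrt(c.u_D * eta + c.v_D * eta**2)
    if name == "fuli_f":
        return (pi - eta_e) / math.sqrt(c.u_F * eta + c.v_F * eta**2)
    raise ValueError(f"unknown statistic {name!r}")


def simulate_null(
    statistic_name: str, n: int, S: int, n_reps: int, rng_seed
) -> np.ndarray:
    """Null distribution of a statistic under the standard neutral coalescent
    conditioned on S segregating sites (mutations placed on branches
    proportional to branch length)."""
    from .synthetic import coalescent_sfs_counts  # local import: cycle with synthetic

    rng = np.random.default_rng(rng_seed)
    c = coefficients(n)
    out = np.empty(n_reps)
    for r in range(n_reps):
        counts = coalescent_sfs_counts(n, S, rng)
        out[r] = _stat_from_counts(statistic_name, counts, n, c)
    return out


def neutrality_pvalue(
    statistic_name: str,
    observed_value: float,
    n: int,
    S: int,
    n_reps: int = 1000,
    rng_seed: int = 0,
) -> float:
    """Two-sided simulation p-value for an observed statistic.

    ``p = (r + 1) / (n_reps + 1)`` where r counts null replicates at least as
    extreme in absolute value; rank-based, hence uniform under the null.
    """
    if not math.isfinite(observed_value):
        raise ValueError("observed statistic is undefined; no p-value")
    if S < 1:
        raise ValueError("S must be >= 1 for a conditional null")
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000 for a stable p-value")
    null = simulate_null(statistic_name, n, S, n_reps, rng_seed)
    r = int((np.abs(null) >= abs(observed_value)).sum())
    return (r + 1) / (n_reps + 1)


@dataclass(frozen=True)
class NeutralityStats:
    """The three statistics with their simulation p-values and defined flags."""

    tajima_d: float
    fuli_d: float
    fuli_f: float
    p_tajima: Optional[float] = None
    p_fuli_d: Optional[float] = None
    p_fuli_f: Optional[float] = None
    n_reps: int = 0
    rng_seed: Optional[int] = None

    @property
    def defined_flags(self) -> Dict[str, bool]:
        return {
            "tajima_d": math.isfinite(self.tajima_d),
            "fuli_d": math.isfinite(self.fuli_d),
            "fuli_f": math.isfinite(self.fuli_f),
        }


def neutrality_stats(
    aln: PopAlignment,
    outgroup_label: Optional[str] = None,
    n_reps: int = 1000,
    rng_seed: int = 0,
    compute_pvalues: bool = True,
) -> "tuple[SiteSummary, NeutralityStats]":
    """End-to-end: summarise the alignment and compute every defined statistic
    with simulation p-values."""
    summary = summarize(aln, outgroup_label)
    d = tajimas_d(summary)
    if outgroup_label is not None:
        fd, ff = fu_li_tests(summary)
    else:
        fd = ff = math.nan
    pvals = {}
    if compute_pvalues and summary.S >= 1:
        for name, value in (("tajima_d", d), ("fuli_d", fd), ("fuli_f", ff)):
            if math.isfinite(value):
                pvals[name] = neutrality_pvalue(
                    name, value, summary.n, summary.S, n_reps, rng_seed
                )
    stats = NeutralityStats(
        tajima_d=d,
        fuli_d=fd,
        fuli_f=ff,
        p_tajima=pvals.get("tajima_d"),
        p_fuli_d=pvals.get("fuli_d"),
        p_fuli_f=pvals.get("fuli_f"),
        n_reps=n_reps if pvals else 0,
        rng_seed=rng_seed,
    )
    return summary, stats
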