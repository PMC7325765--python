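"""Monte Carlo campaign for de novo C2H2 motif origination.

One simulation draws T = floor(genome_size / seed_length) random seed
sequences with genome-matched base frequencies and counts the C2H2 motif
matches over all six reading frames of every seed.  Across ``n_sims``
simulations, the origination probability is the fraction whose total count
reaches the expected number of ancestral starter genes.

Two execution modes:

``stream``
    Every simulation regenerates its T seeds and scans them (exact, memory
    bounded: seeds are generated and scanned in chunks, never all at once).

``two_stage``
    The per-seed match probability p̂ is first estimated from ``n_rate_est``
    fresh seeds, then each simulation's count is drawn from Binomial(T, p̂).
    Exact when seeds are i.i.d. and multi-match seeds are negligible (at 90 bp
    they are vanishingly rare); this makes genome-scale T desk-feasible.

Reproducibility: one integer seed; each simulation uses a substream derived
from (rng_seed, stream tag, simulation index), so results do not depend on
execution order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .motif import MotifPattern, count_matches_batch
from .synthetic import BaseComposition, random_base_matrix

_RATE_TAG = 0
_SIM_TAG = 1

#: Genome-scale defaults for a rice-sized campaign: assembly span of the
#: O. sativa reference nuclear genome (~373 Mb) and its ~43.6% GC
#: mononucleotide composition (A, C, G, T).  Used when no genome FASTA is
#: supplied to derive composition from.
RICE_GENOME_SIZE = 373_245_519
RICE_BASE_FREQS = (0.282, 0.218, 0.218, 0.282)


def seeds_per_simulation(genome_size: int, seed_length: int) -> int:
    """T = floor(genome_size / seed_length); errors when the genome is smaller
    than one seed."""
    if genome_size <= 0 or seed_length <= 0:
        raise ValueError("genome_size and seed_length must be positive")
    T = genome_size // seed_length
    if T == 0:
        raise ValueError(
            f"genome_size {genome_size} is smaller than one seed ({seed_length} bp)"
        )
    return T


@dataclass(frozen=True)
class SimConfig:
    """Campaign parameters.

    Defaults mirror the study conditions: 90-bp seeds, 100,000 simulations,
    five expected starter genes.  ``base_freqs`` are (A, C, G, T).
    """

    genome_size: int
    seed_length: int = 90
    n_sims: int = 100_000
    base_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    expected_count: int = 5
    rng_seed: int = 0
    mode: str = "stream"
    n_rate_est: int = 1_000_000
    count_convention: str = "total_matches"  # or "seeds_with_match"

    def __post_init__(self):
        if self.mode not in ("stream", "two_stage"):
            raise ValueError("mode must be 'stream' or 'two_stage'")
        if self.count_convention not in ("total_matches", "seeds_with_match"):
            raise ValueError("unknown count convention")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.expected_count < 0:
            raise ValueError("expected_count must be >= 0")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base_freqs must be non-negative and sum to 1")
        seeds_per_simulation(self.genome_size, self.seed_length)  # validates T >= 1

    @property
    def T(self) -> int:
        return seeds_per_simulation(self.genome_size, self.seed_length)

    @property
    def composition(self) -> BaseComposition:
        return BaseComposition(*self.base_freqs)


@dataclass(frozen=True)
class SimResult:
    """Campaign output: per-simulation counts and the derived probability."""

    T: int
    counts: np.ndarray
    p_origination: float
    expected_count: int
    rng_seed: int
    mode: str
    per_seed_rate_estimate: Optional[Tuple[float, float]] = None  # (p̂, SE)

    def to_dict(self) -> dict:
        rate, se = self.per_seed_rate_estimate or (None, None)
        return {
            "T": self.T,
            "n_sims": int(len(self.counts)),
            "expected_count": self.expected_count,
            "p_origination": self.p_origination,
            "per_seed_rate_estimate": rate,
            "per_seed_rate_se": se,
            "rng_seed": self.rng_seed,
            "mode": self.mode,
        }


def origination_probability(counts: Sequence[int], expected_count: int) -> float:
    """Fraction of simulations whose motif count reaches ``expected_count``."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if expected_count < 0:
        raise ValueError("expected_count must be >= 0")
    return float((counts >= expected_count).mean())


def estimate_per_seed_rate(
    comp: BaseComposition,
    seed_length: int,
    n_seeds: int,
    rng: np.random.Generator,
    pattern: MotifPattern,
    chunk: int = 100_000,
) -> Tuple[float, float]:
    """(p̂, SE): fraction of random seeds carrying >= 1 motif match."""
    hits = 0
    done = 0
    while done < n_seeds:
        m = min(chunk, n_seeds - done)
        bases = random_base_matrix(comp, seed_length, m, rng)
        hits += int((count_matches_batch(bases, pattern) > 0).sum())
        done += m
    p = hits / n_seeds
    se = math.sqrt(max(p * (1 - p), 1.0 / n_seeds**2) / n_seeds)
    return p, se


def run_simulations(config: SimConfig, pattern: Optional[MotifPattern] = None) -> SimResult:
    """Run the campaign described by ``config`` and return a :class:`SimResult`.

    Determinism: identical configs (including ``rng_seed``) give bitwise
    identical counts; each simulation draws from its own substream.
    """
    pattern = pattern or MotifPattern.c2h2()
    T = config.T
    comp = config.composition
    counts = np.empty(config.n_sims, dtype=np.int64)

    if config.mode == "stream":
        seed_chunk = 200_000  # bases generated at once stay bounded
        for i in range(config.n_sims):
            rng = np.random.default_rng([config.rng_seed, _SIM_TAG, i])
            total = 0
            done = 0
            while done < T:
                m = min(max(seed_chunk // config.seed_length, 1), T - done)
                bases = random_base_matrix(comp, config.seed_length, m, rng)
                per_seed = count_matches_batch(bases, pattern)
                if config.count_convention == "total_matches":
                    total += int(per_seed.sum())
                else:
                    total += int((per_seed > 0).sum())
                done += m
            counts[i] = total
        rate_est = None
    else:
        rate_rng = np.random.default_rng([config.rng_seed, _RATE_TAG])
        p_hat, se = estimate_per_seed_rate(
            comp, config.seed_length, config.n_rate_est, rate_rng, pattern
        )
        if p_hat == 0 and config.n_rate_est < 10**5:
            warnings.warn(
                "per-seed rate estimate is 0 from fewer than 1e5 seeds; "
                "the estimate is uninformative",
                stacklevel=2,
            )
        rate_est = (p_hat, se)
        for i in range(config.n_sims):
            rng = np.random.default_rng([config.rng_seed, _SIM_TAG, i])
            counts[i] = rng.binomial(T, p_hat)

    p = origination_probability(counts, config.expected_count)
    return SimResult(
        T=T,
        counts=counts,
        p_origination=p,
        expected_count=config.expected_count,
        rng_seed=config.rng_seed,
        mode=config.mode,
        per_seed_rate_estimate=rate_est,
    )


def poisson_reference(per_seed_rate: float, T: int, expected_count: int) -> float:
    """Analytic check: P(X >= expected_count) for X ~ Poisson(T * rate).

    Validates the campaign in the Binomial(T, p) → Poisson(Tp) limit.
    """
    if not 0 <= per_seed_rate <= 1:
        raise ValueError("rate must be a probability")
    if T < 1:
        raise ValueError("T must be >= 1")
    if expected_count <= 0:
        return 1.0
    return float(sstats.poisson.sf(expected_count - 1, T * per_seed_rate))


@dataclass(frozen=True)
class CountDensity:
    """Gaussian KDE of the per-simulation counts, evaluable on any grid."""

    counts: np.ndarray
    bandwidth: float

    def grid(self, n_points: int = 512) -> np.ndarray:
        lo = self.counts.min() - 5 * self.bandwidth
        hi = self.counts.max() + 5 * self.bandwidth
        return np.linspace(lo, hi, n_points)

    def evaluate(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.counts[None, :]) / self.bandwidth
        dens = np.exp(-0.5 * z**2).sum(axis=1)
        return dens / (len(self.counts) * self.bandwidth * math.sqrt(2 * math.pi))


def kde_counts(counts: Sequence[int], bandwidth="silverman") -> CountDensity:
    """Gaussian kernel density of the count distribution.

    ``bandwidth`` is an absolute kernel width or ``"silverman"``; a rule-based
    bandwidth on degenerate (single-valued) data falls back to 1 with a
    warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError("bandwidth must be a positive number or 'silverman'")
        sd = counts.std(ddof=1) if counts.size > 1 else 0.0
        if sd == 0:
            warnings.warn(
                "all counts identical; falling back to bandwidth 1", stacklevel=2
            )
            h = 1.0
        else:
            h = 1.06 * sd * counts.size ** (-1 / 5)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    return CountDensity(counts=counts, bandwidth=h)
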