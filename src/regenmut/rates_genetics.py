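"""Per-site mutation frequency, baseline fold change, selfing homozygosity.

The detected homozygous count n is scaled by four: a de novo mutation is
heterozygous when it arises, and a selfed offspring carries it homozygous
with probability 1/4, so 4n estimates the heterozygous mutations present in
the source plant. m = 4n/s with s the unique-reads-covered genome size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPONTANEOUS_BASELINE = 7e-9  # mutations per site per generation, sexual propagation


@dataclass(frozen=True)
class RateEstimate:
    n: int
    s: int
    theoretical: int  # 4n
    m: float  # 4n/s
    fold_change: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "s": self.s,
            "theoretical": self.theoretical,
            "m": self.m,
            "fold_change": self.fold_change,
        }


def estimate_rate(n: int, s: int) -> RateEstimate:
    if n < 0:
        raise ValueError("n must be >= 0")
    if s <= 0:
        raise ValueError("covered genome size s must be > 0")
    return RateEstimate(n=n, s=s, theoretical=4 * n, m=4 * n / s)


def fold_change(m: float, baseline: float = SPONTANEOUS_BASELINE) -> float:
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return m / baseline


def with_fold_change(
    est: RateEstimate, baseline: float = SPONTANEOUS_BASELINE
) -> RateEstimate:
    return RateEstimate(
        n=est.n,
        s=est.s,
        theoretical=est.theoretical,
        m=est.m,
        fold_change=fold_change(est.m, baseline),
    )


@dataclass(frozen=True)
class SelfingResult:
    generations: int
    exact: float
    simulated: float | None
    replicates: int
    standard_error: float | None


def selfing_homozygosity(
    generations: int,
    replicates: int = 0,
    seed: int = 0,
) -> SelfingResult:
    """Fraction of initially heterozygous loci homozygous-mutant after selfing.

    Each selfing generation a heterozygous locus transmits 1/4 hom-mutant,
    1/2 het, 1/4 hom-wildtype; homozygous states are absorbing. The exact
    value is P(hom-mut after g) = (1 - (1/2)^g) / 2, also computed by
    iterating the chain; an optional Monte-Carlo estimate runs ``replicates``
    independent loci.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    # iterate the chain explicitly (hom_wt, het, hom_mut)
    state = np.array([0.0, 1.0, 0.0])
    transition = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.25, 0.5, 0.25],
            [0.0, 0.0, 1.0],
        ]
    )
    for _ in range(generations):
        state = state @ transition
    exact = float(state[2])
    assert abs(exact - (1 - 0.5**generations) / 2) < 1e-12

    simulated = se = None
    if replicates > 0:
        rng = np.random.default_rng(seed)
        # 0 = hom_wt, 1 = het, 2 = hom_mut
        loci = np.ones(replicates, dtype=np.int8)
        for _ in range(generations):
            het = loci == 1
            draws = rng.random(het.sum())
            out = np.where(draws < 0.25, 2, np.where(draws < 0.75, 1, 0))
            loci[het] = out
        simulated = float((loci == 2).mean())
        se = float(np.sqrt(max(exact * (1 - exact), 1e-12) / replicates))
    return SelfingResult(generations, exact, simulated, replicates, se)
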