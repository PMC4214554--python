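"""Bi-allelic genotype space, population genotype priors and the
Mendelian transmission tensor with a de novo mutation rate.

Genotypes are indexed ``0 = RR``, ``1 = RA``, ``2 = AA`` (reference /
alternative allele), matching the VCF PL order for ``0/0``, ``0/1``,
``1/1``.  This ordering is fixed project-wide.

Transmission model: each parent transmits one of its two alleles chosen
uniformly at random; the transmitted allele then mutates into the other
allele with probability ``m`` (one event per meiosis per allele, no
back-mutation chains).  With two homozygous-reference parents the child
is therefore heterozygous with probability ``2m(1-m)`` and homozygous
alternative with probability ``m^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

RR, RA, AA = 0, 1, 2
GENOTYPE_LABELS = ("RR", "RA", "AA")

#: default genotype priors (RR, RA, AA)
NON_DBSNP_PRIOR = (0.9985, 0.001, 0.0005)
DBSNP_PRIOR = (0.45, 0.1, 0.45)
#: default per-allele de novo mutation probability per transmission
DEFAULT_MUTATION_RATE = 1e-7

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class GenotypePrior:
    """Population genotype frequencies P(G) at a site."""

    p_rr: float
    p_ra: float
    p_aa: float

    def __post_init__(self) -> None:
        probs = (self.p_rr, self.p_ra, self.p_aa)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"genotype prior outside [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > _SUM_TOL:
            raise ValueError(f"genotype prior does not sum to 1: {probs}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rr, self.p_ra, self.p_aa])


@dataclass(frozen=True, eq=False)
class TransmissionModel:
    """3x3x3 tensor of P(child | father, mother), indexed [father, mother, child]."""

    m: float
    tensor: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 0.5:
            raise ValueError(f"mutation rate must be in [0, 0.5], got {self.m}")
        sums = self.tensor.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > _SUM_TOL):
            raise ValueError("transmission rows do not sum to 1")


def default_prior(is_dbsnp: bool = False) -> GenotypePrior:
    """Default genotype prior: variant-favouring for known dbSNP sites,
    strongly reference-favouring otherwise."""
    return GenotypePrior(*(DBSNP_PRIOR if is_dbsnp else NON_DBSNP_PRIOR))


def prior_from_allele_freq(q_alt: float) -> GenotypePrior:
    """Genotype prior under Hardy-Weinberg equilibrium at alternative
    allele frequency ``q_alt``."""
    if not 0.0 <= q_alt <= 1.0:
        raise ValueError(f"allele frequency must be in [0,1], got {q_alt}")
    p = 1.0 - q_alt
    return GenotypePrior(p * p, 2.0 * p * q_alt, q_alt * q_alt)


def allele_transmission(parent_genotype: int, m: float) -> tuple[float, float]:
    """(P(transmit R), P(transmit A)) for one meiosis.

    One parental allele is picked uniformly and flips to the other allele
    with probability ``m``.  A heterozygous parent transmits each allele
    with probability 1/2 regardless of ``m``.
    """
    if not 0.0 <= m <= 0.5:
        raise ValueError(f"mutation rate must be in [0, 0.5], got {m}")
    if parent_genotype == RR:
        return (1.0 - m, m)
    if parent_genotype == RA:
        return (0.5, 0.5)
    if parent_genotype == AA:
        return (m, 1.0 - m)
    raise ValueError(f"invalid genotype index {parent_genotype}")


def build_transmission(m: float) -> TransmissionModel:
    """Build the child-given-parents tensor for de novo rate ``m``."""
    t = np.zeros((3, 3, 3))
    for gf in (RR, RA, AA):
        pf = allele_transmission(gf, m)
        for gm in (RR, RA, AA):
            pm = allele_transmission(gm, m)
            for af in (0, 1):  # transmitted allele: 0=R, 1=A
                for am in (0, 1):
                    t[gf, gm, af + am] += pf[af] * pm[am]
    t.setflags(write=False)
    return TransmissionModel(m=m, tensor=t)


@lru_cache(maxsize=8)
def _cached_transmission(m: float) -> TransmissionModel:
    return build_transmission(m)


def mendelian_consistent(config: Sequence[int], ped) -> bool:
    """True iff every child genotype in ``config`` has positive probability
    under mutation-free Mendelian transmission given its parents."""
    if len(config) != ped.n:
        raise ValueError("one genotype per pedigree member required")
    t0 = _cached_transmission(0.0).tensor
    for i in range(ped.n):
        fa = ped.father_index[i]
        if fa < 0:
            continue
        if t0[config[fa], config[ped.mother_index[i]], config[i]] <= 0.0:
            return False
    return True
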