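"""Approximate genotype posteriors by systematic-scan Gibbs sampling,
with an optional heated-Metropolis proposal.

By Mendelian structure a member's genotype full conditional depends only
on its parents, mates and children: it is proportional to the member's
likelihood, times its founder prior or parental transmission term, times
one transmission term per child.  Each sweep updates every member once
in pedigree order.

With heat T > 1 the proposal is drawn from the tempered conditional
p(g)^(1/T) (flatter, so the chain escapes local modes) and accepted with
probability min(1, (p(g')/p(g))^(1-1/T)); this Metropolis-Hastings
correction leaves the target distribution invariant, so heating changes
mixing but never the stationary distribution.  T=1 reduces to plain
Gibbs sampling.

One *iteration* is one single-member update; the default budget of
20,000*n iterations for a pedigree of size n therefore corresponds to
20,000 full sweeps.  The chain starts from the individual-based MAP
genotypes and the first ``burn_in_fraction`` of sweeps is discarded.
Works on looped pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import ZeroConditionalError
from ..evidence import PosteriorCall, SiteEvidence
from ..pedigree import Pedigree

DEFAULT_ITERATIONS_PER_MEMBER = 20_000


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``iterations`` is the total number of single-member updates
    (``None`` means 20,000 x pedigree size); ``heat`` is the proposal
    temperature T >= 1 (1 disables the Metropolis step).
    """

    iterations: int | None = None
    burn_in_fraction: float = 0.1
    heat: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations is not None and self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if not 0.0 <= self.burn_in_fraction <= 0.9:
            raise ValueError("burn_in_fraction must be in [0, 0.9]")
        if self.heat < 1.0:
            raise ValueError("heat must be >= 1")

    def total_iterations(self, n: int) -> int:
        return self.iterations if self.iterations is not None else DEFAULT_ITERATIONS_PER_MEMBER * n


@dataclass
class ChainState:
    genotypes: np.ndarray  # (n,) int
    iteration: int = 0


def full_conditional(
    i: int, state: ChainState, ev: SiteEvidence, ped: Pedigree
) -> np.ndarray:
    """P(G_i | everything else) as a normalised genotype triple."""
    g = state.genotypes
    tensor = ev.transmission.tensor
    v = ev.likelihoods[i].copy()
    fa = ped.father_index[i]
    if fa < 0:
        v *= ev.prior.as_array()
    else:
        v *= tensor[g[fa], g[ped.mother_index[i]], :]
    for c in ped.children_of(i):
        if ped.father_index[c] == i:
            v *= tensor[:, g[ped.mother_index[c]], g[c]]
        else:
            v *= tensor[g[ped.father_index[c]], :, g[c]]
    s = v.sum()
    if s <= 0.0:
        raise ZeroConditionalError(
            f"all genotypes of member {i} have zero conditional probability "
            "(contradictory fixed neighbours at m=0)"
        )
    return v / s


def heated_acceptance(p_proposed: float, p_current: float, heat: float) -> float:
    """Metropolis-Hastings acceptance probability for the tempered proposal."""
    if heat <= 1.0 or p_current <= 0.0:
        return 1.0
    return min(1.0, (p_proposed / p_current) ** (1.0 - 1.0 / heat))


def _sample(p: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(p), rng.random() * p.sum()))


def gibbs_sweep(
    state: ChainState,
    ev: SiteEvidence,
    ped: Pedigree,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> ChainState:
    """Update every member once, in pedigree order."""
    g = state.genotypes.copy()
    working = ChainState(genotypes=g, iteration=state.iteration)
    for i in range(ped.n):
        p = full_conditional(i, working, ev, ped)
        if cfg.heat == 1.0:
            g[i] = _sample(p, rng)
        else:
            q = p ** (1.0 / cfg.heat)
            proposal = _sample(q, rng)
            if rng.random() < heated_acceptance(p[proposal], p[g[i]], cfg.heat):
                g[i] = proposal
    return ChainState(genotypes=g, iteration=state.iteration + ped.n)


def _initial_state(ev: SiteEvidence, ped: Pedigree) -> ChainState:
    # individual-based MAP genotypes: fast-mixing, always positive-likelihood
    start = (ev.likelihoods * ev.prior.as_array()).argmax(axis=1)
    return ChainState(genotypes=start.astype(np.int8), iteration=0)


def mcmc_posteriors(
    ev: SiteEvidence, ped: Pedigree, cfg: McmcConfig | None = None
) -> PosteriorCall:
    """Posterior triples as post-burn-in genotype sample frequencies.

    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or McmcConfig()
    n = ped.n
    sweeps = max(1, cfg.total_iterations(n) // n)
    burn = min(int(round(cfg.burn_in_fraction * sweeps)), sweeps - 1)
    rng = np.random.default_rng(cfg.seed)
    state = _initial_state(ev, ped)
    counts = np.zeros((n, 3))
    rows = np.arange(n)
    for sweep in range(sweeps):
        state = gibbs_sweep(state, ev, ped, cfg, rng)
        if sweep >= burn:
            counts[rows, state.genotypes] += 1.0
    return PosteriorCall(counts / (sweeps - burn), mode="family")
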