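"""Exact posterior genotype marginals by summing the joint distribution
over all 3^n genotype configurations of the pedigree.

The pedigree is a Bayesian network in which each member's genotype
depends only on its parents' genotypes; the joint weight of a
configuration is the product of per-member likelihoods and either the
founder prior or the transmission probability.  Because the full joint
is enumerated, the method works identically for looped and loop-free
pedigrees.

Configurations are indexed 0..3^n-1 and decoded base-3 little-endian in
pedigree member order (configuration index c assigns member i the
genotype ``(c // 3**i) % 3``).  Weights are computed in log scale and
exponentiated after subtracting the maximum log-weight, so large
pedigrees do not underflow.  ``partitioned_sum`` splits the index range
into contiguous parts that are summed independently and combined by
addition — the testable abstraction of running the enumeration on many
parallel workers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..errors import NormalizationError, SizeCapError
from ..evidence import PosteriorCall, SiteEvidence
from ..pedigree import Pedigree

#: default guardrail on pedigree size (3^14 ~ 4.8M configurations)
DEFAULT_SIZE_CAP = 14


def config_genotypes(index: int, n: int) -> tuple[int, ...]:
    """Decode a configuration index into one genotype per member."""
    return tuple((index // 3**i) % 3 for i in range(n))


def joint_weight(config: Sequence[int], ev: SiteEvidence, ped: Pedigree) -> float:
    """Unnormalised joint probability of one full genotype configuration."""
    if len(config) != ped.n:
        raise ValueError("one genotype per member required")
    prior = ev.prior.as_array()
    tensor = ev.transmission.tensor
    w = 1.0
    for i, g in enumerate(config):
        w *= float(ev.likelihoods[i, g])
        fa = ped.father_index[i]
        if fa < 0:
            w *= float(prior[g])
        else:
            w *= float(tensor[config[fa], config[ped.mother_index[i]], g])
    return w


def _log_terms(ev: SiteEvidence):
    with np.errstate(divide="ignore"):
        loglik = np.log(ev.likelihoods)
        logprior = np.log(ev.prior.as_array())
        logtensor = np.log(ev.transmission.tensor)
    return loglik, logprior, logtensor


def _range_sums(lo: int, hi: int, ped: Pedigree, loglik, logprior, logtensor):
    """Max log-weight, scaled total and scaled per-member genotype sums
    over the contiguous configuration range [lo, hi)."""
    n = ped.n
    idx = np.arange(lo, hi, dtype=np.int64)
    powers = 3 ** np.arange(n, dtype=np.int64)
    digits = ((idx[:, None] // powers) % 3).astype(np.int8)
    logw = np.zeros(hi - lo)
    for i in range(n):
        gi = digits[:, i]
        logw += loglik[i, gi]
        fa = ped.father_index[i]
        if fa < 0:
            logw += logprior[gi]
        else:
            logw += logtensor[digits[:, fa], digits[:, ped.mother_index[i]], gi]
    shift = float(logw.max()) if logw.size else -np.inf
    if not np.isfinite(shift):  # every configuration in this range has weight 0
        return -np.inf, 0.0, np.zeros((n, 3))
    w = np.exp(logw - shift)
    marg = np.empty((n, 3))
    for i in range(n):
        marg[i] = np.bincount(digits[:, i], weights=w, minlength=3)
    return shift, float(w.sum()), marg


def _combine(parts, n: int) -> np.ndarray:
    shift = max(p[0] for p in parts)
    if not np.isfinite(shift):
        raise NormalizationError(
            "total joint weight is zero (contradictory evidence at m=0)"
        )
    total = 0.0
    marg = np.zeros((n, 3))
    for s, t, g in parts:
        scale = np.exp(s - shift)
        total += t * scale
        marg += g * scale
    if total <= 0.0:
        raise NormalizationError(
            "total joint weight is zero (contradictory evidence at m=0)"
        )
    return marg / total


def _check_cap(n: int, size_cap: int) -> None:
    if n > size_cap:
        raise SizeCapError(
            f"pedigree size {n} exceeds the exhaustive-enumeration cap "
            f"{size_cap} (3^{n} configurations); raise the cap or use peeling/MCMC"
        )


def exact_posteriors(
    ev: SiteEvidence, ped: Pedigree, size_cap: int = DEFAULT_SIZE_CAP
) -> PosteriorCall:
    """Exact per-member posterior genotype marginals."""
    _check_cap(ped.n, size_cap)
    terms = _log_terms(ev)
    parts = [_range_sums(0, 3**ped.n, ped, *terms)]
    return PosteriorCall(_combine(parts, ped.n), mode="family")


def partitioned_sum(
    ev: SiteEvidence,
    ped: Pedigree,
    n_parts: int,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> PosteriorCall:
    """Exact marginals with the configuration range split into ``n_parts``
    contiguous, independently summed pieces (parallel-worker contract)."""
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    _check_cap(ped.n, size_cap)
    total = 3**ped.n
    cuts = [total * k // n_parts for k in range(n_parts + 1)]
    terms = _log_terms(ev)
    parts = [
        _range_sums(cuts[k], cuts[k + 1], ped, *terms)
        for k in range(n_parts)
        if cuts[k + 1] > cuts[k]
    ]
    return PosteriorCall(_combine(parts, ped.n), mode="family")


def exact_posteriors_many(
    likelihoods: np.ndarray,
    prior,
    transmission,
    ped: Pedigree,
    size_cap: int = DEFAULT_SIZE_CAP,
    chunk_sites: int = 2048,
) -> np.ndarray:
    """Vectorised exact marginals for a batch of sites.

    ``likelihoods`` is (n_sites, n, 3); returns (n_sites, n, 3).  The
    structural part of the log-weight (priors and transmission) is shared
    across sites and computed once.
    """
    n = ped.n
    _check_cap(n, size_cap)
    lik = np.asarray(likelihoods, dtype=float)
    n_sites = lik.shape[0]
    total = 3**n
    powers = 3 ** np.arange(n, dtype=np.int64)
    digits = ((np.arange(total, dtype=np.int64)[:, None] // powers) % 3).astype(np.int8)

    with np.errstate(divide="ignore"):
        logprior = np.log(prior.as_array())
        logtensor = np.log(transmission.tensor)
        loglik = np.log(lik)

    structural = np.zeros(total)
    for i in range(n):
        fa = ped.father_index[i]
        if fa < 0:
            structural += logprior[digits[:, i]]
        else:
            structural += logtensor[digits[:, fa], digits[:, ped.mother_index[i]], digits[:, i]]

    onehot = [np.eye(3)[digits[:, i]] for i in range(n)]  # (total, 3) each
    out = np.empty((n_sites, n, 3))
    for lo in range(0, n_sites, chunk_sites):
        hi = min(lo + chunk_sites, n_sites)
        logw = structural[None, :] + sum(
            loglik[lo:hi, i, digits[:, i]] for i in range(n)
        )
        shift = logw.max(axis=1, keepdims=True)
        bad = ~np.isfinite(shift[:, 0])
        if np.any(bad):
            raise NormalizationError("zero total joint weight for some sites")
        w = np.exp(logw - shift)
        z = w.sum(axis=1)
        for i in range(n):
            out[lo:hi, i, :] = (w @ onehot[i]) / z[:, None]
    return out
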