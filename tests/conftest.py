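"""Shared fixtures and helpers: random loop-free pedigree generation, an
independent brute-force posterior oracle, and evidence builders."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pedcall.evidence import SiteEvidence
from pedcall.genetic_model import build_transmission, default_prior
from pedcall.pedigree import Gender, Individual, Pedigree
from pedcall.simdata import template_pedigree


def brute_posteriors(ev: SiteEvidence, ped: Pedigree) -> np.ndarray:
    """Literal nested-loop reference: enumerate every genotype
    configuration with pure-Python arithmetic on linear scale."""
    n = ped.n
    lik = ev.likelihoods.tolist()
    prior = ev.prior.as_array().tolist()
    tensor = ev.transmission.tensor.tolist()
    totals = [[0.0, 0.0, 0.0] for _ in range(n)]
    z = 0.0
    for config in itertools.product(range(3), repeat=n):
        w = 1.0
        for i, g in enumerate(config):
            w *= lik[i][g]
            fa = ped.father_index[i]
            if fa < 0:
                w *= prior[g]
            else:
                w *= tensor[config[fa]][config[ped.mother_index[i]]][g]
        z += w
        for i, g in enumerate(config):
            totals[i][g] += w
    return np.array(totals) / z


def random_tree_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """A random loop-free pedigree of size n >= 3: grown from a trio by
    either adding a child to an existing couple or marrying an existing
    member to a fresh founder and giving them a child."""
    assert n >= 3
    genders = {"I0": Gender.MALE, "I1": Gender.FEMALE}
    rows = [("I0", None, None), ("I1", None, None)]
    couples = [("I0", "I1")]
    k = 2

    def add_child(father: str, mother: str) -> None:
        nonlocal k
        cid = f"I{k}"
        genders[cid] = Gender.MALE if rng.random() < 0.5 else Gender.FEMALE
        rows.append((cid, mother, father))
        k += 1

    add_child(*couples[0])
    while k < n:
        if k + 1 < n and rng.random() < 0.4:
            # marry a random existing member to a new founder, add a child
            mate_id = f"I{int(rng.integers(0, k))}"
            sid = f"I{k}"
            genders[sid] = (
                Gender.FEMALE if genders[mate_id] is Gender.MALE else Gender.MALE
            )
            rows.append((sid, None, None))
            k += 1
            couple = (
                (mate_id, sid) if genders[mate_id] is Gender.MALE else (sid, mate_id)
            )
            couples.append(couple)
            add_child(*couple)
        else:
            add_child(*couples[int(rng.integers(0, len(couples)))])
    return Pedigree.from_individuals(
        Individual(
            id=i, mother_id=mo, father_id=fa, gender=genders[i], sample_name=i
        )
        for i, mo, fa in rows
    )


def random_evidence(
    ped: Pedigree, rng: np.random.Generator, m: float = 1e-7
) -> SiteEvidence:
    """Strictly positive random likelihoods (no configuration is
    impossible, so totals never vanish even at m=0)."""
    lik = rng.random((ped.n, 3)) + 1e-3
    return SiteEvidence(lik, default_prior(False), build_transmission(m))


def permute_pedigree(ped: Pedigree, perm: np.ndarray) -> Pedigree:
    """The same pedigree with member rows reordered by ``perm``."""
    return Pedigree.from_individuals(ped.members[i] for i in perm)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def trio():
    return template_pedigree("trio")


@pytest.fixture
def quartet():
    return template_pedigree("quartet")


@pytest.fixture
def loop7():
    return template_pedigree("loop7")
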