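"""Per-site calling orchestration: candidate filtering, individual-based
posteriors, family-engine dispatch, the de novo over-correction guard and
output assembly.

Method dispatch (``method="auto"``): loop-free pedigrees go to
Elston-Stewart peeling, looped pedigrees to exact enumeration — peeling
is fastest when it applies and enumeration is exact on loops.  Explicit
``elston_stewart`` / ``exact`` / ``mcmc`` override the choice (peeling
on a looped pedigree is an error).

The over-correction guard addresses true de novo mutations: when every
sequenced member's evidence is individually decisive (best-vs-second
genotype likelihood ratio above a user cutoff) yet the individually
called genotypes violate mutation-free Mendelian transmission, the
family-based call is replaced by the individual-based one instead of
letting the pedigree "correct" a real mutation away.  The guard is off
unless a cutoff is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import NormalizationError, PedcallError
from .evidence import PosteriorCall, SiteEvidence
from .genetic_model import (
    DEFAULT_MUTATION_RATE,
    GenotypePrior,
    TransmissionModel,
    build_transmission,
    default_prior,
    mendelian_consistent,
)
from .inference.exact import DEFAULT_SIZE_CAP, exact_posteriors
from .inference.mcmc import McmcConfig, mcmc_posteriors
from .inference.peeling import peel_posteriors
from .pedigree import Pedigree, read_pedigree
from .variant_io import (
    VariantRecord,
    open_writer,
    read_likelihood_table,
    read_vcf,
)

METHODS = ("auto", "elston_stewart", "exact", "mcmc")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings for a calling pass."""

    method: str = "auto"
    mutation_rate: float = DEFAULT_MUTATION_RATE
    prior_non_dbsnp: GenotypePrior = field(default_factory=lambda: default_prior(False))
    prior_dbsnp: GenotypePrior = field(default_factory=lambda: default_prior(True))
    lr_cutoff: float | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    first_alt: bool = False
    size_cap: int = DEFAULT_SIZE_CAP

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        if self.lr_cutoff is not None and self.lr_cutoff <= 1.0:
            raise ValueError("lr_cutoff must be > 1 when set")


def build_evidence(
    rec: VariantRecord,
    ped: Pedigree,
    cfg: RunConfig,
    transmission: TransmissionModel | None = None,
) -> SiteEvidence:
    if transmission is None:
        transmission = build_transmission(cfg.mutation_rate)
    prior = cfg.prior_dbsnp if rec.is_dbsnp else cfg.prior_non_dbsnp
    return SiteEvidence(
        likelihoods=rec.likelihoods, prior=prior, transmission=transmission
    )


def individual_posteriors(ev: SiteEvidence) -> PosteriorCall:
    """Per-member posterior from likelihood x prior alone (no pedigree)."""
    prod = ev.likelihoods * ev.prior.as_array()
    z = prod.sum(axis=1)
    if np.any(z <= 0):
        raise NormalizationError("a member has zero likelihood x prior everywhere")
    return PosteriorCall(prod / z[:, None], mode="individual")


def is_candidate(rec: VariantRecord) -> bool:
    """Positions with no alternative allele mean every member is
    homozygous reference; they are skipped, not jointly called."""
    return rec.candidate


def overcorrection_guard(
    ev: SiteEvidence, ped: Pedigree, ind_call: PosteriorCall, cutoff: float
) -> bool:
    """True iff the individual-based call should stand (likely true de
    novo event): all sequenced members decisive AND jointly
    Mendelian-inconsistent at m=0."""
    if mendelian_consistent(ind_call.genotypes, ped):
        return False
    for i in ped.sequenced_index.values():
        ordered = np.sort(ev.likelihoods[i])[::-1]
        if ordered[1] > 0 and ordered[0] / ordered[1] <= cutoff:
            return False
    return True


def call_site(
    rec: VariantRecord,
    ped: Pedigree,
    cfg: RunConfig,
    site_index: int = 0,
    transmission: TransmissionModel | None = None,
) -> tuple[VariantRecord, PosteriorCall | None, PosteriorCall | None]:
    """Compute individual- and family-based calls for one record.

    Non-candidate records pass through uncalled.  ``site_index`` keeps
    per-site MCMC seeds distinct yet reproducible.
    """
    if not is_candidate(rec):
        return rec, None, None
    ev = build_evidence(rec, ped, cfg, transmission)
    try:
        ind = individual_posteriors(ev)
        if cfg.method == "elston_stewart" or (cfg.method == "auto" and not ped.has_loop):
            fam = peel_posteriors(ev, ped)
        elif cfg.method == "mcmc":
            site_seed = (cfg.mcmc.seed * 1_000_003 + site_index) % (2**31)
            fam = mcmc_posteriors(ev, ped, replace(cfg.mcmc, seed=site_seed))
        else:  # exact enumeration; also the auto route for looped pedigrees
            fam = exact_posteriors(ev, ped, size_cap=cfg.size_cap)
    except PedcallError as e:
        raise type(e)(f"{rec.chrom}:{rec.pos}: {e}") from None
    if cfg.lr_cutoff is not None and overcorrection_guard(ev, ped, ind, cfg.lr_cutoff):
        fam = PosteriorCall(ind.posteriors.copy(), mode="family")
    return rec, ind, fam


def call_records(
    records: Iterator[VariantRecord], ped: Pedigree, cfg: RunConfig
) -> Iterator[tuple[VariantRecord, PosteriorCall | None, PosteriorCall | None]]:
    transmission = build_transmission(cfg.mutation_rate)
    site_index = 0
    for rec in records:
        yield call_site(rec, ped, cfg, site_index=site_index, transmission=transmission)
        if rec.candidate:
            site_index += 1


def call_file(
    input_path: str | Path,
    ped: Pedigree | str | Path,
    output_path: str | Path,
    cfg: RunConfig | None = None,
    input_format: str | None = None,
) -> dict:
    """Run the full calling pass on a VCF or likelihood table.

    ``input_format`` is ``"vcf"``, ``"table"`` or ``None`` (sniff from
    the file extension).  Returns a summary dict with record counts.
    """
    cfg = cfg or RunConfig()
    if not isinstance(ped, Pedigree):
        ped = read_pedigree(ped)
    if input_format is None:
        input_format = "vcf" if str(input_path).endswith(".vcf") else "table"
    if input_format == "vcf":
        records = read_vcf(input_path, ped, first_alt=cfg.first_alt)
    else:
        records = read_likelihood_table(input_path, ped)

    writer = None
    n_records = n_called = 0
    try:
        for rec, ind, fam in call_records(records, ped, cfg):
            if writer is None:
                writer = open_writer(rec, output_path)
            writer.write_site(rec, ped, ind, fam)
            n_records += 1
            if ind is not None:
                n_called += 1
    finally:
        if writer is not None:
            writer.close()
    return {
        "records": n_records,
        "called": n_called,
        "skipped": n_records - n_called,
        "method": cfg.method,
        "has_loop": ped.has_loop,
    }
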