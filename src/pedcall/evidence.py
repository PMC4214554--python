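"""Per-site evidence container and posterior-call result type shared by
all inference engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_model import GenotypePrior, TransmissionModel

_POST_SUM_TOL = 1e-9


def uniform_likelihoods(n: int) -> np.ndarray:
    """The non-informative likelihood matrix used for unsequenced members."""
    return np.ones((n, 3))


@dataclass(frozen=True, eq=False)
class SiteEvidence:
    """Everything one site contributes to inference: the per-member
    linear-scale genotype likelihoods P(D_i|G_i) (uniform rows for
    unsequenced members), the founder genotype prior, and the
    transmission model."""

    likelihoods: np.ndarray  # (n, 3)
    prior: GenotypePrior
    transmission: TransmissionModel

    def __post_init__(self) -> None:
        lik = np.asarray(self.likelihoods, dtype=float)
        if lik.ndim != 2 or lik.shape[1] != 3:
            raise ValueError(f"likelihoods must be (n, 3), got {lik.shape}")
        if np.any(lik < 0):
            raise ValueError("negative likelihood")
        if np.any(~np.isfinite(lik)):
            raise ValueError("non-finite likelihood")
        if np.any(lik.max(axis=1) <= 0):
            raise ValueError("a member has no positive likelihood entry")
        object.__setattr__(self, "likelihoods", lik)

    @property
    def n(self) -> int:
        return self.likelihoods.shape[0]


@dataclass(frozen=True, eq=False)
class PosteriorCall:
    """Per-member posterior genotype triples plus the argmax call.

    ``mode`` is ``"individual"`` (likelihood x prior only) or
    ``"family"`` (pedigree-marginalised).
    """

    posteriors: np.ndarray  # (n, 3), rows sum to 1
    mode: str
    genotypes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        post = np.asarray(self.posteriors, dtype=float)
        if post.ndim != 2 or post.shape[1] != 3:
            raise ValueError(f"posteriors must be (n, 3), got {post.shape}")
        if np.any(np.abs(post.sum(axis=1) - 1.0) > _POST_SUM_TOL):
            raise ValueError("posterior rows must sum to 1")
        if self.mode not in ("individual", "family"):
            raise ValueError(f"invalid mode {self.mode!r}")
        object.__setattr__(self, "posteriors", post)
        object.__setattr__(self, "genotypes", post.argmax(axis=1))

    @property
    def n(self) -> int:
        return self.posteriors.shape[0]

    def called_probability(self, i: int) -> float:
        """Posterior probability of member i's called genotype."""
        return float(self.posteriors[i, self.genotypes[i]])
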