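"""Population and mutation models for the founder-coalescent simulator."""

from __future__ import annotations

import math
from dataclasses import dataclass


class ModelError(ValueError):
    """Invalid population or mutation model parameters."""


@dataclass(frozen=True)
class PopulationModel:
    """A single, isolated, constant-size maternal-lineage population.

    Parameters
    ----------
    n_females:
        Effective number of maternal lineages (female effective population
        size).  Coalescence rate for a pair of lineages is 1/n_females per
        generation.  Non-integer values are allowed (grids are log-spaced).
    t_iso_calBP:
        Founding / isolation time in years calBP.  All lineages still
        distinct at this time are forced to coalesce into the single founder
        lineage, so the founding population carries exactly one haplotype.
    """

    n_females: float
    t_iso_calBP: float = 12_000.0

    def __post_init__(self) -> None:
        if not (self.n_females >= 1 and math.isfinite(self.n_females)):
            raise ModelError("n_females must be finite and >= 1")
        if not (self.t_iso_calBP > 0 and math.isfinite(self.t_iso_calBP)):
            raise ModelError("t_iso_calBP must be finite and positive")


# Transition partner under the standard nucleotide encoding A=0, C=1, G=2, T=3:
# A<->G, C<->T.
TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}
TRANSVERSIONS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}
BASES = "ACGT"


@dataclass(frozen=True)
class MutationModel:
    """Poisson mutation process on the genealogy.

    The expected number of mutations on a branch of length ``t`` years is
    ``mu_per_site_year * L * t``.

    Parameters
    ----------
    mu_per_site_year:
        Mutation rate per site per year.
    L:
        Sequence length in sites (default 16,506 bp, the length of the
        masked mitogenome alignment).
    transition_prob:
        Probability that a substitution is a transition (kappa); 1/3 means
        no transition bias, 0.98 a strong one.  Only meaningful in finite
        mode; each transversion is chosen with probability (1 - kappa)/2.
    sites_mode:
        ``"finite"``: mutations hit uniformly random sites of an explicit
        L-site sequence; repeat hits and reversions are possible.
        ``"infinite"``: every mutation hits a fresh site (infinite-sites
        approximation), so haplotype identity reduces to mutation sets.
    """

    mu_per_site_year: float
    L: int = 16_506
    transition_prob: float = 1.0 / 3.0
    sites_mode: str = "infinite"

    def __post_init__(self) -> None:
        if self.mu_per_site_year < 0 or not math.isfinite(self.mu_per_site_year):
            raise ModelError("mutation rate must be finite and >= 0")
        if self.L < 1:
            raise ModelError("sequence length must be a positive integer")
        if not 0.0 <= self.transition_prob <= 1.0:
            raise ModelError("transition_prob must lie in [0, 1]")
        if self.sites_mode not in ("finite", "infinite"):
            raise ModelError("sites_mode must be 'finite' or 'infinite'")

    @property
    def rate_per_branch_year(self) -> float:
        """Expected mutations per year of branch length (mu * L)."""
        return self.mu_per_site_year * self.L
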