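"""The study-level analyses: the island founder-population rate inference.

These functions tie the pieces together exactly as the analysis scripts run
them: the observed Holocene haplotype count is taken from the packaged
metadata table, the sampling schedule from its median calibrated ages, and
the (N_ef, mu) grids are scored with the serial founder-coalescent.

Default problem sizes are the package's scaled-down standard (40 x 40 cells
at 400 replicates for the narrow prior, 30 x 30 at 300 for the wide prior);
the full 100 x 100 x 1000 setting of the original design is available by
argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (
    GridSpec,
    RateEstimate,
    ProbabilitySurface,
    estimate_surface,
    find_mode_and_hpd,
    marginalize_over_N,
    narrow_grid,
    plateau_rate,
    wide_grid,
)
from .models import MutationModel, PopulationModel
from .schedule import wrangel_schedule
from .synth import holocene_wrangel_rows, table1_fixture


def observed_holocene_haplotype_count() -> int:
    """Distinct haplotype labels among the Holocene island samples in the
    packaged metadata (the observed K the simulations must reproduce)."""
    return int(holocene_wrangel_rows().haplotype.nunique())


def narrow_rate_inference(
    seed: int,
    n_mu: int = 40,
    n_N: int = 40,
    reps_per_cell: int = 400,
    t_iso: float = 12_000.0,
    level: float = 0.95,
) -> tuple[ProbabilitySurface, RateEstimate]:
    """Narrow-prior grid inference of the island mutation rate.

    N_ef 100-450 individuals, mu 0.17-66.7e-8 /site/year, both log-spaced;
    the marginal curve averages all N_ef rows.
    """
    schedule = wrangel_schedule()
    spec = narrow_grid(n_mu=n_mu, n_N=n_N, reps_per_cell=reps_per_cell)
    pop = PopulationModel(n_females=1.0, t_iso_calBP=t_iso)
    mut = MutationModel(mu_per_site_year=1e-8)
    k_obs = observed_holocene_haplotype_count()
    surface = estimate_surface(spec, schedule, pop, mut, k_obs, seed)
    estimate = find_mode_and_hpd(surface.mu_axis, marginalize_over_N(surface), level)
    return surface, estimate


def wide_plateau_rate(
    seed: int,
    n_mu: int = 30,
    n_N: int = 30,
    reps_per_cell: int = 300,
    t_iso: float = 12_000.0,
    N_min: float = 5000.0,
) -> tuple[ProbabilitySurface, float]:
    """Wide-prior grid; the large-N plateau of the per-row best rate.

    N_ef 1-1e7 individuals, mu 0.07-667e-8; rows with N_ef > N_min each
    contribute their argmax mu and the median is the plateau readout.
    """
    schedule = wrangel_schedule()
    spec = wide_grid(n_mu=n_mu, n_N=n_N, reps_per_cell=reps_per_cell)
    pop = PopulationModel(n_females=1.0, t_iso_calBP=t_iso)
    mut = MutationModel(mu_per_site_year=1e-8)
    k_obs = observed_holocene_haplotype_count()
    surface = estimate_surface(spec, schedule, pop, mut, k_obs, seed)
    return surface, plateau_rate(surface, N_min)


@dataclass(frozen=True)
class RecoveryResult:
    n_datasets: int
    n_covered: int
    modes: tuple[float, ...]

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_datasets


def parameter_recovery(
    seed: int,
    n_datasets: int = 50,
    true_mu: float = 3e-8,
    true_n_females: float = 164.0,
    n_mu: int = 16,
    n_N: int = 10,
    reps_per_cell: int = 150,
    level: float = 0.95,
) -> RecoveryResult:
    """Simulate datasets at known (mu, N_ef females) and re-infer the rate.

    Each dataset is one serial founder-coalescent realization under the
    island sampling schedule; the scaled-down narrow-grid inference is run
    on its haplotype count and coverage of the true rate by the HPD hull is
    tallied.  The truth N_ef = 164 maternal lineages corresponds to the
    narrow grid's 328 individuals under the 1:1 sex ratio.
    """
    schedule = wrangel_schedule()
    pop = PopulationModel(n_females=true_n_females)
    mut = MutationModel(mu_per_site_year=true_mu)
    spec = narrow_grid(n_mu=n_mu, n_N=n_N, reps_per_cell=reps_per_cell)
    pop_t = PopulationModel(n_females=1.0)
    covered = 0
    modes = []
    from .coalescent import simulate_k

    for i in range(n_datasets):
        k_true = max(
            simulate_k(schedule, pop, mut, 1,
                       np.random.SeedSequence(entropy=(int(seed), 0x5EC0, i))).counts
        )
        surface = estimate_surface(spec, schedule, pop_t, mut, k_true,
                                   seed=int(seed) * 1000 + i)
        try:
            est = find_mode_and_hpd(surface.mu_axis, marginalize_over_N(surface), level)
        except Exception:
            continue
        modes.append(est.mode_mu)
        if est.hpd_low <= true_mu <= est.hpd_high:
            covered += 1
    return RecoveryResult(n_datasets=n_datasets, n_covered=covered,
                          modes=tuple(modes))
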