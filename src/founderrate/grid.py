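"""Grid inference of the mutation rate from an observed haplotype count.

A log-spaced grid over (N_ef, mu) is scored cell by cell with the Monte-Carlo
probability of reproducing the observed number of haplotypes, the surface is
averaged over the N_ef axis (uniform prior over the log-spaced grid values),
and the mode and a highest-density interval of the resulting mutation-rate
curve are reported.

The N_ef axis counts effective individuals of both sexes, as in the narrow
prior of the study (an estimate of 328 individuals and a 1:1 sex ratio); the
number of maternal lineages handed to the coalescent simulator is
``maternal_fraction * N_ef`` with ``maternal_fraction = 0.5`` by default.
See docs/methods.md for the rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coalescent import simulate_k
from .models import MutationModel, PopulationModel
from .schedule import SampleSchedule


class GridError(ValueError):
    """Invalid grid settings or degenerate inference input."""


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced (N_ef, mu) grid with per-cell Monte-Carlo settings.

    Default ranges follow the study's narrow prior (N_ef 100-450 individuals,
    mu 0.17-66.7e-8 /site/year); :func:`wide_grid` gives the wide prior.
    """

    n_mu: int = 100
    n_N: int = 100
    mu_range: tuple[float, float] = (0.17e-8, 66.7e-8)
    N_range: tuple[float, float] = (100.0, 450.0)
    reps_per_cell: int = 1000

    def __post_init__(self) -> None:
        if self.n_mu < 1 or self.n_N < 1:
            raise GridError("grid dimensions must be positive")
        if self.reps_per_cell < 1:
            raise GridError("reps_per_cell must be positive")
        for lo, hi in (self.mu_range, self.N_range):
            if not (0 < lo < hi):
                raise GridError("grid ranges need 0 < low < high")


def narrow_grid(n_mu: int = 100, n_N: int = 100, reps_per_cell: int = 1000) -> GridSpec:
    """The narrow prior: N_ef 100-450 individuals, mu 0.17-66.7e-8."""
    return GridSpec(n_mu=n_mu, n_N=n_N, reps_per_cell=reps_per_cell)


def wide_grid(n_mu: int = 100, n_N: int = 100, reps_per_cell: int = 1000) -> GridSpec:
    """The wide prior: N_ef 1-1e7 individuals, mu 0.07-667e-8."""
    return GridSpec(
        n_mu=n_mu,
        n_N=n_N,
        mu_range=(0.07e-8, 667e-8),
        N_range=(1.0, 1e7),
        reps_per_cell=reps_per_cell,
    )


def log_axis(low: float, high: float, n: int) -> np.ndarray:
    if not (0 < low < high):
        raise GridError("axis bounds must satisfy 0 < low < high")
    if n == 1:
        raise GridError("a log axis needs at least two points")
    return np.exp(np.linspace(np.log(low), np.log(high), n))


def build_grid(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (mu_axis, N_axis): values equally spaced in log, endpoints exact."""
    mu_axis = log_axis(*spec.mu_range, spec.n_mu)
    N_axis = log_axis(*spec.N_range, spec.n_N)
    # pin the endpoints exactly despite floating-point exp/log round trips
    mu_axis[0], mu_axis[-1] = spec.mu_range
    N_axis[0], N_axis[-1] = spec.N_range
    return mu_axis, N_axis


@dataclass
class ProbabilitySurface:
    """Monte-Carlo estimates of P(K = k_obs) over the (N_ef, mu) grid.

    ``p[i, j]`` is the estimate for ``N_axis[i]``, ``mu_axis[j]``;
    ``se`` holds the matching binomial standard errors.
    """

    mu_axis: np.ndarray
    N_axis: np.ndarray
    p: np.ndarray
    se: np.ndarray
    k_obs: int
    reps: int
    seed: int
    maternal_fraction: float = 0.5


def cell_seed(master_seed: int, i_N: int, i_mu: int) -> np.random.SeedSequence:
    """Documented per-cell seed derivation: cells are independent streams
    keyed by (master seed, N index, mu index), so the grid can be evaluated
    in any order, or in parallel, with identical results."""
    return np.random.SeedSequence(entropy=(int(master_seed), int(i_N), int(i_mu)))


def estimate_surface(
    spec: GridSpec,
    schedule: SampleSchedule,
    pop_template: PopulationModel,
    mut_template: MutationModel,
    k_obs: int,
    seed: int,
    maternal_fraction: float = 0.5,
) -> ProbabilitySurface:
    """Score every grid cell with simulate_k and record P(K = k_obs).

    ``pop_template`` supplies the isolation time, ``mut_template`` the
    sequence length / transition bias / sites mode; the grid supplies N_ef
    and mu.  ``maternal_fraction`` converts the N_ef axis (individuals) to
    maternal lineages.
    """
    if k_obs < 1:
        raise GridError("k_obs must be >= 1")
    if len(schedule) == 0:
        raise GridError("schedule is empty")
    mu_axis, N_axis = build_grid(spec)
    p = np.zeros((spec.n_N, spec.n_mu))
    se = np.zeros_like(p)
    if k_obs > len(schedule):
        warnings.warn(
            f"k_obs={k_obs} exceeds the sample size n={len(schedule)}; "
            "the surface is identically zero",
            stacklevel=2,
        )
        return ProbabilitySurface(mu_axis, N_axis, p, se, k_obs, spec.reps_per_cell,
                                  seed, maternal_fraction)
    for i_N, N in enumerate(N_axis):
        n_fem = max(1.0, maternal_fraction * N)
        pop = PopulationModel(n_females=n_fem, t_iso_calBP=pop_template.t_iso_calBP)
        for i_mu, mu in enumerate(mu_axis):
            mut = MutationModel(
                mu_per_site_year=mu,
                L=mut_template.L,
                transition_prob=mut_template.transition_prob,
                sites_mode=mut_template.sites_mode,
            )
            dist = simulate_k(schedule, pop, mut, spec.reps_per_cell,
                              cell_seed(seed, i_N, i_mu))
            p[i_N, i_mu] = dist.p(k_obs)
            se[i_N, i_mu] = dist.se(k_obs)
    return ProbabilitySurface(mu_axis, N_axis, p, se, k_obs, spec.reps_per_cell,
                              seed, maternal_fraction)


def marginalize_over_N(surface: ProbabilitySurface, N_subset=None) -> np.ndarray:
    """Arithmetic mean of the surface across the N_ef axis.

    This is a uniform prior over the log-spaced N_ef grid values
    ("incorporating all values of N_ef").  ``N_subset`` optionally restricts
    the average to a boolean mask or index array over the N axis.
    """
    rows = surface.p
    if N_subset is not None:
        idx = np.asarray(N_subset)
        if idx.size == 0:
            raise GridError("N_subset selects no rows")
        rows = rows[idx if idx.dtype == bool else idx.astype(int)]
        if rows.size == 0:
            raise GridError("N_subset selects no rows")
    return rows.mean(axis=0)


@dataclass(frozen=True)
class RateEstimate:
    """Mode and highest-density interval of the marginal mutation-rate curve."""

    mode_mu: float
    hpd_low: float
    hpd_high: float
    level: float
    mu_axis: np.ndarray
    weights: np.ndarray  # normalized to sum 1
    hpd_indices: np.ndarray
    multimodal: bool  # True when the HPD set is not contiguous on the grid

    def as_dict(self) -> dict:
        return {
            "mode_mu": self.mode_mu,
            "hpd_low": self.hpd_low,
            "hpd_high": self.hpd_high,
            "level": self.level,
            "multimodal": self.multimodal,
        }


def find_mode_and_hpd(mu_axis, curve, level: float = 0.95) -> RateEstimate:
    """Mode and discrete HPD of a non-negative curve over the mu grid.

    The curve is normalized to sum 1 and treated as an unnormalized
    posterior over mu under a uniform log-prior.  The mode is the mu of
    maximum weight (ties broken toward the smaller mu).  The HPD set is the
    smallest set of grid points, accumulated in order of descending weight
    (ties toward smaller mu), whose total weight reaches ``level``; the
    reported interval is the (min, max) hull of that set, and ``multimodal``
    flags a non-contiguous set.
    """
    mu_axis = np.asarray(mu_axis, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if mu_axis.shape != curve.shape:
        raise GridError("mu_axis and curve must have equal length")
    if np.any(curve < 0):
        raise GridError("curve must be non-negative")
    total = curve.sum()
    if total <= 0:
        raise GridError("all-zero curve: no signal at this grid size / replicate count")
    if not 0 < level < 1:
        raise GridError("level must lie in (0, 1)")
    w = curve / total
    mode_idx = int(np.argmax(w))  # np.argmax returns the first (smallest-mu) maximum
    # stable sort on -w keeps the smaller-mu point first among ties
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    n_sel = int(np.searchsorted(cum, level - 1e-12) + 1)
    sel = np.sort(order[:n_sel])
    multimodal = bool(np.any(np.diff(sel) > 1))
    return RateEstimate(
        mode_mu=float(mu_axis[mode_idx]),
        hpd_low=float(mu_axis[sel[0]]),
        hpd_high=float(mu_axis[sel[-1]]),
        level=level,
        mu_axis=mu_axis,
        weights=w,
        hpd_indices=sel,
        multimodal=multimodal,
    )


def infer_rate(
    spec: GridSpec,
    schedule: SampleSchedule,
    pop_template: PopulationModel,
    mut_template: MutationModel,
    k_obs: int,
    seed: int,
    level: float = 0.95,
    maternal_fraction: float = 0.5,
    fix_N=None,
) -> tuple[ProbabilitySurface, RateEstimate]:
    """End-to-end: surface, N-marginalization, mode + HPD.

    ``fix_N`` restricts the marginalization to the grid row nearest a given
    N_ef (the conditional-estimate variant) instead of averaging all rows.
    """
    surface = estimate_surface(
        spec, schedule, pop_template, mut_template, k_obs, seed, maternal_fraction
    )
    subset = None
    if fix_N is not None:
        subset = [int(np.argmin(np.abs(np.log(surface.N_axis) - np.log(fix_N))))]
    curve = marginalize_over_N(surface, subset)
    return surface, find_mode_and_hpd(surface.mu_axis, curve, level)


def plateau_rate(surface: ProbabilitySurface, N_min: float = 5000.0) -> float:
    """Median over rows with N_ef > N_min of the per-row argmax mu.

    For large populations the genealogy is essentially a star and the
    best-fitting rate stabilizes; this is the plateau readout of the wide
    grid.
    """
    rows = surface.N_axis > N_min
    if not np.any(rows):
        raise GridError(f"no grid rows with N_ef > {N_min}")
    argmax_mu = surface.mu_axis[np.argmax(surface.p[rows], axis=1)]
    return float(np.median(argmax_mu))
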