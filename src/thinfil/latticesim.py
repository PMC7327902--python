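"""Kinetic Monte Carlo simulation of cooperative ligand binding to 1D lattices.

Each actin filament is modeled as a one-dimensional lattice whose sites are
regulatory units (seven actin monomers).  A Tn-Tpm ligand binds an empty site
with probability ``k1·[L]·dt`` per iteration and unbinds with probability
``k_minus1·σ^(−n)·dt``, where ``n ∈ {0, 1, 2}`` is the number of bound nearest
neighbors and ``σ > 1`` encodes positive (nucleation/elongation) cooperativity
acting on the dissociation rate only.  Lattice ends contribute no neighbor.
The free-ligand pool is finite: the ensemble of ``M`` sites represents a site
concentration, one molecule ↔ ``site_conc/M`` nM, and ligand count is
conserved exactly at every step.

The update scheme is a synchronous-sweep fixed-timestep kinetic Monte Carlo
(matching an "iterations" picture of the dynamics rather than event-driven
Gillespie); ``dt`` must keep all per-event probabilities well below 1.

A deterministic mean-field companion integrates

    dθ/dt = k1·[L]_t·(1 − θ) − k_minus1·σ^(−⟨n⟩)·θ

with ``[L]_t`` from mass conservation and ``⟨n⟩`` from a quasi-chemical pair
closure, and serves as an independent oracle for the stochastic model.

Concentrations are in nM.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .isotherm import BindingIsotherm, FitError, HillParameters, fit_hill

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ConfigError",
    "LatticeEnsemble",
    "SteadyStateResult",
    "NeighborAbundance",
    "CalibrationResult",
    "init_ensemble",
    "step",
    "run_to_steady_state",
    "simulate_isotherm",
    "calibrate_rate_ratio",
    "calibrate_sigma_grid",
    "neighbor_abundance",
    "meanfield_ode",
    "equilibrium_theta",
    "mean_neighbors_closure",
]

#: experimental titration design: total ligand concentrations in nM
TITRATION_NM: tuple[float, ...] = (12.5, 25.0, 50.0, 100.0, 250.0, 500.0, 750.0)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    Parameters
    ----------
    k1
        Forward stochastic rate constant, per nM of free ligand per unit time.
    k_minus1
        Backward stochastic rate constant for an isolated bound ligand, per
        unit time.
    sigma
        Cooperativity parameter (> 0): a bound nearest neighbor divides the
        dissociation rate by ``sigma``.
    dt
        Time step; one iteration advances time by ``dt``.
    ligand_totals
        Total ligand concentrations of the titration (nM).
    total_site_conc
        Lattice-site concentration represented by the whole ensemble (nM).
        ``None`` selects stoichiometric mode: at each titration point the site
        concentration equals that point's total ligand concentration,
        emulating reconstitution at constant 1:1:7 Tn:Tpm:actin stoichiometry.
    n_lattices, mean_sites, min_sites
        Ensemble geometry: number of lattices and the exponential law of
        integer site counts.
    max_iterations, window, tol
        Steady-state control: iterate until the moving-window mean of θ
        changes by less than ``tol`` between consecutive windows.
    fixed_free
        If set (nM), the free-ligand concentration is held constant
        (grand-canonical mode; mass conservation disabled).  Used for
        analytical cross-checks and for decorating synthetic filaments at a
        prescribed free concentration.
    seed
        Master seed; per-titration-point substreams are derived from it.
    """

    k1: float = 2.7e-4
    k_minus1: float = 0.25
    sigma: float = 2.0
    dt: float = 1.0
    ligand_totals: tuple[float, ...] = TITRATION_NM
    total_site_conc: float | None = None
    n_lattices: int = 100
    mean_sites: float = 40.0
    min_sites: int = 1
    max_iterations: int = 3000
    window: int = 20
    tol: float = 1e-3
    fixed_free: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k_minus1 < 0:
            raise ConfigError("rate constants must be non-negative")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.n_lattices < 1:
            raise ConfigError("n_lattices must be >= 1")
        if self.mean_sites < 1:
            raise ConfigError("mean_sites must be >= 1")
        if not self.ligand_totals and self.fixed_free is None:
            raise ConfigError("ligand_totals must be non-empty")
        if any(c < 0 for c in self.ligand_totals):
            raise ConfigError("ligand totals must be non-negative")
        conc_max = max(
            [self.fixed_free or 0.0, *(self.ligand_totals or (0.0,))]
        )
        p_on_max = self.k1 * conc_max * self.dt
        p_off_max = self.k_minus1 * self.dt
        if p_on_max >= 1.0 or p_off_max >= 1.0:
            raise ConfigError(
                f"per-event probability >= 1 (p_on_max={p_on_max:.3g}, "
                f"p_off_max={p_off_max:.3g}); reduce dt"
            )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class LatticeEnsemble:
    """State of the lattice ensemble at one iteration.

    The ensemble is stored flat: ``occupancy`` concatenates all lattices and
    ``lattice_id`` labels each site's lattice.  ``conc_per_molecule`` maps
    molecule counts to concentration (nM per molecule).
    """

    occupancy: np.ndarray
    lattice_id: np.ndarray
    site_counts: np.ndarray
    conc_per_molecule: float
    free_count: int
    ligand_total: float
    fixed_free: float | None = None
    iteration: int = 0
    # same-lattice masks for neighbor lookups (computed once)
    _left_valid: np.ndarray = field(default=None, repr=False)
    _right_valid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._left_valid is None:
            lid = self.lattice_id
            self._left_valid = np.zeros(lid.size, dtype=bool)
            self._right_valid = np.zeros(lid.size, dtype=bool)
            self._left_valid[1:] = lid[1:] == lid[:-1]
            self._right_valid[:-1] = lid[:-1] == lid[1:]

    @property
    def n_sites(self) -> int:
        return int(self.occupancy.size)

    @property
    def theta(self) -> float:
        """Overall bound fraction."""
        return float(self.occupancy.sum()) / self.n_sites

    @property
    def free_ligand(self) -> float:
        """Free ligand concentration (nM)."""
        if self.fixed_free is not None:
            return self.fixed_free
        return self.free_count * self.conc_per_molecule

    def neighbor_numbers(self) -> np.ndarray:
        """Bound-neighbor count (0, 1 or 2) for every site, from scratch."""
        occ = self.occupancy
        n = np.zeros(occ.size, dtype=np.int8)
        n[1:] += occ[:-1] * self._left_valid[1:]
        n[:-1] += occ[1:] * self._right_valid[:-1]
        return n

    def neighbor_tally(self) -> np.ndarray:
        """Counts of bound ligands with 0, 1 and 2 bound neighbors."""
        bound = self.occupancy.astype(bool)
        n = self.neighbor_numbers()[bound]
        return np.bincount(n, minlength=3)[:3]

    def per_lattice_theta(self) -> np.ndarray:
        bound = np.bincount(self.lattice_id, weights=self.occupancy,
                            minlength=self.site_counts.size)
        return bound / self.site_counts

    def occupancies(self) -> list[np.ndarray]:
        """Per-lattice occupancy vectors."""
        edges = np.cumsum(self.site_counts)[:-1]
        return np.split(self.occupancy.copy(), edges)


def _sample_site_counts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    raw = rng.exponential(config.mean_sites, size=config.n_lattices)
    return np.maximum(config.min_sites, np.rint(raw)).astype(np.int64)


def init_ensemble(
    config: SimConfig,
    ligand_total: float | None = None,
    rng: np.random.Generator | None = None,
    site_counts: Sequence[int] | np.ndarray | None = None,
) -> LatticeEnsemble:
    """Create an empty ensemble for one titration point.

    ``site_counts`` overrides the exponential sampling (used when decorating
    externally generated filaments).  In stoichiometric mode
    (``total_site_conc is None``) the site concentration equals
    ``ligand_total``.
    """
    rng = rng or np.random.default_rng(config.seed)
    if ligand_total is None:
        ligand_total = config.ligand_totals[0] if config.ligand_totals else 0.0
    if site_counts is None:
        site_counts = _sample_site_counts(config, rng)
    else:
        site_counts = np.asarray(site_counts, dtype=np.int64)
        if np.any(site_counts < 1):
            raise ConfigError("site counts must be >= 1")
    M = int(site_counts.sum())
    site_conc = config.total_site_conc
    if site_conc is None:
        site_conc = ligand_total if ligand_total > 0 else 1.0
    u = site_conc / M
    free_count = int(round(ligand_total / u))
    lattice_id = np.repeat(np.arange(site_counts.size), site_counts)
    return LatticeEnsemble(
        occupancy=np.zeros(M, dtype=np.int8),
        lattice_id=lattice_id,
        site_counts=site_counts,
        conc_per_molecule=u,
        free_count=free_count,
        ligand_total=float(ligand_total),
        fixed_free=config.fixed_free,
    )


def step(
    ensemble: LatticeEnsemble,
    config: SimConfig,
    rng: np.random.Generator,
) -> LatticeEnsemble:
    """Advance the ensemble by one synchronous iteration (in place).

    All events are decided from the pre-step state.  Binding candidates in
    excess of the available free-ligand pool are rejected uniformly at random
    (random site order); ligand count is conserved exactly.
    """
    occ = ensemble.occupancy
    free_conc = ensemble.free_ligand
    p_on = config.k1 * free_conc * config.dt
    p_off_base = config.k_minus1 * config.dt
    if p_on >= 1.0 or p_off_base >= 1.0:
        raise ConfigError(
            f"per-event probability >= 1 at iteration {ensemble.iteration} "
            f"(p_on={p_on:.3g}, p_off={p_off_base:.3g}); reduce dt"
        )

    nbr = ensemble.neighbor_numbers()
    bound = occ.astype(bool)
    empty = ~bound

    # binding
    cand = np.flatnonzero(empty & (rng.random(occ.size) < p_on))
    if ensemble.fixed_free is None and cand.size > ensemble.free_count:
        cand = rng.choice(cand, size=ensemble.free_count, replace=False)

    # unbinding: p = k_minus1 * sigma^(-n) * dt
    p_off = p_off_base * np.power(config.sigma, -nbr[bound].astype(float))
    unbind_idx = np.flatnonzero(bound)[rng.random(int(bound.sum())) < p_off]

    occ[cand] = 1
    occ[unbind_idx] = 0
    if ensemble.fixed_free is None:
        ensemble.free_count += int(unbind_idx.size) - int(cand.size)
        assert ensemble.free_count >= 0
    ensemble.iteration += 1
    return ensemble


@dataclass
class SteadyStateResult:
    """Trajectory and steady-state summary for one titration point."""

    ligand_total: float
    theta_t: np.ndarray
    free_t: np.ndarray
    tally_t: np.ndarray  # iterations x 3 counts of bound ligands by n
    converged: bool
    ensemble: LatticeEnsemble
    window: int

    @property
    def theta_ss(self) -> float:
        """Steady-state θ: mean over the final window."""
        return float(self.theta_t[-self.window:].mean())

    @property
    def free_ss(self) -> float:
        return float(self.free_t[-self.window:].mean())

    @property
    def tally_ss(self) -> np.ndarray:
        """Mean class counts (n = 0, 1, 2) over the final window."""
        return self.tally_t[-self.window:].mean(axis=0)

    @property
    def theta_lattice_sd(self) -> float:
        return float(self.ensemble.per_lattice_theta().std(ddof=1))


def run_to_steady_state(
    config: SimConfig,
    ligand_total: float | None = None,
    rng: np.random.Generator | None = None,
    site_counts: np.ndarray | None = None,
) -> SteadyStateResult:
    """Iterate one titration point until θ's moving-window mean stabilizes.

    Convergence: the mean of θ over the last ``window`` iterations differs
    from the mean over the preceding window by less than ``tol``.
    Non-convergence within ``max_iterations`` is flagged, not raised.
    """
    rng = rng or np.random.default_rng(config.seed)
    ens = init_ensemble(config, ligand_total, rng=rng, site_counts=site_counts)
    w = config.window
    thetas, frees, tallies = [], [], []
    converged = False
    for _ in range(config.max_iterations):
        step(ens, config, rng)
        thetas.append(ens.theta)
        frees.append(ens.free_ligand)
        tallies.append(ens.neighbor_tally())
        if len(thetas) >= 2 * w:
            recent = np.mean(thetas[-w:])
            prev = np.mean(thetas[-2 * w:-w])
            if abs(recent - prev) < config.tol:
                converged = True
                break
    if not converged:
        logger.warning(
            "steady state not reached in %d iterations (ligand_total=%g nM)",
            config.max_iterations, ens.ligand_total,
        )
    return SteadyStateResult(
        ligand_total=ens.ligand_total,
        theta_t=np.asarray(thetas),
        free_t=np.asarray(frees),
        tally_t=np.asarray(tallies),
        converged=converged,
        ensemble=ens,
        window=w,
    )


def simulate_isotherm(
    config: SimConfig,
    group: str = "simulation",
) -> tuple[BindingIsotherm, list[SteadyStateResult]]:
    """Steady-state binding isotherm across the configured titration.

    One independent run per ligand total (substream seeds spawned from
    ``config.seed``); each point is (steady-state free ligand, θ) with the SD
    of per-lattice bound fractions.
    """
    if len(config.ligand_totals) < 4:
        raise ConfigError("need at least 4 titration points for an isotherm")
    streams = np.random.SeedSequence(config.seed).spawn(len(config.ligand_totals))
    results = []
    for ligand_total, ss in zip(config.ligand_totals, streams):
        rng = np.random.default_rng(ss)
        results.append(run_to_steady_state(config, ligand_total, rng=rng))
    free = np.array([r.free_ss for r in results])
    theta = np.array([r.theta_ss for r in results])
    sd = np.array([r.theta_lattice_sd for r in results])
    order = np.argsort(free)
    iso = BindingIsotherm(
        concentrations=free[order],
        response=theta[order],
        sd=sd[order],
        response_kind="saturation",
        group=group,
    )
    return iso, [results[i] for i in order]


@dataclass
class CalibrationResult:
    config: SimConfig
    fit: HillParameters
    trace: list[tuple[float, float]]  # (k1/k_minus1 ratio, fitted Kd)
    converged: bool


def averaged_isotherm(
    config: SimConfig,
    n_seeds: int = 3,
    group: str = "simulation",
) -> tuple[BindingIsotherm, list[list[SteadyStateResult]]]:
    """Isotherm with points averaged over independent replicate sweeps.

    Runs ``simulate_isotherm`` under ``n_seeds`` seeds derived from
    ``config.seed`` and averages steady-state (free, θ) per titration point;
    the per-point SD is taken across replicate θ values.
    """
    frees, thetas, all_results = [], [], []
    for s in range(n_seeds):
        iso_s, res = simulate_isotherm(config.replace(seed=config.seed + 7919 * s))
        res = sorted(res, key=lambda r: r.ligand_total)
        frees.append([r.free_ss for r in res])
        thetas.append([r.theta_ss for r in res])
        all_results.append(res)
    free = np.mean(frees, axis=0)
    theta = np.mean(thetas, axis=0)
    sd = np.std(thetas, axis=0, ddof=1) if n_seeds > 1 else None
    order = np.argsort(free)
    iso = BindingIsotherm(
        concentrations=free[order],
        response=theta[order],
        sd=None if sd is None else np.maximum(sd[order], 1e-4),
        response_kind="saturation",
        group=group,
    )
    return iso, all_results


def _fit_at_ratio(
    config: SimConfig, ratio: float, n_seeds: int = 3
) -> tuple[HillParameters, SimConfig]:
    cfg = config.replace(k1=ratio * config.k_minus1)
    iso, _ = averaged_isotherm(cfg, n_seeds=n_seeds)
    return fit_hill(iso, fix_scale=1.0), cfg


def calibrate_rate_ratio(
    target_kd: float,
    config: SimConfig,
    rel_tol: float = 0.05,
    max_octaves: int = 10,
    max_bisections: int = 30,
    n_seeds: int = 3,
) -> CalibrationResult:
    """Adjust ``k1/k_minus1`` so the Hill-fit ``K_d`` of the simulated
    isotherm matches ``target_kd`` (nM).

    ``sigma`` is held fixed.  The fitted ``K_d`` decreases monotonically with
    the ratio, so a bracket is expanded in octaves around the starting ratio
    and then bisected on ``log(ratio)``.  Each evaluation averages the
    isotherm over ``n_seeds`` replicate sweeps and reuses the same seeds,
    making the objective deterministic.
    """
    if target_kd <= 0:
        raise ConfigError("target_kd must be positive")
    trace: list[tuple[float, float]] = []

    def eval_at(log_ratio: float) -> tuple[HillParameters, SimConfig]:
        fit, cfg = _fit_at_ratio(config, float(np.exp(log_ratio)), n_seeds=n_seeds)
        trace.append((float(np.exp(log_ratio)), fit.kd))
        return fit, cfg

    x0 = float(np.log(config.k1 / config.k_minus1))
    fit0, cfg0 = eval_at(x0)
    f0 = fit0.kd
    if abs(f0 / target_kd - 1.0) < rel_tol:
        return CalibrationResult(cfg0, fit0, trace, True)

    # expand bracket: the fitted Kd decreases monotonically with the ratio
    direction = 1.0 if f0 > target_kd else -1.0
    x_prev, f_prev = x0, f0
    lo = hi = x0
    found = False
    for k in range(1, max_octaves + 1):
        x1 = x0 + direction * k * np.log(2.0)
        try:
            f1 = eval_at(x1)[0].kd
        except (FitError, ConfigError):
            # isotherm degenerate (flat) or rates invalid at this extreme:
            # no bracket in this direction
            break
        if (f1 - target_kd) * (f_prev - target_kd) <= 0:
            lo, hi = (x_prev, x1) if x_prev < x1 else (x1, x_prev)
            found = True
            break
        x_prev, f_prev = x1, f1
    if not found:
        raise ConfigError(
            f"could not bracket target Kd={target_kd:g} nM within "
            f"{max_octaves} octaves of k1/k_minus1"
        )

    best_fit, best_cfg, best_err = None, None, np.inf
    for _ in range(max_bisections):
        mid = 0.5 * (lo + hi)
        fit, cfg = eval_at(mid)
        err = abs(fit.kd / target_kd - 1.0)
        if err < best_err:
            best_fit, best_cfg, best_err = fit, cfg, err
        if err < rel_tol:
            return CalibrationResult(cfg, fit, trace, True)
        # kd decreases with ratio: if kd too big, increase ratio
        if fit.kd > target_kd:
            lo = mid
        else:
            hi = mid
    logger.warning("rate-ratio calibration hit bisection limit (best err %.3g)", best_err)
    return CalibrationResult(best_cfg, best_fit, trace, False)


def calibrate_sigma_grid(
    target_kd: float,
    target_nh: float,
    config: SimConfig,
    sigma_grid: Sequence[float] = (1.0, 1.5, 2.0, 3.0, 5.0, 10.0),
    rel_tol: float = 0.05,
    n_seeds: int = 3,
) -> tuple[CalibrationResult, list[dict]]:
    """Joint coarse calibration: for each σ on the grid, calibrate
    ``k1/k_minus1`` against ``target_kd`` and keep the σ whose fitted Hill
    coefficient is nearest ``target_nh``.
    """
    records = []
    candidates: list[tuple[float, bool, CalibrationResult]] = []
    for sigma in sigma_grid:
        try:
            cal = calibrate_rate_ratio(target_kd, config.replace(sigma=sigma),
                                       rel_tol=rel_tol, n_seeds=n_seeds)
        except ConfigError as exc:
            logger.warning("sigma=%g calibration failed: %s", sigma, exc)
            continue
        records.append({
            "sigma": sigma,
            "ratio": cal.config.k1 / cal.config.k_minus1,
            "kd": cal.fit.kd,
            "n_h": cal.fit.n_h,
            "converged": cal.converged,
        })
        candidates.append((abs(cal.fit.n_h - target_nh), cal.converged, cal))
    if not candidates:
        raise ConfigError("sigma-grid calibration failed at every grid point")
    converged = [c for c in candidates if c[1]]
    best = min(converged or candidates, key=lambda c: c[0])[2]
    return best, records


@dataclass
class NeighborAbundance:
    """Neighbor-class composition of bound ligands across a titration.

    ``fractions`` holds, per concentration, the fraction of bound ligands with
    0, 1 and 2 bound neighbors; ``integrated`` is the normalized area under
    each class's abundance curve across the titration (percent, summing to
    100).
    """

    free_ligand: np.ndarray
    fractions: np.ndarray  # n_points x 3
    counts: np.ndarray     # n_points x 3
    integrated: np.ndarray  # 3, percent
    axis: str
    weight: str


def neighbor_abundance(
    results: Sequence[SteadyStateResult],
    axis: Literal["log", "linear"] = "log",
    weight: Literal["count", "fraction"] = "count",
) -> NeighborAbundance:
    """Classify bound ligands by bound-neighbor number across the titration.

    At each steady-state point every bound ligand has 0, 1 or 2 bound nearest
    neighbors (isolated, one-side, two-side).  Each class's abundance curve —
    mean steady-state counts by default, or per-point fractions with
    ``weight="fraction"`` — is integrated over the titration by the trapezoid
    rule on the free-ligand axis (log-scaled by default, as abundance curves
    are plotted against a logarithmic concentration axis) and the three areas
    are normalized to sum to 100%.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 titration points to integrate")
    pts = sorted(results, key=lambda r: r.free_ss)
    free = np.array([r.free_ss for r in pts])
    counts = np.vstack([r.tally_ss for r in pts])
    totals = counts.sum(axis=1)
    if not np.any(totals > 0):
        raise ValueError("no bound ligands anywhere on the titration")
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
    x = np.log10(free) if axis == "log" else free
    y = counts if weight == "count" else fractions
    areas = np.trapezoid(y, x=x, axis=0)
    integrated = 100.0 * areas / areas.sum()
    return NeighborAbundance(
        free_ligand=free,
        fractions=fractions,
        counts=counts,
        integrated=integrated,
        axis=axis,
        weight=weight,
    )


def mean_neighbors_closure(theta: float, sigma: float) -> float:
    """Quasi-chemical estimate of the mean bound-neighbor number ⟨n⟩.

    For an infinite lattice at coverage θ with pairwise Boltzmann factor σ the
    conditional probability ``p`` that a given neighbor of a bound ligand is
    bound solves the quasi-chemical quadratic

        θ(σ−1)·p² − (2σθ + 1 − 2θ)·p + σθ = 0,

    and ⟨n⟩ = 2p.  Reduces to random mixing (p = θ) at σ = 1.
    """
    if theta <= 0.0:
        return 0.0
    if theta >= 1.0:
        return 2.0
    if abs(sigma - 1.0) < 1e-12:
        return 2.0 * theta
    a = theta * (sigma - 1.0)
    b = -(2.0 * sigma * theta + 1.0 - 2.0 * theta)
    c = sigma * theta
    disc = b * b - 4.0 * a * c
    p = (-b - np.sqrt(max(disc, 0.0))) / (2.0 * a)
    return 2.0 * float(np.clip(p, 0.0, 1.0))


def _meanfield_rhs(theta: float, config: SimConfig, ligand_total: float,
                   site_conc: float) -> float:
    if config.fixed_free is not None:
        L = config.fixed_free
    else:
        L = max(ligand_total - theta * site_conc, 0.0)
    n_bar = mean_neighbors_closure(theta, config.sigma)
    return (config.k1 * L * (1.0 - theta)
            - config.k_minus1 * config.sigma ** (-n_bar) * theta)


def meanfield_ode(
    config: SimConfig,
    ligand_total: float | None = None,
    n_steps: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mean-field trajectory θ(t).

    Integrates dθ/dt = k1·[L]_t·(1−θ) − k_minus1·σ^(−⟨n⟩)·θ with fixed-step
    RK4 at the simulation time step, mass conservation for ``[L]_t`` and the
    quasi-chemical ⟨n⟩ closure.  Returns (times, θ) sampled at every step.
    """
    if ligand_total is None:
        ligand_total = config.ligand_totals[0]
    site_conc = config.total_site_conc
    if site_conc is None:
        site_conc = ligand_total if ligand_total > 0 else 1.0
    n_steps = n_steps or config.max_iterations
    dt = config.dt
    theta = 0.0
    thetas = np.empty(n_steps + 1)
    thetas[0] = 0.0
    for i in range(n_steps):
        f = lambda th: _meanfield_rhs(th, config, ligand_total, site_conc)
        k1_ = f(theta)
        k2_ = f(theta + 0.5 * dt * k1_)
        k3_ = f(theta + 0.5 * dt * k2_)
        k4_ = f(theta + dt * k3_)
        theta = theta + dt / 6.0 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        if theta < -1e-9 or theta > 1.0 + 1e-9:
            raise ConfigError(
                f"mean-field integration unstable at step {i} (θ={theta:.4g}); "
                "reduce dt"
            )
        theta = float(np.clip(theta, 0.0, 1.0))
        thetas[i + 1] = theta
    times = np.arange(n_steps + 1) * dt
    return times, thetas


def equilibrium_theta(
    config: SimConfig,
    ligand_total: float | None = None,
) -> float:
    """Fixed point of the mean-field rate balance (dθ/dt = 0)."""
    from scipy.optimize import brentq

    if ligand_total is None:
        ligand_total = config.ligand_totals[0]
    site_conc = config.total_site_conc
    if site_conc is None:
        site_conc = ligand_total if ligand_total > 0 else 1.0
    f = lambda th: _meanfield_rhs(th, config, ligand_total, site_conc)
    if f(0.0) <= 0.0:
        return 0.0
    return float(brentq(f, 0.0, 1.0 - 1e-12, xtol=1e-12))
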