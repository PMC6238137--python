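"""Individual-based stochastic simulation of the bequeathal life cycle.

``N`` breeding sites hold at most one adult each.  A generation runs
(a) birth: every resident adult produces one juvenile, whose allele copies
the mother with probability ``rho`` and is otherwise drawn from the current
population allele frequency (an ambient father pool); (b) dispersal: the
adult's allele decides who leaves — a Bequeath adult disperses itself
(surviving with probability ``d_A``), a Stay adult evicts the juvenile
(``d_J``); survivors land uniformly on any other site (global topology) or
on one of the two ring neighbours; (c) competition: every site's stayer and
arrivals enter one weighted lottery (weight ``C_A`` per adult, 1 per
juvenile) with a single winner; (d) survival: the winner lives to the next
season with its class survival (``s_A`` / ``s_J``), and surviving juveniles
mature.  All randomness flows through one NumPy generator per replicate, so
a configuration and seed fully determine the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core import ModelParams

__all__ = [
    "SimConfig",
    "SimState",
    "Trajectory",
    "InvasionEstimate",
    "inherit_alleles",
    "births_and_dispersal",
    "step_generation",
    "run_simulation",
    "estimate_invasion",
]

_ADULT, _JUV = 0, 1  # class codes
_S, _B = 0, 1  # allele codes


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation experiment."""

    params: ModelParams
    topology: Literal["global", "ring"] = "global"
    generations: int = 200
    initial_p: float = 0.5
    seed: int = 0
    replicates: int = 1
    stop_on_absorption: bool = False

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.initial_p <= 1.0:
            raise ValueError("initial_p must lie in [0, 1]")
        if self.topology not in ("global", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class SimState:
    """Per-site occupancy and occupant alleles at the start of a season.

    All occupants at the start of a season are adults (winning juveniles
    matured at the end of the previous one).
    """

    occupied: np.ndarray  # bool[N]
    allele: np.ndarray  # int8[N], valid where occupied
    generation: int = 0

    @property
    def R(self) -> float:
        return float(np.mean(self.occupied))

    @property
    def p(self) -> float:
        """Bequeath frequency among occupants; NaN for an empty habitat."""
        n = int(np.sum(self.occupied))
        if n == 0:
            return float("nan")
        return float(np.sum(self.allele[self.occupied] == _B) / n)


@dataclass
class Trajectory:
    """Per-generation (p, R) series and the terminal outcome."""

    p: np.ndarray
    R: np.ndarray
    outcome: Literal["B_fixed", "S_fixed", "polymorphic", "extinct"]
    generations: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": np.arange(len(self.p)), "p": self.p, "R": self.R}
        )


def initial_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Saturated habitat with a fixed count of Bequeath alleles.

    Exactly ``round(initial_p * N)`` sites get the B allele, placed
    uniformly at random, which pins the initial frequency even for rare
    invaders.
    """
    N = config.params.N
    allele = np.full(N, _S, dtype=np.int8)
    n_B = int(round(config.initial_p * N))
    allele[rng.choice(N, size=n_B, replace=False)] = _B
    return SimState(occupied=np.ones(N, dtype=bool), allele=allele)


def inherit_alleles(
    mother_alleles: np.ndarray, population_freq_p: float, rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring alleles under the mixture transmission rule.

    Each offspring copies its mother's allele with probability ``rho`` and
    otherwise draws B with probability equal to the current population
    frequency (the ambient father pool).  ``rho = 1`` is clonal
    transmission; ``rho = 0.5`` realises haploid sexual reproduction with
    random mating, giving a parent-offspring allele correlation of 1/2.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    n = len(mother_alleles)
    copy = rng.random(n) < rho
    ambient = (rng.random(n) < population_freq_p).astype(np.int8)
    return np.where(copy, mother_alleles, ambient).astype(np.int8)


def births_and_dispersal(
    state: SimState, params: ModelParams, topology: str, rng: np.random.Generator
):
    """Birth and dispersal phases of one generation.

    Returns ``(stay_site, stay_cls, stay_allele, dest, disp_cls,
    disp_allele)``: the stayer left at each occupied site and the surviving
    dispersers with their destination sites.  The household's (mother's)
    allele decides who leaves: a Bequeath adult disperses itself, a Stay
    adult evicts its juvenile.
    """
    N = params.N
    occ_idx = np.flatnonzero(state.occupied)
    mothers = state.allele[occ_idx]
    pop_p = float(np.mean(mothers == _B)) if occ_idx.size else 0.0
    offspring = inherit_alleles(mothers, pop_p, params.rho, rng)

    bequeaths = mothers == _B
    stay_cls = np.where(bequeaths, _JUV, _ADULT)  # B leaves its juvenile home
    stay_allele = np.where(bequeaths, offspring, mothers)
    disp_cls = np.where(bequeaths, _ADULT, _JUV)
    disp_allele = np.where(bequeaths, mothers, offspring)

    # Dispersal survival, then destination.
    d = np.where(disp_cls == _ADULT, params.d_A, params.d_J)
    survives = rng.random(occ_idx.size) < d
    origin = occ_idx[survives]
    disp_cls = disp_cls[survives]
    disp_allele = disp_allele[survives]
    if topology == "global":
        draw = rng.integers(0, N - 1, size=origin.size)
        dest = draw + (draw >= origin)  # uniform over the other N-1 sites
    elif topology == "ring":
        step = rng.choice(np.array([-1, 1]), size=origin.size)
        dest = (origin + step) % N
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return occ_idx, stay_cls, stay_allele, dest, disp_cls, disp_allele


def step_generation(
    state: SimState, params: ModelParams, topology: str, rng: np.random.Generator
) -> SimState:
    """Advance one full life cycle: birth, dispersal, competition, survival."""
    N = params.N
    if not state.occupied.any():
        return SimState(
            occupied=np.zeros(N, dtype=bool),
            allele=state.allele.copy(),
            generation=state.generation + 1,
        )

    occ_idx, stay_cls, stay_allele, dest, disp_cls, disp_allele = (
        births_and_dispersal(state, params, topology, rng)
    )

    # One lottery per site over stayers + arrivals, via the exponential
    # race: min of Exp(1)/weight identifies the weighted-draw winner.
    site = np.concatenate([occ_idx, dest])
    cls = np.concatenate([stay_cls, disp_cls]).astype(np.int8)
    allele = np.concatenate([stay_allele, disp_allele]).astype(np.int8)
    weight = np.where(cls == _ADULT, params.C_A, 1.0)
    score = rng.exponential(size=site.size) / weight
    best = np.full(N, np.inf)
    np.minimum.at(best, site, score)
    is_winner = score == best[site]  # ties have probability zero

    win_site = site[is_winner]
    win_cls = cls[is_winner]
    win_allele = allele[is_winner]

    # Season survival of winners; surviving juveniles mature.
    s = np.where(win_cls == _ADULT, params.s_A, params.s_J)
    alive = rng.random(win_site.size) < s

    occupied = np.zeros(N, dtype=bool)
    new_allele = state.allele.copy()
    occupied[win_site[alive]] = True
    new_allele[win_site[alive]] = win_allele[alive]
    return SimState(
        occupied=occupied, allele=new_allele, generation=state.generation + 1
    )


def _single_run(config: SimConfig, seed: int) -> Trajectory:
    rng = np.random.default_rng(seed)
    state = initial_state(config, rng)
    ps = [state.p]
    Rs = [state.R]
    for _ in range(config.generations):
        state = step_generation(state, config.params, config.topology, rng)
        ps.append(state.p)
        Rs.append(state.R)
        if config.stop_on_absorption and (
            state.R == 0.0 or state.p in (0.0, 1.0)
        ):
            break
    p_arr = np.array(ps)
    R_arr = np.array(Rs)
    if R_arr[-1] == 0.0:
        outcome = "extinct"
    elif p_arr[-1] == 1.0:
        outcome = "B_fixed"
    elif p_arr[-1] == 0.0:
        outcome = "S_fixed"
    else:
        outcome = "polymorphic"
    return Trajectory(p=p_arr, R=R_arr, outcome=outcome, generations=len(ps) - 1)


def run_simulation(config: SimConfig) -> Trajectory | list[Trajectory]:
    """Run the configured simulation; a list is returned for replicates > 1.

    Replicate ``i`` uses seed ``config.seed + i``, so the whole experiment
    is reproducible from the configuration alone.
    """
    if config.replicates == 1:
        return _single_run(config, config.seed)
    return [_single_run(config, config.seed + i) for i in range(config.replicates)]


@dataclass(frozen=True)
class InvasionEstimate:
    """Replicate fixation frequency of an invading allele, with Wilson CI."""

    invader: str
    fixed: int
    replicates: int
    estimate: float
    ci_low: float
    ci_high: float


def estimate_invasion(config: SimConfig, invader: Literal["B", "S"]) -> InvasionEstimate:
    """Estimate the invader's fixation probability over replicates.

    The invader starts at frequency ``config.initial_p`` (e.g. 5/N); each
    replicate runs until fixation, loss, extinction, or the generation cap.
    Under neutrality the fixation probability equals the initial frequency,
    which anchors the significance comparison.
    """
    if invader == "B":
        cfg = config
        target = "B_fixed"
    elif invader == "S":
        cfg = SimConfig(
            params=config.params,
            topology=config.topology,
            generations=config.generations,
            initial_p=1.0 - config.initial_p,
            seed=config.seed,
            replicates=config.replicates,
            stop_on_absorption=True,
        )
        target = "S_fixed"
    else:
        raise ValueError(f"invader must be 'B' or 'S', got {invader!r}")
    if not cfg.stop_on_absorption:
        cfg = SimConfig(
            params=cfg.params,
            topology=cfg.topology,
            generations=cfg.generations,
            initial_p=cfg.initial_p,
            seed=cfg.seed,
            replicates=cfg.replicates,
            stop_on_absorption=True,
        )
    trajectories = run_simulation(cfg)
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    fixed = sum(t.outcome == target for t in trajectories)
    n = len(trajectories)
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(fixed, n, alpha=0.05, method="wilson")
    return InvasionEstimate(
        invader=invader,
        fixed=fixed,
        replicates=n,
        estimate=fixed / n,
        ci_low=float(lo),
        ci_high=float(hi),
    )
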