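"""ESS analysis under local (ring-lattice) dispersal.

On the ring each site has exactly two neighbours, so at most two immigrants
can ever reach a focal site and the Poisson limit does not apply.  At the
monomorphic boundaries (``p`` = 0 or 1) the immigration law is binomial:
each neighbour independently contributes an immigrant with probability
``R (p d_A + (1-p) d_J) / 2`` (the neighbour must be occupied, its
disperser must survive, and it moves toward the focal site half of the
time).  Immigrant class matches the resident strategy: a Stay population
(``p = 0``) exports juveniles, a Bequeath population (``p = 1``) exports
adults.

At an away site the focal disperser itself consumes one of the two inbound
slots, so only one "coin" remains to flip — the key difference from global
dispersal, where the ambient immigrant field is independent of the focal
disperser.  Interior frequencies are out of reach analytically (local
dispersal builds spatial genotype correlations); the individual-based
simulator covers them.

The residency recurrence is mean-field: it uses the population residency
rate for each neighbour independently, ignoring spatial occupancy
correlations.  Its fidelity is assessed against the simulator, not assumed.
"""

from __future__ import annotations

import numpy as np

from .core import ModelParams, local_immigrant_distribution
from .global_dispersal import (
    FitnessComponents,
    SteadyState,
    _classify_from_differentials,
)

__all__ = [
    "local_winner_class_probs",
    "local_steady_state_R",
    "local_boundary_fitness",
    "local_selection_differential",
    "classify_ess_local",
]


def local_winner_class_probs(params: ModelParams, R: float):
    """Winner-class probabilities with two-neighbour binomial immigration.

    Same contract as :func:`bequeathal.global_dispersal.winner_class_probs`
    but restricted to monomorphic ``p``; all immigrants share one class.
    """
    from .global_dispersal import WinnerClassProbs

    dist = local_immigrant_distribution(params, R, "home")
    n_A, n_J, pr = dist.support()
    C = params.C_A
    imm = n_A * C + n_J

    win_adult_defender = np.sum(pr * (C + n_A * C) / (C + imm))
    win_juv_defender = np.sum(pr * n_A * C / (1.0 + imm))
    pr_A_given_O = float(
        (1.0 - params.p) * win_adult_defender + params.p * win_juv_defender
    )

    nonzero = imm > 0
    pr_A_given_V = float(np.sum(pr[nonzero] * n_A[nonzero] * C / imm[nonzero]))
    pr_J_given_V = float(np.sum(pr[nonzero] * n_J[nonzero] / imm[nonzero]))
    return WinnerClassProbs(
        pr_A_given_O=pr_A_given_O,
        pr_A_given_V=pr_A_given_V,
        pr_J_given_V=pr_J_given_V,
        pr_stays_vacant=dist.zero_prob(),
    )


def local_steady_state_R(
    params: ModelParams,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    R0: float = 1.0,
) -> SteadyState:
    """Mean-field fixed point of the residency recurrence on the ring.

    A vacant site is colonised unless both neighbours fail to send an
    immigrant, i.e. with probability ``1 - (1 - pi_arrive)^2``.
    """
    if params.p not in (0.0, 1.0):
        raise ValueError("local steady state requires monomorphic p in {0, 1}")
    R = R0
    for it in range(1, max_iter + 1):
        wcp = local_winner_class_probs(params, R)
        occupied = (
            wcp.pr_A_given_O * params.s_A + (1.0 - wcp.pr_A_given_O) * params.s_J
        )
        vacant = wcp.pr_A_given_V * params.s_A + wcp.pr_J_given_V * params.s_J
        R_next = R * occupied + (1.0 - R) * vacant
        residual = abs(R_next - R)
        R = min(max(R_next, 0.0), 1.0)
        if residual < tol:
            return SteadyState(R=R, iterations=it, converged=True, residual=residual)
    return SteadyState(R=R, iterations=max_iter, converged=False, residual=residual)


def local_boundary_fitness(
    params: ModelParams, invader: str, R: float | None = None
) -> FitnessComponents:
    """Inclusive fitness of both strategies at a monomorphic boundary.

    ``invader = "B"`` analyses a rare Bequeath lineage in a Stay population
    (``p = 0``); ``invader = "S"`` a rare Stay lineage in a Bequeath
    population (``p = 1``).  Home components face Binomial(2, pi_arrive)
    immigrants; away components face Binomial(1, pi_arrive) additional
    immigrants plus, with probability ``R``, a resident defender whose
    class is set by the resident strategy (Stay keeps adults home, Bequeath
    leaves juveniles).  Relatedness weighting mirrors the global model:
    ``W_B = rho * home_B + away_B``, ``W_S = home_S + rho * away_S``.
    """
    if invader not in ("B", "S"):
        raise ValueError(f"invader must be 'B' or 'S', got {invader!r}")
    params = params.with_(p=0.0 if invader == "B" else 1.0)
    if R is None:
        R = local_steady_state_R(params).R

    home = local_immigrant_distribution(params, R, "home")
    away = local_immigrant_distribution(params, R, "away")
    C = params.C_A

    h_nA, h_nJ, h_pr = home.support()
    h_imm = h_nA * C + h_nJ
    pr_home_B = params.s_J * float(np.sum(h_pr / (1.0 + h_imm)))
    pr_home_S = params.s_A * float(np.sum(h_pr * C / (C + h_imm)))

    a_nA, a_nJ, a_pr = away.support()
    a_imm = a_nA * C + a_nJ
    # Resident defender at the away site: juvenile (weight 1) in a Bequeath
    # population, adult (weight C_A) in a Stay population.
    res_w = 1.0 if params.p == 1.0 else C
    away_B = (1.0 - R) * C / (C + a_imm) + R * C / (C + res_w + a_imm)
    pr_away_B = params.d_A * params.s_A * float(np.sum(a_pr * away_B))
    away_S = (1.0 - R) / (1.0 + a_imm) + R / (1.0 + res_w + a_imm)
    pr_away_S = params.d_J * params.s_J * float(np.sum(a_pr * away_S))

    rho = params.rho
    return FitnessComponents(
        pr_home_B=pr_home_B,
        pr_away_B=pr_away_B,
        pr_home_S=pr_home_S,
        pr_away_S=pr_away_S,
        W_B=rho * pr_home_B + pr_away_B,
        W_S=pr_home_S + rho * pr_away_S,
    )


def local_selection_differential(params: ModelParams, invader: str) -> float:
    """``W(B) - W(S)`` at the named monomorphic boundary (local dispersal)."""
    return local_boundary_fitness(params, invader).delta_W


def classify_ess_local(params: ModelParams) -> str:
    """ESS classification under local dispersal (same labels as global).

    The Bequeath-invasion differential is evaluated in a Stay resident
    population and the Stay-invasion differential in a Bequeath one, each
    at its own mean-field residency steady state.
    """
    from .dynamics import viability

    if not viability(params, "S"):
        return "nonviable"
    dW0 = local_selection_differential(params, "B")
    dW1 = local_selection_differential(params, "S")
    return _classify_from_differentials(dW0, dW1)
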