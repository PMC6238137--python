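"""Inclusive fitness and ESS analysis under global dispersal.

Under global dispersal every site is equidistant, so in the
large-population limit the immigrants at any site follow the Poisson
mixture law of :func:`bequeathal.core.global_immigrant_distribution` and
the whole system is summarised by two state variables: the Bequeath
frequency ``p`` and the residency rate ``R`` (the fraction of sites with a
resident at the start of the season).

The residency rate obeys the recurrence

    R' = R [Pr(A|O) s_A + (1 - Pr(A|O)) s_J]
         + (1 - R) [Pr(A|V) s_A + Pr(J|V) s_J]

where Pr(A|O) is the probability the winner of an *occupied* site is an
adult, and Pr(A|V), Pr(J|V) are the probabilities an adult or a juvenile
wins a *vacant* site (which stays vacant only if nobody arrives).  An
occupied site's defender is a juvenile with probability ``p`` (a Bequeath
household left its offspring home) and an adult with probability ``1 - p``.

Inclusive fitness of the two strategies is accounted per household:

    W(B) = rho * Pr(home|B) + Pr(away|B)
    W(S) = Pr(home|S) + rho * Pr(away|S)

where the "home" component belongs to the juvenile for B (hence devalued by
the parent-offspring relatedness ``rho``) and to the adult for S, and
vice versa for the "away" component.  The strategy frequency dynamics are
governed by the sign of ``W(B) - W(S)``; evolutionary stability is decided
at the monomorphic boundaries ``p = 0`` (can B invade?) and ``p = 1``
(can S invade back?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelParams, global_immigrant_distribution

__all__ = [
    "WinnerClassProbs",
    "SteadyState",
    "FitnessComponents",
    "winner_class_probs",
    "steady_state_R",
    "fitness_components",
    "selection_differential",
    "classify_ess",
    "TIE_TOL",
]

#: |W(B) - W(S)| below this is treated as a neutral tie (e.g. the exactly
#: symmetric point C_A = 1, rho = 1) rather than a sign.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class WinnerClassProbs:
    """Class of the lottery winner at occupied and vacant sites."""

    pr_A_given_O: float
    pr_A_given_V: float
    pr_J_given_V: float
    pr_stays_vacant: float


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the residency recurrence, with convergence metadata."""

    R: float
    iterations: int
    converged: bool
    residual: float


@dataclass(frozen=True)
class FitnessComponents:
    """Home/away site-acquisition probabilities and inclusive fitness.

    ``pr_home_B`` is the probability the B household's juvenile retains the
    natal site (including its season survival ``s_J``); ``pr_away_B`` the
    probability the bequeathing adult survives dispersal, wins its away
    site and survives the season; ``pr_home_S`` / ``pr_away_S`` are the
    mirror-image quantities for Stay.  ``W_B`` and ``W_S`` combine them
    with the relatedness discount ``rho`` on the partner's share.
    """

    pr_home_B: float
    pr_away_B: float
    pr_home_S: float
    pr_away_S: float
    W_B: float
    W_S: float

    @property
    def delta_W(self) -> float:
        return self.W_B - self.W_S


def winner_class_probs(params: ModelParams, R: float) -> WinnerClassProbs:
    """Expected winner class at occupied and vacant sites.

    All expectations are over the global immigrant distribution at
    residency ``R``.  The defending side at an occupied site has weight
    ``C_A`` (adult defender, probability ``1 - p``) or 1 (juvenile left by
    a Bequeath parent, probability ``p``); immigrants add ``n_A C_A + n_J``
    to the lottery total.  A vacant site goes to whichever class wins the
    lottery among arrivals, and stays vacant only when none arrive.
    """
    dist = global_immigrant_distribution(params, R)
    n_A, n_J, pr = dist.support()
    C = params.C_A
    imm = n_A * C + n_J

    # Occupied site: probability the *winner* is an adult.
    win_adult_defender = np.sum(pr * (C + n_A * C) / (C + imm))
    with np.errstate(invalid="ignore"):
        juv_def = np.where(imm + 1.0 > 0, n_A * C / (1.0 + imm), 0.0)
    win_juv_defender = np.sum(pr * juv_def)
    pr_A_given_O = float(
        (1.0 - params.p) * win_adult_defender + params.p * win_juv_defender
    )

    # Vacant site: condition on at least one arrival.
    nonzero = imm > 0
    pr_A_given_V = float(np.sum(pr[nonzero] * n_A[nonzero] * C / imm[nonzero]))
    pr_J_given_V = float(np.sum(pr[nonzero] * n_J[nonzero] / imm[nonzero]))
    pr_stays_vacant = dist.zero_prob()
    return WinnerClassProbs(
        pr_A_given_O=pr_A_given_O,
        pr_A_given_V=pr_A_given_V,
        pr_J_given_V=pr_J_given_V,
        pr_stays_vacant=pr_stays_vacant,
    )


def _residency_map(params: ModelParams, R: float, wcp: WinnerClassProbs) -> float:
    occupied = wcp.pr_A_given_O * params.s_A + (1.0 - wcp.pr_A_given_O) * params.s_J
    vacant = wcp.pr_A_given_V * params.s_A + wcp.pr_J_given_V * params.s_J
    return R * occupied + (1.0 - R) * vacant


def steady_state_R(
    params: ModelParams,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    R0: float = 1.0,
) -> SteadyState:
    """Solve the residency recurrence to its fixed point by iteration.

    The immigrant distribution is rebuilt every step because its mean
    depends on the current residency.  Starting from a saturated habitat
    (``R0 = 1``) the map is a contraction toward the stable fixed point for
    all parameter regimes we use; nonviable populations decay toward 0.
    """
    R = R0
    for it in range(1, max_iter + 1):
        R_next = _residency_map(params, R, winner_class_probs(params, R))
        residual = abs(R_next - R)
        R = min(max(R_next, 0.0), 1.0)
        if residual < tol:
            return SteadyState(R=R, iterations=it, converged=True, residual=residual)
    return SteadyState(R=R, iterations=max_iter, converged=False, residual=residual)


def fitness_components(params: ModelParams, R: float) -> FitnessComponents:
    """Inclusive fitness of Bequeath and Stay at frequency ``p``, residency ``R``.

    Home components: the stayer (B's juvenile, S's adult) defends the natal
    site against the full immigrant draw.  Away components: the disperser
    (B's adult with survival ``d_A``, S's juvenile with ``d_J``) meets the
    same immigrant draw plus, with probability ``R``, a resident defender
    whose class mirrors the strategy mix (juvenile with probability ``p``,
    adult with ``1 - p``).  Season survival of the relevant class multiplies
    each term.
    """
    dist = global_immigrant_distribution(params, R)
    n_A, n_J, pr = dist.support()
    C = params.C_A
    imm = n_A * C + n_J
    p = params.p

    pr_home_B = params.s_J * float(np.sum(pr / (1.0 + imm)))
    pr_home_S = params.s_A * float(np.sum(pr * C / (C + imm)))

    away_B = (
        (1.0 - R) * C / (C + imm)
        + R * p * C / (C + 1.0 + imm)
        + R * (1.0 - p) * C / (2.0 * C + imm)
    )
    pr_away_B = params.d_A * params.s_A * float(np.sum(pr * away_B))

    away_S = (
        (1.0 - R) / (1.0 + imm)
        + R * p / (2.0 + imm)
        + R * (1.0 - p) / (1.0 + C + imm)
    )
    pr_away_S = params.d_J * params.s_J * float(np.sum(pr * away_S))

    rho = params.rho
    return FitnessComponents(
        pr_home_B=pr_home_B,
        pr_away_B=pr_away_B,
        pr_home_S=pr_home_S,
        pr_away_S=pr_away_S,
        W_B=rho * pr_home_B + pr_away_B,
        W_S=pr_home_S + rho * pr_away_S,
    )


def selection_differential(params: ModelParams) -> float:
    """``W(B) - W(S)`` at the ecological steady state for the given ``p``.

    Positive values mean selection pushes the Bequeath frequency up.
    """
    ss = steady_state_R(params)
    return fitness_components(params, ss.R).delta_W


def _classify_from_differentials(dW0: float, dW1: float) -> str:
    if abs(dW0) < TIE_TOL or abs(dW1) < TIE_TOL:
        return "boundary"
    if dW0 > 0 and dW1 > 0:
        return "B_only"
    if dW0 < 0 and dW1 < 0:
        return "S_only"
    if dW0 < 0 and dW1 > 0:
        return "both_ESS"
    return "neither_ESS"


def classify_ess(params: ModelParams) -> str:
    """ESS classification from the two monomorphic invasion boundaries.

    Evaluates the selection differential at ``p = 0`` (B invades a Stay
    population iff positive) and ``p = 1`` (B resists invasion by S iff
    positive), each at its own ecological steady state; a rare invader does
    not perturb the immigration field or the residency rate.

    Returns one of ``"B_only"``, ``"S_only"``, ``"both_ESS"``,
    ``"neither_ESS"``, ``"nonviable"`` (the monomorphic Stay population
    cannot persist: ``s_A + d_J s_J <= 1``), or ``"boundary"`` when a
    differential is within :data:`TIE_TOL` of zero (neutral symmetry).
    """
    from .dynamics import viability  # local import to avoid a cycle

    if not viability(params, "S"):
        return "nonviable"
    dW0 = selection_differential(params.with_(p=0.0))
    dW1 = selection_differential(params.with_(p=1.0))
    return _classify_from_differentials(dW0, dW1)
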