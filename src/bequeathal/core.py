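"""Shared model primitives: parameters, lottery competition, immigration laws.

The model describes a population breeding at discrete sites, one adult per
site.  Each season an adult produces one juvenile and either bequeaths the
natal site to it (the adult disperses; strategy B) or evicts it (the
juvenile disperses; strategy S).  Everyone arriving at or staying on a site
enters a single weighted lottery for ownership: adults carry competitive
weight ``C_A``, juveniles weight 1.

Immigration at a focal site is described by the distribution of
``(n_A, n_J)``, the numbers of adult and juvenile arrivals.  Under global
dispersal (all sites equidistant, large-population limit) the total count is
Poisson with mean ``lam = R (p d_A + (1-p) d_J)`` and each arrival is an
adult independently with probability ``pi = p d_A / (p d_A + (1-p) d_J)``.
Under local dispersal (ring lattice) each of the focal site's two neighbours
sends an immigrant with probability ``R (p d_A + (1-p) d_J) / 2`` — a
neighbour's disperser goes the other way half of the time — so the count is
binomial with at most two (home site) or one (away site, where the focal
disperser occupies one inbound slot) arrivals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "ImmigrantCounts",
    "ImmigrantDistribution",
    "lottery_win_probability",
    "global_immigrant_distribution",
    "local_immigrant_distribution",
    "truncate_support",
]

# Smallest Poisson upper-tail mass at which total-arrival enumeration stops.
_TAIL_TOL = 1e-12
_SUPPORT_CAP = 200


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """All rates and constants of the bequeathal model.

    Parameters
    ----------
    s_A, s_J
        Season (baseline) survival probability of adults / juveniles.
    d_A, d_J
        Probability an adult / juvenile survives dispersal.
    C_A
        Relative competitive ability of an adult against a juvenile
        (lottery weight ratio); must be positive, typically >= 1.
    rho
        Parent-offspring coefficient of relatedness (1 = clonal,
        0.5 = haploid sexual reproduction with random mating).
    p
        Population frequency of the Bequeath strategy.
    N
        Number of habitable sites (individual-based simulation only).
    """

    s_A: float = 1.0
    s_J: float = 1.0
    d_A: float = 1.0
    d_J: float = 1.0
    C_A: float = 2.0
    rho: float = 0.5
    p: float = 0.0
    N: int = 1000

    def __post_init__(self) -> None:
        for name in ("s_A", "s_J", "d_A", "d_J", "rho", "p"):
            _check_prob(name, getattr(self, name))
        if self.C_A <= 0:
            raise ValueError(f"C_A must be positive, got {self.C_A!r}")
        if self.N < 3:
            raise ValueError(f"N must be at least 3, got {self.N!r}")

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @property
    def disperser_pool(self) -> float:
        """Mean per-capita contribution to the dispersal pool,
        ``p d_A + (1-p) d_J``."""
        return self.p * self.d_A + (1.0 - self.p) * self.d_J

    @property
    def pi_adult(self) -> float:
        """Adult fraction of the surviving disperser pool; 0 by convention
        when the pool is empty."""
        pool = self.disperser_pool
        if pool == 0.0:
            return 0.0
        return self.p * self.d_A / pool


@dataclass(frozen=True)
class ImmigrantCounts:
    """Numbers of adult and juvenile immigrants at a site."""

    n_A: int
    n_J: int

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_J < 0:
            raise ValueError("immigrant counts must be non-negative")


def lottery_win_probability(
    focal_class: Literal["adult", "juvenile"],
    n_A: int,
    n_J: int,
    C_A: float,
) -> float:
    """Probability the focal individual wins the site lottery.

    ``n_A`` and ``n_J`` count the *other* contestants.  Each adult carries
    weight ``C_A`` and each juvenile weight 1; the winner is a single
    weighted draw, so the focal's chance is its weight over the total.

    Examples
    --------
    >>> lottery_win_probability("adult", 1, 0, C_A=2.0)
    0.5
    >>> lottery_win_probability("juvenile", 1, 1, C_A=2.0)
    0.25
    """
    if n_A < 0 or n_J < 0:
        raise ValueError("competitor counts must be non-negative")
    if C_A <= 0:
        raise ValueError("C_A must be positive")
    if focal_class == "adult":
        w = C_A
    elif focal_class == "juvenile":
        w = 1.0
    else:
        raise ValueError(f"unknown focal class {focal_class!r}")
    return w / (w + n_A * C_A + n_J)


@dataclass(frozen=True)
class ImmigrantDistribution:
    """Probability law of ``(n_A, n_J)`` arrivals at a focal site.

    ``mode`` selects the arrival process:

    - ``"global"``: total count Poisson(``lam``), each arrival an adult
      independently with probability ``pi_adult``;
    - ``"local_home"``: Binomial(2, ``pi_arrive``) arrivals (two inbound
      neighbour slots);
    - ``"local_away"``: Binomial(1, ``pi_arrive``) arrivals (the focal
      disperser holds the other slot).

    In the local modes every immigrant belongs to a single class
    (``local_class``), fixed by the monomorphic resident strategy.
    """

    mode: Literal["global", "local_home", "local_away"]
    lam: float = 0.0
    pi_adult: float = 0.0
    pi_arrive: float = 0.0
    local_class: Literal["adult", "juvenile"] = "juvenile"
    support_cap: int = _SUPPORT_CAP

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("mean arrival count lam must be non-negative")
        _check_prob("pi_adult", self.pi_adult)
        _check_prob("pi_arrive", self.pi_arrive)

    # -- support enumeration ------------------------------------------------

    def _total_count_pmf(self, tail_tol: float = _TAIL_TOL) -> np.ndarray:
        """pmf of the total arrival count n = n_A + n_J, truncated.

        The Poisson pmf is built by the multiplicative recurrence
        ``p_{n+1} = p_n lam / (n + 1)``, stopping at the smallest n whose
        upper-tail mass is below ``tail_tol`` (capped at ``support_cap``).
        """
        if self.mode == "global":
            if self.lam == 0.0:
                return np.array([1.0])
            pmf = [np.exp(-self.lam)]
            cum = pmf[0]
            n = 0
            while cum < 1.0 - tail_tol and n < self.support_cap:
                pmf.append(pmf[-1] * self.lam / (n + 1))
                cum += pmf[-1]
                n += 1
            return np.array(pmf)
        q = 1.0 - self.pi_arrive
        if self.mode == "local_home":
            return np.array(
                [q * q, 2.0 * self.pi_arrive * q, self.pi_arrive**2]
            )
        return np.array([q, self.pi_arrive])

    def support(
        self, tail_tol: float = _TAIL_TOL
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Enumerate ``(n_A, n_J, probability)`` as flat arrays.

        Total mass is at least ``1 - tail_tol`` (exactly 1 for the finite
        local modes).
        """
        pn = self._total_count_pmf(tail_tol)
        if self.mode == "global":
            pi = self.pi_adult
        else:
            pi = 1.0 if self.local_class == "adult" else 0.0
        if pi == 0.0 or pi == 1.0:
            n = np.arange(len(pn))
            n_A = n if pi == 1.0 else np.zeros_like(n)
            n_J = n - n_A
            return n_A, n_J, pn
        # Thin each total count binomially over the two classes, in one
        # vectorised log-space evaluation over the triangular support.
        n_max = len(pn) - 1
        n = np.repeat(np.arange(n_max + 1), np.arange(1, n_max + 2))
        k = np.concatenate([np.arange(m + 1) for m in range(n_max + 1)])
        log_binom = (
            gammaln(n + 1.0)
            - gammaln(k + 1.0)
            - gammaln(n - k + 1.0)
            + k * np.log(pi)
            + (n - k) * np.log1p(-pi)
        )
        pr = pn[n] * np.exp(log_binom)
        return k, n - k, pr

    def pmf(self, n_A: int, n_J: int) -> float:
        """Probability of exactly ``n_A`` adult and ``n_J`` juvenile arrivals."""
        if n_A < 0 or n_J < 0:
            return 0.0
        n = n_A + n_J
        if self.mode == "global":
            if self.lam == 0.0:
                return 1.0 if n == 0 else 0.0
            p_n = stats.poisson.pmf(n, self.lam)
            return float(p_n * stats.binom.pmf(n_A, n, self.pi_adult))
        n_slots = 2 if self.mode == "local_home" else 1
        if n > n_slots:
            return 0.0
        class_ok = n_A == 0 if self.local_class == "juvenile" else n_J == 0
        if not class_ok:
            return 0.0
        return float(stats.binom.pmf(n, n_slots, self.pi_arrive))

    def zero_prob(self) -> float:
        """Probability of no arrivals at all (closed form)."""
        if self.mode == "global":
            return float(np.exp(-self.lam))
        n_slots = 2 if self.mode == "local_home" else 1
        return float((1.0 - self.pi_arrive) ** n_slots)

    def mean_arrivals(self) -> float:
        """Expected total number of immigrants at the focal site."""
        if self.mode == "global":
            return self.lam
        n_slots = 2 if self.mode == "local_home" else 1
        return n_slots * self.pi_arrive

    def expect(self, fn, tail_tol: float = _TAIL_TOL) -> float:
        """Expectation of ``fn(n_A, n_J)`` (vectorised) over the support."""
        n_A, n_J, pr = self.support(tail_tol)
        return float(np.sum(pr * fn(n_A, n_J)))


def global_immigrant_distribution(
    params: ModelParams, R: float
) -> ImmigrantDistribution:
    """Immigration law at a focal site under global dispersal.

    Each occupied site (fraction ``R``) emits one disperser that survives
    the journey with the class-appropriate probability; in the
    large-population limit arrivals at any one site are Poisson with mean
    ``lam = R (p d_A + (1-p) d_J)`` and each is an adult with probability
    ``pi = p d_A / (p d_A + (1-p) d_J)``.
    """
    _check_prob("R", R)
    lam = R * params.disperser_pool
    return ImmigrantDistribution(mode="global", lam=lam, pi_adult=params.pi_adult)


def local_immigrant_distribution(
    params: ModelParams, R: float, site_role: Literal["home", "away"]
) -> ImmigrantDistribution:
    """Immigration law at a focal site on the ring lattice.

    Only defined at monomorphic strategy frequencies (``p`` in {0, 1}):
    at interior frequencies local dispersal builds up spatial genotype
    correlations that a single residency rate cannot summarise.

    Each neighbouring site holds a resident with probability ``R``, whose
    household's disperser survives with probability ``p d_A + (1-p) d_J``
    and moves toward the focal site half of the time, giving a per-neighbour
    arrival probability ``R (p d_A + (1-p) d_J) / 2``.  A home site has two
    inbound slots; at an away site the focal disperser occupies one of them.
    """
    _check_prob("R", R)
    if params.p not in (0.0, 1.0):
        raise ValueError(
            "local immigration is defined only for monomorphic populations "
            f"(p in {{0, 1}}); got p={params.p!r}"
        )
    if site_role not in ("home", "away"):
        raise ValueError(f"site_role must be 'home' or 'away', got {site_role!r}")
    pi_arrive = R * params.disperser_pool / 2.0
    local_class = "adult" if params.p == 1.0 else "juvenile"
    mode = "local_home" if site_role == "home" else "local_away"
    return ImmigrantDistribution(
        mode=mode, pi_arrive=pi_arrive, local_class=local_class
    )


def truncate_support(
    dist: ImmigrantDistribution, tail_tol: float = _TAIL_TOL
) -> list[tuple[ImmigrantCounts, float]]:
    """Enumerate the distribution's support as ``(counts, probability)`` pairs.

    The enumerated mass is at least ``1 - tail_tol``.  Local modes enumerate
    exactly: every composition of up to two (home) or one (away) arrivals
    into adult and juvenile counts, including the off-class compositions
    that carry zero mass at a monomorphic boundary.  ``tail_tol`` must lie
    in (0, 1e-6].
    """
    if not 0.0 < tail_tol <= 1e-6:
        raise ValueError("tail_tol must lie in (0, 1e-6]")
    if dist.mode in ("local_home", "local_away"):
        n_slots = 2 if dist.mode == "local_home" else 1
        return [
            (ImmigrantCounts(a, n - a), dist.pmf(a, n - a))
            for n in range(n_slots + 1)
            for a in range(n + 1)
        ]
    n_A, n_J, pr = dist.support(tail_tol)
    return [
        (ImmigrantCounts(int(a), int(j)), float(q))
        for a, j, q in zip(n_A, n_J, pr)
    ]
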