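"""Strategic-form analysis of the one-shot capacity game.

Each of ``M`` agents simultaneously chooses to attend or stay home. An
attendee earns ``b`` if total attendance ``N`` is at most the capacity
``B``, and ``-b`` if the venue is crowded (``N > B``); staying home pays 0.

The pure-strategy Nash equilibria are exactly the profiles in which
``min(B, M)`` agents attend: no attendee gains by leaving (they would drop
from ``b`` to 0) and no stayer gains by joining (their arrival would tip
attendance over the limit). There is also a unique symmetric mixed
equilibrium; its attendance probability is commonly quoted as ``B/M``,
while the exact finite-population indifference condition

    P[Binomial(M-1, p) <= B-1] = 1/2

(the attend payoff ``b*(2*P[uncrowded] - 1)`` must vanish) yields a value
that differs from ``B/M`` at small ``M``. Both are exposed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .core import SimulationParams

__all__ = [
    "StrategyProfile",
    "EquilibriumReport",
    "payoff",
    "is_pure_nash",
    "enumerate_pure_nash",
    "pure_nash_count",
    "symmetric_mixed_probability",
    "equilibrium_report",
]

#: Largest population for which exhaustive profile enumeration is allowed.
MAX_ENUMERATION_AGENTS = 20


@dataclass(frozen=True)
class StrategyProfile:
    """A pure action assignment: ``actions[i]`` is True iff agent i attends."""

    actions: tuple[bool, ...]

    @property
    def n_attending(self) -> int:
        return sum(self.actions)


@dataclass(frozen=True)
class EquilibriumReport:
    params: SimulationParams
    pure_equilibrium_count: int
    symmetric_mixed_p_paper: float
    symmetric_mixed_p_exact: float

    def to_dict(self) -> dict:
        return {
            "M": self.params.n_agents,
            "B": self.params.capacity,
            "b": self.params.benefit,
            "pure_equilibrium_count": self.pure_equilibrium_count,
            "symmetric_mixed_p_paper": self.symmetric_mixed_p_paper,
            "symmetric_mixed_p_exact": self.symmetric_mixed_p_exact,
        }


def payoff(attends: bool, n_attending: int, params: SimulationParams) -> float:
    """Payoff of a single agent given total attendance ``n_attending``.

    ``n_attending`` counts every attendee, including this agent when
    ``attends`` is True. Crowding is strict: ``N = B`` is still enjoyable.
    """
    if not attends:
        return 0.0
    return params.benefit if n_attending <= params.capacity else -params.benefit


def is_pure_nash(
    profile: StrategyProfile | Sequence[bool], params: SimulationParams
) -> bool:
    """True iff no agent can strictly gain by unilaterally switching.

    A deviation recomputes total attendance with the deviator's action
    flipped: a stayer who deviates to attend faces ``N + 1``.
    """
    actions = profile.actions if isinstance(profile, StrategyProfile) else tuple(profile)
    if len(actions) != params.n_agents:
        raise ValueError(
            f"profile length {len(actions)} != n_agents {params.n_agents}"
        )
    n = sum(actions)
    for attends in set(actions):
        current = payoff(attends, n, params)
        deviated = payoff(not attends, n - 1 if attends else n + 1, params)
        if deviated > current:
            return False
    return True


def enumerate_pure_nash(params: SimulationParams) -> list[StrategyProfile]:
    """Exhaustively enumerate all pure-strategy Nash equilibria.

    Brute force over all ``2^M`` profiles with the unilateral-deviation
    check; guarded to small populations. For ``B <= M`` the result is the
    ``C(M, B)`` profiles with exactly ``B`` attendees.
    """
    m = params.n_agents
    if m > MAX_ENUMERATION_AGENTS:
        raise ValueError(
            f"exhaustive enumeration limited to M <= {MAX_ENUMERATION_AGENTS}, "
            f"got M = {m}"
        )
    out = []
    for actions in itertools.product((False, True), repeat=m):
        profile = StrategyProfile(actions=actions)
        if is_pure_nash(profile, params):
            out.append(profile)
    return out


def pure_nash_count(params: SimulationParams) -> int:
    """Number of pure equilibria, ``C(M, min(B, M))``, closed form.

    Valid for any population size; the characterization is validated
    against :func:`enumerate_pure_nash` for small ``M`` in the test suite.
    """
    return math.comb(params.n_agents, min(params.capacity, params.n_agents))


def symmetric_mixed_probability(
    params: SimulationParams, method: str = "paper"
) -> float:
    """Symmetric mixed-equilibrium attendance probability.

    ``method="paper"`` returns the familiar ``B/M`` (capped at 1).
    ``method="exact"`` solves the finite-population indifference condition
    ``P[Binomial(M-1, p) <= B-1] = 1/2`` by bisection to 1e-10. When
    ``B >= M`` attending can never hurt, so both methods return 1.
    """
    m, b_cap = params.n_agents, params.capacity
    if b_cap < 1:
        raise ValueError("symmetric mixed equilibrium requires capacity >= 1")
    if b_cap >= m:
        return 1.0
    if method == "paper":
        return b_cap / m
    if method != "exact":
        raise ValueError(f"method must be 'paper' or 'exact', got {method!r}")
    if m < 2:
        raise ValueError("method='exact' requires n_agents >= 2")

    # P[Bin(M-1, p) <= B-1] is continuous and strictly decreasing in p on
    # (0, 1), from 1 at p=0 to 0 at p=1, so bisection is valid.
    def excess(p: float) -> float:
        return stats.binom.cdf(b_cap - 1, m - 1, p) - 0.5

    lo, hi = 0.0, 1.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def equilibrium_report(params: SimulationParams) -> EquilibriumReport:
    """Assemble the equilibrium summary for the given parameters."""
    return EquilibriumReport(
        params=params,
        pure_equilibrium_count=pure_nash_count(params),
        symmetric_mixed_p_paper=symmetric_mixed_probability(params, "paper"),
        symmetric_mixed_p_exact=symmetric_mixed_probability(params, "exact"),
    )
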