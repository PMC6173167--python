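"""Equilibrium relatedness between patch-mates.

Two randomly chosen distinct breeders of a patch are identical by
descent if their parental lineages coalesce in the patch's recent
history.  Conditioning on the patch's previous type gamma (backward
chain), both are philopatric with probability h_gamma^2 (vacancies are
independent draws from the same pool); philopatric winners descend from
a given local mother in proportion to her fecundity share.  Siblings
have relatedness one, offspring of distinct local mothers inherit the
mothers' relatedness, and any immigrant ancestry breaks identity.
Inheritance is haploid and asexual with no mutation correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographicState
from .params import EnvironmentProcess, ModelParams

__all__ = ["RelatednessState", "recursion_coefficients", "solve_relatedness"]


@dataclass(frozen=True)
class RelatednessState:
    """Equilibrium pairwise relatedness and its recursion coefficients."""

    r_R: float
    r_P: float
    phi: np.ndarray        # (2,) prob. both members philopatric, by prev type
    U: np.ndarray          # (2, 2) maternity shares [quality, prev type]
    same_mother: np.ndarray  # (2,) prob. two philopatric winners are siblings

    @property
    def r(self) -> np.ndarray:
        return np.array([self.r_R, self.r_P])


def recursion_coefficients(
    demo: DemographicState, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients of the relatedness recursion.

    Returns (phi, U, same_mother): phi[gamma] = h_gamma^2; U[rho, gamma]
    is a single quality-rho mother's share of the philopatric pool times
    the number of such mothers summing to one over qualities; and
    same_mother[gamma] is the probability that two independent
    philopatric winners share a mother, sum_rho (n/2) * share_rho^2 with
    share_rho = f_rho / ((n/2) (f_H + f_L)).
    """
    phi = demo.h ** 2
    half = params.n / 2.0
    F = demo.f[0] + demo.f[1]
    share = demo.f / (half * F)[None, :]     # one mother's share, by quality
    U = half * share                          # class maternity fraction
    same_mother = half * np.sum(share ** 2, axis=0)
    return phi, U, same_mother


def solve_relatedness(
    demo: DemographicState, params: ModelParams, env: EnvironmentProcess
) -> RelatednessState:
    """Solve the two-type relatedness recursion at equilibrium.

    The recursion r'_sigma = sum_gamma p_{gamma|sigma} * phi_gamma *
    (same_mother_gamma + (1 - same_mother_gamma) * r_gamma) is linear in
    (r_R, r_P) and solved directly (no geometric-series shortcut, so the
    correlation extremes tau = +/-1 are handled exactly).
    """
    phi, U, same_mother = recursion_coefficients(demo, params)
    back = env.backward  # back[gamma, sigma] = p_{gamma | sigma}
    # r_sigma = a_sigma + sum_gamma M[sigma, gamma] r_gamma
    a = np.array([
        float(np.sum(back[:, s] * phi * same_mother)) for s in (0, 1)
    ])
    M = np.array([
        [back[g, s] * phi[g] * (1.0 - same_mother[g]) for g in (0, 1)]
        for s in (0, 1)
    ])
    r = np.linalg.solve(np.eye(2) - M, a)
    return RelatednessState(
        r_R=float(r[0]), r_P=float(r[1]), phi=phi, U=U, same_mother=same_mother
    )
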