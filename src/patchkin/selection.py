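"""Neighbour-modulated selection on competitive effort.

The selection gradient on each class trait is the slope of mean fitness
on the breeding value of that class, holding the resident demographic
background (global pools, class frequencies u and reproductive values v)
fixed: only the focal patch's phenotypes, fecundities and local
competition pool deviate.  The same quantity is re-derived as a
Hamilton's-rule sum of a primary fecundity cost, a relatedness-weighted
primary benefit, and a kin-competition cost from locally displaced
offspring; the two routes must agree up to the positive class frequency,
which is the central internal consistency check of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behaviour
from .behaviour import TraitProfile, fecundity_table
from .demography import (
    DemographicState,
    class_index,
    resident_demography,
)
from .params import (
    HIGH,
    LOW,
    EnvironmentProcess,
    ModelParams,
    make_env_process,
)
from .relatedness import RelatednessState, solve_relatedness

__all__ = [
    "ResidentState",
    "SelectionReport",
    "solve_resident",
    "resident_from_fecundity",
    "class_fitness",
    "selection_gradient",
    "hamilton_decomposition",
    "potential_for_helping",
    "mean_fitness",
]

FD_STEP = 1e-6


@dataclass
class ResidentState:
    """Resident equilibrium: environment, demography and relatedness."""

    params: ModelParams
    env: EnvironmentProcess
    z: TraitProfile | None
    f: np.ndarray
    demo: DemographicState
    rel: RelatednessState


def solve_resident(z: TraitProfile, params: ModelParams) -> ResidentState:
    """Resident equilibrium for a monomorphic effort profile."""
    env = make_env_process(params.tau, params.p)
    f = fecundity_table(z, params)
    demo = resident_demography(f, params, env)
    rel = solve_relatedness(demo, params, env)
    return ResidentState(params=params, env=env, z=z, f=f, demo=demo, rel=rel)


def resident_from_fecundity(f: np.ndarray, params: ModelParams) -> ResidentState:
    """Resident equilibrium for fecundities given directly (behaviour held
    fixed), as in cost/benefit-ratio analyses of helping potential."""
    env = make_env_process(params.tau, params.p)
    f = np.asarray(f, dtype=float)
    demo = resident_demography(f, params, env)
    rel = solve_relatedness(demo, params, env)
    return ResidentState(params=params, env=env, z=None, f=f, demo=demo, rel=rel)


def _member_fecundities(
    x_H: np.ndarray, x_L: np.ndarray, patch_type: int, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fecundity of every member of a focal patch with explicit efforts."""
    x_all = np.concatenate([x_H, x_L])
    xbar = float(x_all.mean())
    if xbar <= 0.0:
        raise ValueError("mean effort is zero: resource shares undefined")
    theta = (1.0 - xbar) / xbar
    mu = params.mu[patch_type]
    f_H = mu * (params.q[HIGH, patch_type] + x_H * theta)
    f_L = mu * (params.q[LOW, patch_type] + x_L * theta)
    return f_H, f_L, xbar


def class_fitness(
    x_H: np.ndarray,
    x_L: np.ndarray,
    patch_type: int,
    state: ResidentState,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour-modulated fitness of every member of one focal patch.

    ``x_H``/``x_L`` are the efforts of the n/2 high- and low-quality
    members.  Fitness counts a breeder's recruits weighted by their
    reproductive value and divided by the value of her own class; at the
    resident phenotypes it is one for every class.  Only the focal
    patch's fecundities and local pool respond to the deviant efforts;
    immigration and the v, u background stay resident.
    """
    params, demo = state.params, state.demo
    x_H = np.atleast_1d(np.asarray(x_H, dtype=float))
    x_L = np.atleast_1d(np.asarray(x_L, dtype=float))
    f_H, f_L, _ = _member_fecundities(x_H, x_L, patch_type, params)
    O_local = (1.0 - params.d) * (f_H.sum() + f_L.sum())
    home = (1.0 - params.d) * params.n / (O_local + demo.I) * demo.s[patch_type]
    away = float(demo.V[patch_type] - demo.w_phi[patch_type] * demo.s[patch_type])
    per_offspring = home + away
    W_H = f_H * per_offspring / demo.v[class_index(HIGH, patch_type)]
    W_L = f_L * per_offspring / demo.v[class_index(LOW, patch_type)]
    return W_H, W_L


def mean_fitness(state: ResidentState) -> float:
    """Expected fitness of a random breeder (1 at resident equilibrium)."""
    wbar = 0.0
    for sigma in (0, 1):
        half = state.params.n // 2
        za = state.z.as_array() if state.z is not None else None
        if za is None:
            raise ValueError("mean fitness requires a trait profile")
        x_H = np.full(half, za[HIGH, sigma])
        x_L = np.full(half, za[LOW, sigma])
        W_H, W_L = class_fitness(x_H, x_L, sigma, state)
        u, v = state.demo.u, state.demo.v
        wbar += (
            u[class_index(HIGH, sigma)] * v[class_index(HIGH, sigma)] * W_H[0]
            + u[class_index(LOW, sigma)] * v[class_index(LOW, sigma)] * W_L[0]
        )
    return float(wbar)


def _fitness_derivatives(
    state: ResidentState, sigma: int, alpha: int, step: float = FD_STEP
) -> tuple[float, float, float]:
    """Central finite differences of class fitness in a class-alpha effort.

    Returns (dW_self, dW_same, dW_cross): the response of the actor's
    own fitness, of one same-class patch-mate's fitness, and of one
    other-class patch-mate's fitness to the actor's effort.  dW_same is
    zero-filled for patches with a single member per quality.
    """
    params = state.params
    half = params.n // 2
    if state.z is None:
        raise ValueError("selection analysis requires a trait profile")
    z = state.z.as_array()
    base_H = np.full(half, z[HIGH, sigma])
    base_L = np.full(half, z[LOW, sigma])

    def eval_at(delta: float) -> tuple[float, float, float]:
        x_H, x_L = base_H.copy(), base_L.copy()
        (x_H if alpha == HIGH else x_L)[0] += delta
        W_H, W_L = class_fitness(x_H, x_L, sigma, state)
        own = W_H[0] if alpha == HIGH else W_L[0]
        same = (W_H[1] if alpha == HIGH else W_L[1]) if half > 1 else 0.0
        cross = W_L[0] if alpha == HIGH else W_H[0]
        return own, same, cross

    up = eval_at(step)
    dn = eval_at(-step)
    return tuple((u - d) / (2.0 * step) for u, d in zip(up, dn))


def selection_gradient(
    z: TraitProfile, params: ModelParams, state: ResidentState | None = None
) -> np.ndarray:
    """Selection gradient S[quality, patch type] on the four class traits.

    S is the slope of mean fitness on the class breeding value: the
    actor's own-fitness response plus the relatedness-weighted responses
    of its n - 1 patch-mates (n/2 - 1 of the same class, n/2 of the
    other class).  Classes in the other patch type contribute nothing
    because social interactions are patch-local.
    """
    if state is None:
        state = solve_resident(z, params)
    demo, rel = state.demo, state.rel
    half = params.n // 2
    S = np.zeros((2, 2))
    for sigma in (0, 1):
        r = rel.r[sigma]
        for alpha in (HIGH, LOW):
            other = LOW if alpha == HIGH else HIGH
            d_self, d_same, d_cross = _fitness_derivatives(state, sigma, alpha)
            uv_a = demo.u[class_index(alpha, sigma)] * demo.v[class_index(alpha, sigma)]
            uv_o = demo.u[class_index(other, sigma)] * demo.v[class_index(other, sigma)]
            S[alpha, sigma] = uv_a * d_self + r * (
                (half - 1) * uv_a * d_same + half * uv_o * d_cross
            )
    return S


@dataclass
class SelectionReport:
    """Per-class selection summary at a resident profile."""

    S: np.ndarray                # (2, 2) direct finite-difference gradient
    hamilton_lhs: np.ndarray     # (2, 2) inclusive-fitness route (per actor)
    kappa: np.ndarray            # (2, 2) proportionality S / lhs (class freq.)
    primary_cost: np.ndarray     # (2, 2) own-fecundity term, -C * V
    primary_benefit: np.ndarray  # (2, 2) recipients' term, B * V * r
    kin_competition: np.ndarray  # (2, 2) displacement term
    A: np.ndarray                # (2, 2) potential for helping
    C: np.ndarray                # (2, 2) net fecundity cost of own effort
    B: np.ndarray                # (2, 2) per-recipient fecundity benefit
    wbar: float


class DecompositionError(RuntimeError):
    """Hamilton decomposition is not proportional to the direct gradient."""


def hamilton_decomposition(
    z: TraitProfile, params: ModelParams, state: ResidentState | None = None
) -> SelectionReport:
    """Hamilton's-rule partition of selection on each class trait.

    For an actor of quality alpha in a type-sigma patch, a marginal
    effort increase changes her own fecundity by a (the share gain net
    of her exposure to pool depletion, a = -C) and each patch-mate's by
    b (pure depletion, the per-recipient benefit B, negative here).  The
    inclusive-fitness effect is

        -C*V + B_tot*V*r - (B_tot - C) * (w_phi/n) * D,

    where B_tot sums b over the n-1 recipients, V is offspring
    reproductive value, and the last term prices the displacement of
    local offspring: each extra recruit evicts a uniformly random winner
    of the n home vacancies, destroying philopatric value
    D = v_phi_actor * (1 + (n/2-1) r) + (n/2) r v_phi_other.

    The result equals the direct gradient divided by the class frequency
    u (kappa below); a non-constant or non-positive ratio raises
    :class:`DecompositionError`.
    """
    if state is None:
        state = solve_resident(z, params)
    demo, rel = state.demo, state.rel
    half = params.n // 2
    za = z.as_array()
    S = selection_gradient(z, params, state=state)
    lhs = np.zeros((2, 2))
    cost_t = np.zeros((2, 2))
    benefit_t = np.zeros((2, 2))
    kin_t = np.zeros((2, 2))
    C_out = np.zeros((2, 2))
    B_out = np.zeros((2, 2))
    for sigma in (0, 1):
        r = rel.r[sigma]
        x_patch = (za[HIGH, sigma], za[LOW, sigma])
        V = demo.V[sigma]
        w_phi = demo.w_phi[sigma]
        for alpha in (HIGH, LOW):
            other = LOW if alpha == HIGH else HIGH
            a, b_cross = behaviour.fecundity_gradients(x_patch, alpha, sigma, params)
            xbar = 0.5 * (x_patch[0] + x_patch[1])
            k = params.mu[sigma] / (params.n * xbar * xbar)
            b_same = -za[alpha, sigma] * k
            B_tot = (half - 1) * b_same + half * b_cross
            v_phi_a = demo.v_phi[alpha, sigma]
            v_phi_o = demo.v_phi[other, sigma]
            displaced = v_phi_a * (1.0 + (half - 1) * r) + half * r * v_phi_o
            cost_t[alpha, sigma] = a * V
            benefit_t[alpha, sigma] = B_tot * r * V
            kin_t[alpha, sigma] = -(a + B_tot) * (w_phi / params.n) * displaced
            lhs[alpha, sigma] = (
                cost_t[alpha, sigma] + benefit_t[alpha, sigma] + kin_t[alpha, sigma]
            )
            C_out[alpha, sigma] = -a
            B_out[alpha, sigma] = b_cross
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(np.abs(lhs) > 1e-14, S / lhs, np.nan)
    A = potential_for_helping(z, params, state=state)
    return SelectionReport(
        S=S, hamilton_lhs=lhs, kappa=kappa,
        primary_cost=cost_t, primary_benefit=benefit_t, kin_competition=kin_t,
        A=A, C=C_out, B=B_out, wbar=mean_fitness(state),
    )


def potential_for_helping(
    z: TraitProfile | None,
    params: ModelParams,
    state: ResidentState | None = None,
) -> np.ndarray:
    """Critical cost-benefit ratio A[quality, patch type] for helping.

    A is the value of C/B at which a helping trait (cost C > 0 to the
    actor, benefit B > 0 to the patch partner) is selectively neutral:

        A = (r*V - (w_phi/n) * (v_phi_a + r*v_phi_o))
            / (V - (w_phi/n) * (v_phi_a + r*v_phi_o)).

    Helping evolves for 0 < C/B < A; A < 0 means even free help is
    disfavoured and harming can evolve.  A vanishing denominator marks a
    threshold regime and yields +/-inf.
    """
    if state is None:
        if z is None:
            raise ValueError("either a trait profile or a resident state is required")
        state = solve_resident(z, params)
    demo, rel = state.demo, state.rel
    A = np.zeros((2, 2))
    for sigma in (0, 1):
        r = rel.r[sigma]
        V = demo.V[sigma]
        w_tilde = demo.w_phi[sigma] / params.n
        for alpha in (HIGH, LOW):
            other = LOW if alpha == HIGH else HIGH
            disp = w_tilde * (demo.v_phi[alpha, sigma] + r * demo.v_phi[other, sigma])
            denom = V - disp
            with np.errstate(divide="ignore", invalid="ignore"):
                A[alpha, sigma] = (r * V - disp) / denom
    return A
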