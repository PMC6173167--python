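"""Model extensions: early-life quality acquisition and larger patches.

The main model fixes each pair-patch at one high- and one low-quality
breeder (roles assigned among winners).  Here quality is instead drawn
at birth with probability Q, so patch composition is binomial and pure
(HH, LL) as well as mixed (HL) patches occur; efforts condition on own
quality, the partner's quality and the patch type — eight traits.

Larger patches (n > 2 breeders, half of each quality) need no separate
machinery: the core pipeline is written for general even n, and
``solve_ess_patch_size`` simply runs it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .behaviour import TRAIT_FLOOR
from .ess import damped_ascent
from .params import HIGH, LOW, EnvironmentProcess, ModelParams, make_env_process

__all__ = [
    "EXT_TRAIT_NAMES",
    "composition_probs",
    "EarlyQualityState",
    "solve_resident_early",
    "selection_gradient_early",
    "ExtendedESSResult",
    "solve_ess_early_quality",
    "solve_ess_patch_size",
]

# trait/class index: (own quality rho, partner quality eps, patch type sigma)
# -> (2*rho + eps)*2 + sigma
EXT_TRAIT_NAMES = (
    "z_HH_R", "z_HH_P", "z_HL_R", "z_HL_P",
    "z_LH_R", "z_LH_P", "z_LL_R", "z_LL_P",
)
# patch compositions, as (quality of member 1, quality of member 2)
COMPS = ((HIGH, HIGH), (HIGH, LOW), (LOW, LOW))
COMP_LABELS = ("HH", "HL", "LL")


def _tidx(rho: int, eps: int, sigma: int) -> int:
    return (2 * rho + eps) * 2 + sigma


def composition_probs(Q: float, n: int = 2) -> dict[str, float]:
    """Binomial patch-composition frequencies over the number of
    high-quality members (pairs: HH, HL, LL)."""
    if not 0.0 <= Q <= 1.0:
        raise ValueError(f"Q={Q!r} must be a probability")
    if n != 2:
        raise NotImplementedError("compositions are enumerated for pairs only")
    return {"HH": Q * Q, "HL": 2.0 * Q * (1.0 - Q), "LL": (1.0 - Q) ** 2}


@dataclass
class EarlyQualityState:
    """Resident equilibrium of the eight-class early-quality model."""

    params: ModelParams
    env: EnvironmentProcess
    z: np.ndarray            # (8,) resident efforts, EXT_TRAIT_NAMES order
    f: dict                  # fecundity of each member by (comp, sigma)
    O: np.ndarray            # (3 comps, 2 types) philopatric pools
    I: float
    w: np.ndarray            # (8, 8) class fitness matrix
    u: np.ndarray            # (8,) class frequencies
    v: np.ndarray            # (8,) reproductive values, sum(u*v) = 1
    lam: float
    s: np.ndarray            # (2,) newly-settled breeder value by type
    land: np.ndarray         # (2,) per-offspring dispersal settlement weight
    r: np.ndarray            # (2,) pair relatedness by patch type


def _member_fecundities(
    z: np.ndarray, comp: tuple[int, int], sigma: int, params: ModelParams
) -> tuple[float, float]:
    """Fecundities of the two members of a (composition, type) patch."""
    q1, q2 = comp
    x1 = z[_tidx(q1, q2, sigma)]
    x2 = z[_tidx(q2, q1, sigma)]
    xbar = 0.5 * (x1 + x2)
    theta = (1.0 - xbar) / xbar
    mu = params.mu[sigma]
    f1 = mu * (params.q[q1, sigma] + x1 * theta)
    f2 = mu * (params.q[q2, sigma] + x2 * theta)
    return f1, f2


def solve_resident_early(z: np.ndarray, params: ModelParams) -> EarlyQualityState:
    """Resident equilibrium with binomial composition and 8 classes.

    Classes are (own quality, partner quality, patch type); stationary
    class frequencies factorise as Bernoulli(Q) x Bernoulli(Q) x patch
    frequency because winner qualities are drawn independently of
    parentage each generation.
    """
    env = make_env_process(params.tau, params.p)
    Q = params.Q
    pq = np.array([Q, 1.0 - Q])                       # P(quality)
    pcomp = np.array([Q * Q, 2 * Q * (1 - Q), (1 - Q) ** 2])
    pi = env.stationary

    f: dict = {}
    O = np.zeros((3, 2))
    for ci, comp in enumerate(COMPS):
        for sigma in (0, 1):
            f1, f2 = _member_fecundities(z, comp, sigma, params)
            f[(ci, sigma)] = (f1, f2)
            O[ci, sigma] = (1.0 - params.d) * (f1 + f2)
    F_mean = float(np.sum(pcomp[:, None] * (O / (1.0 - params.d)) * pi[None, :]))
    I = params.d * (1.0 - params.c) * F_mean
    # per-offspring settlement weight for dispersers landing on a random
    # patch of type sigma' (composition-averaged lottery)
    land = params.d * (1.0 - params.c) * pi * np.array([
        float(np.sum(pcomp * 2.0 / (O[:, sp] + I))) for sp in (0, 1)
    ])

    # 8x8 class fitness matrix
    w = np.zeros((8, 8))
    for ci, comp in enumerate(COMPS):
        for sigma in (0, 1):
            f1, f2 = f[(ci, sigma)]
            stay = (1.0 - params.d) * 2.0 / (O[ci, sigma] + I)
            settle = land.copy()
            settle[sigma] += stay
            child_type = settle @ env.forward
            for member, (own, other) in enumerate((comp, comp[::-1])):
                fm = (f1, f2)[member]
                row = _tidx(own, other, sigma)
                for eta in (0, 1):
                    for epsp in (0, 1):
                        for gamma in (0, 1):
                            col = _tidx(eta, epsp, gamma)
                            w[row, col] += (
                                pcomp_weight(ci, comp)
                                * fm * child_type[gamma] * pq[eta] * pq[epsp]
                            )
    # rows must not double-count: each row was visited once per member
    # of the composition that realises the class; mixed compositions
    # realise (H,L) and (L,H) rows once each, pure ones twice the same
    # row -- handled by pcomp_weight below.

    vals, vl, vr = scipy.linalg.eig(w, left=True, right=True)
    i = int(np.argmax(vals.real))
    lam = float(vals[i].real)
    u = np.abs(vl[:, i].real)
    u /= u.sum()
    v = np.abs(vr[:, i].real)
    v /= float(u @ v)

    # newly settled breeder value by pre-transition patch type
    v8 = v.reshape(4, 2)  # [(rho,eps), sigma]
    pq_pair = np.array([pq[r] * pq[e] for r, e in
                        ((0, 0), (0, 1), (1, 0), (1, 1))])
    s = env.forward @ (v8.T @ pq_pair)

    # pair relatedness by current patch type: previous composition is
    # independent of everything else, so it enters with its prior
    h2 = (O / (O + I)) ** 2                          # (3, 2) both philopatric
    sm = np.zeros((3, 2))
    for ci in range(3):
        for g in (0, 1):
            f1, f2 = f[(ci, g)]
            tot = f1 + f2
            sm[ci, g] = (f1 * f1 + f2 * f2) / (tot * tot)
    a = np.zeros(2)
    M = np.zeros((2, 2))
    for sigma in (0, 1):
        for g in (0, 1):
            pg = env.backward[g, sigma]
            a[sigma] += pg * float(np.sum(pcomp * h2[:, g] * sm[:, g]))
            M[sigma, g] += pg * float(np.sum(pcomp * h2[:, g] * (1.0 - sm[:, g])))
    r = np.linalg.solve(np.eye(2) - M, a)

    return EarlyQualityState(
        params=params, env=env, z=np.asarray(z, float), f=f, O=O, I=float(I),
        w=w, u=u, v=v, lam=lam, s=s, land=land, r=r,
    )


def pcomp_weight(ci: int, comp: tuple[int, int]) -> float:
    """Weight of one member-perspective within its class row.

    A class (rho, eps, sigma) is realised by exactly one composition, so
    each row receives contributions from a single (ci, member) pair for
    mixed compositions and from two identical member-perspectives for
    pure ones; the latter must be averaged, not summed.
    """
    return 0.5 if comp[0] == comp[1] else 1.0


def _focal_fitness_early(
    x1: float, x2: float, comp: tuple[int, int], sigma: int,
    state: EarlyQualityState,
) -> tuple[float, float]:
    """Fitness of both members of a deviant focal patch (resident
    background): member 1 has quality comp[0] and effort x1."""
    params = state.params
    q1, q2 = comp
    xbar = 0.5 * (x1 + x2)
    theta = (1.0 - xbar) / xbar
    mu = params.mu[sigma]
    f1 = mu * (params.q[q1, sigma] + x1 * theta)
    f2 = mu * (params.q[q2, sigma] + x2 * theta)
    O_loc = (1.0 - params.d) * (f1 + f2)
    per_off = (
        (1.0 - params.d) * 2.0 / (O_loc + state.I) * state.s[sigma]
        + float(state.land @ state.s)
    )
    W1 = f1 * per_off / state.v[_tidx(q1, q2, sigma)]
    W2 = f2 * per_off / state.v[_tidx(q2, q1, sigma)]
    return W1, W2


def selection_gradient_early(
    z: np.ndarray, params: ModelParams, state: EarlyQualityState | None = None,
    step: float = 1e-6,
) -> np.ndarray:
    """Selection gradient on the eight partner-conditioned traits.

    For mixed-patch traits the actor's deviation moves her own fitness
    plus, weighted by pair relatedness, her partner's (who expresses the
    mirrored trait).  For pure-patch traits actor and partner express
    the same trait, so both channels load on it at once.
    """
    if state is None:
        state = solve_resident_early(z, params)
    S = np.zeros(8)
    for sigma in (0, 1):
        r = state.r[sigma]
        for rho in (0, 1):
            for eps in (0, 1):
                t = _tidx(rho, eps, sigma)
                comp = (rho, eps)
                x1_0 = z[_tidx(rho, eps, sigma)]
                x2_0 = z[_tidx(eps, rho, sigma)]

                def dW(which: int) -> tuple[float, float]:
                    # derivative of (W1, W2) in member-`which`'s effort
                    outs = []
                    for delta in (step, -step):
                        x1 = x1_0 + (delta if which == 1 else 0.0)
                        x2 = x2_0 + (delta if which == 2 else 0.0)
                        outs.append(
                            _focal_fitness_early(x1, x2, comp, sigma, state)
                        )
                    return (
                        (outs[0][0] - outs[1][0]) / (2 * step),
                        (outs[0][1] - outs[1][1]) / (2 * step),
                    )

                uv_own = state.u[t] * state.v[t]
                t_partner = _tidx(eps, rho, sigma)
                uv_par = state.u[t_partner] * state.v[t_partner]
                dW1_d1, dW2_d1 = dW(1)
                S[t] = uv_own * dW1_d1 + r * uv_par * dW2_d1
    return S


@dataclass
class ExtendedESSResult:
    """Singular strategy of the eight-trait early-quality model."""

    z_star: np.ndarray
    gradient: np.ndarray
    gradient_norm: float
    iterations: int
    converged: bool
    trait_names: tuple[str, ...] = EXT_TRAIT_NAMES


def solve_ess_early_quality(
    params: ModelParams,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> ExtendedESSResult:
    """Joint singular strategy of the eight partner-conditioned efforts."""
    z0 = np.full(8, 0.5) if init is None else np.asarray(init, float)

    def grad(z: np.ndarray) -> np.ndarray:
        return selection_gradient_early(np.clip(z, TRAIT_FLOOR, 1.0), params)

    z, S, norm, it, converged, _, _ = damped_ascent(
        grad, z0, tol=tol, max_iter=max_iter
    )
    return ExtendedESSResult(
        z_star=z, gradient=S, gradient_norm=norm,
        iterations=it, converged=converged,
    )


def early_metrics(state: EarlyQualityState) -> dict[str, float]:
    """Quality-mean fecundities, productivities and inequality coefficients.

    Within-group inequality uses the mean fecundity of a quality class
    over partner compositions (1 - fbar_L / fbar_H per patch type);
    productivity averages patch output over the binomial compositions.
    """
    Q = state.params.Q
    pq = {HIGH: Q, LOW: 1.0 - Q}
    pcomp = np.array([Q * Q, 2 * Q * (1 - Q), (1 - Q) ** 2])
    out: dict[str, float] = {}
    for sigma, lab in ((0, "R"), (1, "P")):
        fbar = {HIGH: 0.0, LOW: 0.0}
        for rho in (HIGH, LOW):
            for eps in (HIGH, LOW):
                f_own, _ = _member_fecundities(state.z, (rho, eps), sigma,
                                               state.params)
                fbar[rho] += pq[eps] * f_own
        F = float(np.sum(pcomp * np.array(
            [sum(state.f[(ci, sigma)]) for ci in range(3)]
        )))
        out[f"fbar_H{lab}"] = fbar[HIGH]
        out[f"fbar_L{lab}"] = fbar[LOW]
        out[f"F_{lab}"] = F
        out[f"G_omega_{lab}"] = 1.0 - fbar[LOW] / fbar[HIGH]
    out["G_beta"] = 1.0 - out["F_P"] / out["F_R"]
    return out


def solve_ess_patch_size(params: ModelParams, n: int, **kwargs):
    """Singular strategy for patches of n breeders (half each quality).

    The core pipeline handles general even n; this simply runs it."""
    from .ess import solve_ess

    return solve_ess(params.with_(n=int(n)), **kwargs)
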