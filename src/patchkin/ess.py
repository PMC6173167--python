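"""Locating convergence-stable competitive-effort equilibria.

The four (quality x patch type) conditional traits evolve up their
selection gradients; a singular profile z* has zero gradient on every
interior trait.  It is located by damped fixed-point iteration on the
gradient map with the full resident state (fecundities, pools, fitness
matrix, class frequencies, reproductive values, relatedness) recomputed
each step, and its convergence stability is judged from the Jacobian of
the gradient with respect to the resident traits: all eigenvalue real
parts negative means nearby residents evolve back to z*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import TRAIT_FLOOR, TraitProfile
from .metrics import baseline_inequality, between_group_inequality, within_group_inequality
from .params import HIGH, LOW, ModelParams
from .selection import potential_for_helping, selection_gradient, solve_resident

__all__ = ["ESSResult", "solve_ess", "convergence_stability", "sweep_tau", "SWEEP_COLUMNS"]

TRAIT_NAMES = ("z_HR", "z_LR", "z_HP", "z_LP")


@dataclass
class ESSResult:
    """Outcome of a singular-strategy search."""

    z_star: TraitProfile
    gradient: np.ndarray          # (2, 2) gradient at z_star
    gradient_norm: float
    iterations: int
    converged: bool
    boundary_classes: tuple[str, ...] = ()
    jacobian: np.ndarray | None = None
    stable: bool | None = None
    trajectory_tail: list = field(default_factory=list)


def _flat(z: np.ndarray) -> np.ndarray:
    """(2, 2) quality-by-type array -> (z_HR, z_LR, z_HP, z_LP)."""
    return np.array([z[0, 0], z[1, 0], z[0, 1], z[1, 1]])


def damped_ascent(
    grad_fn,
    z0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    eta_max: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray, list]:
    """Damped fixed-point iteration z <- clip(z + eta * S(z)).

    The step size is halved on an overshoot (gradient norm increase)
    and grown back geometrically otherwise.  Convergence requires the
    gradient of every interior trait to vanish to ``tol``; traits
    pinned at a domain edge with an outward gradient are masked out.
    Returns (z, S, norm, iterations, converged, interior_mask, tail).
    """
    z = np.asarray(z0, dtype=float).copy()
    eta = eta_max
    S = grad_fn(z)
    tail: list = []

    def interior_mask(z, S):
        out = (z >= 1.0 - 1e-12) & (S > 0)
        out |= (z <= TRAIT_FLOOR + 1e-12) & (S < 0)
        return ~out

    for it in range(1, max_iter + 1):
        interior = interior_mask(z, S)
        norm = float(np.abs(np.where(interior, S, 0.0)).max())
        if norm < tol:
            return z, S, norm, it, True, interior, tail
        z_new = np.clip(z + eta * S, TRAIT_FLOOR, 1.0)
        S_new = grad_fn(z_new)
        norm_new = float(np.abs(np.where(interior, S_new, 0.0)).max())
        if norm_new > norm and eta > 1e-6:
            eta *= 0.5  # overshoot: retry from the same point, smaller step
            continue
        eta = min(eta * 1.3, eta_max)
        z, S = z_new, S_new
        tail.append((it, z.ravel().tolist(), norm_new))
        del tail[:-20]
    interior = interior_mask(z, S)
    norm = float(np.abs(np.where(interior, S, 0.0)).max())
    return z, S, norm, max_iter, False, interior, tail


def solve_ess(
    params: ModelParams,
    init: TraitProfile | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    eta_max: float = 0.5,
) -> ESSResult:
    """Find the singular effort profile by damped gradient ascent.

    The full resident state (fecundities, pools, fitness matrix, class
    frequencies, reproductive values, relatedness) is recomputed at
    every step.  Deterministic given the initial condition (default:
    all traits 0.5).
    """
    z0 = (init or TraitProfile.uniform(0.5)).as_array()

    def grad(z: np.ndarray) -> np.ndarray:
        return selection_gradient(TraitProfile.from_array(z), params)

    z, S, norm, it, converged, interior, tail = damped_ascent(
        grad, z0, tol=tol, max_iter=max_iter, eta_max=eta_max
    )
    pinned = tuple(
        nm for nm, (a, s) in zip(TRAIT_NAMES, [(0, 0), (1, 0), (0, 1), (1, 1)])
        if not interior[a, s]
    )
    return ESSResult(
        z_star=TraitProfile.from_array(z), gradient=S, gradient_norm=norm,
        iterations=it, converged=converged, boundary_classes=pinned,
        trajectory_tail=tail if not converged else [],
    )


def convergence_stability(
    z_star: TraitProfile,
    params: ModelParams,
    step: float = 1e-5,
    boundary_classes: tuple[str, ...] = (),
) -> tuple[np.ndarray, bool]:
    """Jacobian dS/dz of the gradient map at z* and the stability verdict.

    The derivative is with respect to *resident* trait values (central
    differences): a perturbed resident shifts the whole demographic and
    genetic background, unlike the focal deviations inside S itself.
    Stability requires every eigenvalue of the interior block to have
    negative real part.  Boundary-pinned classes are excluded.
    """
    interior = [i for i, nm in enumerate(TRAIT_NAMES) if nm not in boundary_classes]
    z0 = _flat(z_star.as_array())
    m = len(interior)
    jac = np.full((m, m), np.nan)
    for col, j in enumerate(interior):
        zp, zm = z0.copy(), z0.copy()
        zp[j] = min(zp[j] + step, 1.0)
        zm[j] = max(zm[j] - step, TRAIT_FLOOR)
        h = zp[j] - zm[j]
        Sp = _flat(selection_gradient(_profile(zp), params))
        Sm = _flat(selection_gradient(_profile(zm), params))
        jac[:, col] = (Sp[interior] - Sm[interior]) / h
    eig = np.linalg.eigvals(jac)
    stable = bool(np.all(eig.real < 0.0))
    return jac, stable


def _profile(flat: np.ndarray) -> TraitProfile:
    return TraitProfile(z_HR=flat[0], z_LR=flat[1], z_HP=flat[2], z_LP=flat[3])


SWEEP_COLUMNS = [
    "tau", "z_HR", "z_LR", "z_HP", "z_LP",
    "f_HR", "f_LR", "f_HP", "f_LP", "r_R", "r_P",
    "A_HR", "A_LR", "A_HP", "A_LP",
    "G_omega_R", "G_omega_P", "G_beta",
    "F_R", "F_P", "F_rel_R", "F_rel_P",
    "stable", "iterations",
]


def sweep_tau(
    params: ModelParams,
    tau_grid,
    check_stability: bool = True,
    warm_start: bool = True,
    init: TraitProfile | None = None,
) -> pd.DataFrame:
    """Solve the ESS across a temporal-correlation grid.

    Returns one row per tau with the evolved efforts, fecundities,
    relatedness, helping potentials, inequality coefficients and
    productivities (relative productivity is against the frozen
    environment tau = 1).  Each solve warm-starts from the previous
    grid point's solution; failures are recorded per row and the sweep
    continues.
    """
    tau_grid = list(tau_grid)
    rows = []
    # reference productivity at tau = 1 for F_rel (the frozen-environment
    # solve approaches its fixed point slowly; give it extra iterations)
    ref = solve_ess(params.with_(tau=1.0), init=init, max_iter=30_000)
    ref_state = solve_resident(ref.z_star, params.with_(tau=1.0))
    F0 = ref_state.f[0] + ref_state.f[1]
    current_init = init
    for tau in tau_grid:
        p_tau = params.with_(tau=float(tau))
        try:
            res = solve_ess(p_tau, init=current_init)
            if warm_start:
                current_init = res.z_star
            state = solve_resident(res.z_star, p_tau)
            f = state.f
            F = f[0] + f[1]
            A = potential_for_helping(res.z_star, p_tau, state=state)
            stable = None
            if check_stability:
                _, stable = convergence_stability(
                    res.z_star, p_tau, boundary_classes=res.boundary_classes
                )
            row = {
                "tau": float(tau),
                "z_HR": res.z_star.z_HR, "z_LR": res.z_star.z_LR,
                "z_HP": res.z_star.z_HP, "z_LP": res.z_star.z_LP,
                "f_HR": f[HIGH, 0], "f_LR": f[LOW, 0],
                "f_HP": f[HIGH, 1], "f_LP": f[LOW, 1],
                "r_R": state.rel.r_R, "r_P": state.rel.r_P,
                "A_HR": A[HIGH, 0], "A_LR": A[LOW, 0],
                "A_HP": A[HIGH, 1], "A_LP": A[LOW, 1],
                "G_omega_R": within_group_inequality(f[HIGH, 0], f[LOW, 0]),
                "G_omega_P": within_group_inequality(f[HIGH, 1], f[LOW, 1]),
                "G_beta": between_group_inequality(F[0], F[1]),
                "F_R": F[0], "F_P": F[1],
                "F_rel_R": F[0] / F0[0], "F_rel_P": F[1] / F0[1],
                "stable": stable, "iterations": res.iterations,
            }
            if not res.converged:
                row["error"] = "no convergence"
        except Exception as exc:  # pragma: no cover - per-row robustness
            row = {"tau": float(tau), "error": str(exc)}
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in SWEEP_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]
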