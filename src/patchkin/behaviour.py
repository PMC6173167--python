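"""Competitive effort and fecundity.

Each breeder expresses a competitive effort x in (0, 1] conditioned on
its own quality (H/L) and the current patch type (R/P).  Effort buys a
larger share of the patch's common resource pool but depletes the pool
itself: with patch mean effort xbar, a breeder of baseline quality q in
a patch with resource level mu has fecundity

    f = mu * (q + (x / xbar) * (1 - xbar))

i.e. a personal (share) component Psi = x and a group (public-good)
component Theta = (1 - xbar) / xbar, entering multiplicatively on top of
the additive baseline.  Effort x = 1 by every member is the "fully
selfish" corner where the public good is exhausted and f = mu * q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import HIGH, LOW, ModelParams

__all__ = [
    "TRAIT_FLOOR",
    "TraitProfile",
    "fecundity",
    "fecundity_table",
    "group_components",
    "marginal_terms",
    "fecundity_gradients",
]

#: Lower bound on competitive effort; keeps shares x/xbar well defined.
TRAIT_FLOOR = 1e-6


def _check_effort(x: float, name: str = "effort") -> None:
    if not TRAIT_FLOOR <= x <= 1.0:
        raise ValueError(f"{name}={x!r} outside [{TRAIT_FLOOR}, 1]")


@dataclass(frozen=True)
class TraitProfile:
    """Resident competitive efforts by quality and patch type."""

    z_HR: float
    z_LR: float
    z_HP: float
    z_LP: float

    def __post_init__(self) -> None:
        for nm in ("z_HR", "z_LR", "z_HP", "z_LP"):
            _check_effort(getattr(self, nm), nm)

    @classmethod
    def from_array(cls, z: np.ndarray) -> "TraitProfile":
        """Build from shape (2 qualities, 2 patch types) array."""
        z = np.asarray(z, dtype=float)
        return cls(z_HR=z[0, 0], z_LR=z[1, 0], z_HP=z[0, 1], z_LP=z[1, 1])

    def as_array(self) -> np.ndarray:
        """Efforts as array with shape (quality, patch type)."""
        return np.array([[self.z_HR, self.z_HP], [self.z_LR, self.z_LP]])

    @classmethod
    def uniform(cls, z: float) -> "TraitProfile":
        return cls(z, z, z, z)


def group_components(x_patch) -> tuple[float, float]:
    """Mean effort xbar and group component Theta for one patch.

    ``x_patch`` is the pair (x_H, x_L) of per-quality efforts; half the
    patch members express each one, so xbar = (x_H + x_L) / 2 for any
    patch size.
    """
    x_h, x_l = x_patch
    xbar = 0.5 * (x_h + x_l)
    if xbar <= 0.0:
        raise ValueError("mean effort is zero: resource shares undefined")
    return xbar, (1.0 - xbar) / xbar


def fecundity(x_patch, quality: int, patch_type: int, params: ModelParams) -> float:
    """Expected offspring number of one breeder, f = mu*(q + Psi*Theta).

    Parameters
    ----------
    x_patch : (x_H, x_L)
        Per-quality competitive efforts in the breeder's patch.
    quality, patch_type : int
        Breeder quality (0=H, 1=L) and patch type (0=R, 1=P).
    """
    xbar, theta = group_components(x_patch)
    x_own = x_patch[quality]
    mu = params.mu[patch_type]
    q = params.q[quality, patch_type]
    return mu * (q + x_own * theta)


def fecundity_table(z: TraitProfile, params: ModelParams) -> np.ndarray:
    """Resident fecundities f[quality, patch_type] for a monomorphic population."""
    za = z.as_array()
    f = np.empty((2, 2))
    for sigma in (0, 1):
        x_patch = (za[HIGH, sigma], za[LOW, sigma])
        for rho in (HIGH, LOW):
            f[rho, sigma] = fecundity(x_patch, rho, sigma, params)
    return f


def marginal_terms(
    x_patch, actor_quality: int, patch_type: int, params: ModelParams
) -> tuple[float, float]:
    """Marginal fecundity cost C and benefit B of the actor's effort.

    C is the share channel: raising own effort raises the actor's share
    of the pool, C = -mu * (dPsi/dx) * Theta = -mu * Theta (negative
    whenever the pool is not exhausted, i.e. a raised effort *gains*
    fecundity through this channel).  B is the public-good channel felt
    by the patch partner: B = mu * (dTheta/dx_actor) * Psi_recipient,
    always <= 0 since extra effort depletes the common pool.  Both are
    in offspring units (the resource level mu is included).
    """
    xbar, theta = group_components(x_patch)
    mu = params.mu[patch_type]
    recipient = LOW if actor_quality == HIGH else HIGH
    dtheta_dx = -1.0 / (params.n * xbar * xbar)
    cost = -mu * theta
    benefit = mu * dtheta_dx * x_patch[recipient]
    return cost, benefit


def fecundity_gradients(
    x_patch, actor_quality: int, patch_type: int, params: ModelParams
) -> tuple[float, float]:
    """Total derivatives of own and partner fecundity in the actor's effort.

    Returns (a, b) with a = d f_actor / d x_actor (share gain minus the
    actor's exposure to pool depletion) and b = d f_partner / d x_actor
    (pure pool depletion).  These are the exact marginals of the
    fecundity function; the Hamilton's-rule decomposition consumes them.
    """
    xbar, theta = group_components(x_patch)
    mu = params.mu[patch_type]
    recipient = LOW if actor_quality == HIGH else HIGH
    dtheta_dx = -1.0 / (params.n * xbar * xbar)
    a = mu * (theta + x_patch[actor_quality] * dtheta_dx)
    b = mu * x_patch[recipient] * dtheta_dx
    return a, b
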