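"""Inequality and productivity measures.

Within-group inequality compares the two quality classes of a patch,
between-group inequality compares the productivities of the two patch
types; both are one minus a low-to-high ratio, so 0 is egalitarian and
1 is complete monopolisation.  Baselines evaluate the same coefficients
at the fully selfish corner (every effort equal to one), where social
interactions contribute nothing and only baseline qualities remain.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "within_group_inequality",
    "between_group_inequality",
    "baseline_inequality",
    "productivity",
]


def within_group_inequality(f_H: float, f_L: float) -> float:
    """G_omega = 1 - f_L / f_H for one patch type."""
    if f_H <= 0.0:
        raise ValueError(f"high-quality fecundity must be positive, got {f_H!r}")
    if f_L < 0.0:
        raise ValueError(f"low-quality fecundity must be non-negative, got {f_L!r}")
    if f_L > f_H * (1.0 + 1e-12):
        raise ValueError(
            f"f_L={f_L!r} exceeds f_H={f_H!r}: quality labels swapped upstream"
        )
    return 1.0 - f_L / f_H


def between_group_inequality(F_R: float, F_P: float) -> float:
    """G_beta = 1 - F_P / F_R across patch types."""
    if F_R <= 0.0:
        raise ValueError(f"rich-patch productivity must be positive, got {F_R!r}")
    return 1.0 - F_P / F_R


def baseline_inequality(params: ModelParams) -> tuple[float, float, float]:
    """Initial (fully selfish) inequality (G0_omega_R, G0_omega_P, G0_beta).

    With every effort at one, fecundity reduces to mu * q, so the
    within-type baseline is 1 - q_L/q_H and the between-type baseline is
    1 - mu_P (q_HP + q_LP) / (mu_R (q_HR + q_LR)).
    """
    if params.q_HR <= 0.0 or params.q_HP <= 0.0:
        raise ValueError("baseline inequality needs positive high-quality q")
    g0_r = 1.0 - params.q_LR / params.q_HR
    g0_p = 1.0 - params.q_LP / params.q_HP
    denom = params.mu_R * (params.q_HR + params.q_LR)
    if denom <= 0.0:
        raise ValueError("rich-patch baseline productivity is zero")
    g0_b = 1.0 - params.mu_P * (params.q_HP + params.q_LP) / denom
    return g0_r, g0_p, g0_b


def productivity(f: np.ndarray, f_reference: np.ndarray | None = None):
    """Patch productivities F_sigma = f_H + f_L and, if a frozen-environment
    reference table is given, relative productivities F(tau)/F(tau=1)."""
    f = np.asarray(f, dtype=float)
    F = f[0] + f[1]
    if f_reference is None:
        return F
    f_ref = np.asarray(f_reference, dtype=float)
    F0 = f_ref[0] + f_ref[1]
    if np.any(F0 <= 0.0):
        raise ValueError("reference productivities must be positive")
    return F, F / F0
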