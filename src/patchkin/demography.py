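"""Demography of the infinite-island model with two patch types.

Breeders fall into four classes (quality x patch type, ordered
HR, LR, HP, LP).  Each generation every breeder produces a large number
of offspring; a fraction 1-d stay home, the rest disperse and survive
with probability 1-c, landing uniformly over the (infinitely many)
patches.  The n breeding vacancies of a patch are then filled by
independent weighted draws from the local pool of stayers plus the
immigrant pool, winners are assigned qualities (half high, half low in
expectation), and finally the patch may switch type.

The class fitness matrix ``w[parent, child]`` counts the expected
recruits a parent leaves in each child class.  Its leading eigenvalue is
one for any monomorphic resident (patch number and patch size are
constant); the left eigenvector gives stable class frequencies u and the
right eigenvector gives breeder reproductive values v, normalised so
that sum(u * v) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .params import EnvironmentProcess, ModelParams

__all__ = [
    "DemographicState",
    "DemographicCollapse",
    "offspring_pools",
    "settlement",
    "build_fitness_matrix",
    "eigen_quantities",
    "value_components",
    "resident_demography",
    "class_index",
]


class DemographicCollapse(RuntimeError):
    """No offspring compete for breeding vacancies (O + I = 0)."""


def class_index(quality: int, patch_type: int) -> int:
    """Index into 4-vectors ordered HR, LR, HP, LP."""
    return 2 * patch_type + quality


@dataclass
class DemographicState:
    """Resident demographic equilibrium for a given fecundity table.

    Attributes
    ----------
    f : (2, 2) array
        Fecundities by (quality, patch type).
    w : (4, 4) array
        Class fitness matrix, ``w[parent, child]``.
    u, v : (4,) arrays
        Stable class frequencies (sum 1) and breeder reproductive
        values (sum(u*v) = 1), class order HR, LR, HP, LP.
    lam : float
        Leading eigenvalue of w (1 at a resident equilibrium).
    O : (2,) array
        Philopatric offspring pool per patch of each type.
    I : float
        Immigrant offspring pool arriving at any one patch.
    h : (2,) array
        Probability a vacancy winner is philopatric, O / (O + I).
    w_phi : (2,) array
        Per-native-offspring probability of staying home and winning one
        of the n local vacancies.
    s : (2,) array
        Expected reproductive value of a newly settled breeder in a
        currently-type-sigma patch (patch transition still to come).
    V : (2,) array
        Offspring reproductive value by natal patch type (independent
        of the mother's quality: offspring are identical at birth).
    v_phi : (2, 2) array
        Philopatric component of breeder reproductive value by
        (quality, patch type): value realised through offspring that
        stay and win a home vacancy.
    """

    f: np.ndarray
    w: np.ndarray
    u: np.ndarray
    v: np.ndarray
    lam: float
    O: np.ndarray
    I: float
    h: np.ndarray
    w_phi: np.ndarray
    s: np.ndarray
    V: np.ndarray
    v_phi: np.ndarray


def offspring_pools(
    f: np.ndarray, params: ModelParams, env: EnvironmentProcess
) -> tuple[np.ndarray, float]:
    """Philopatric pools O_sigma and the immigrant pool I per patch.

    A patch holds n/2 breeders of each quality, so its total fecundity
    is (n/2) * (f_H + f_L).  Migrants from everywhere mix and land
    uniformly, hence every patch receives the same immigrant pool.
    """
    half = params.n / 2.0
    F = half * (f[0] + f[1])  # per-patch total fecundity by type
    O = (1.0 - params.d) * F
    I = params.d * (1.0 - params.c) * float(env.stationary @ F)
    if np.all(O + I <= 0.0):
        raise DemographicCollapse(
            "no offspring reach competition (d and c leave an empty pool)"
        )
    return O, I


def settlement(
    f: np.ndarray, params: ModelParams, env: EnvironmentProcess
) -> tuple[np.ndarray, np.ndarray]:
    """Philopatry share h_sigma and native recruitment probability w_phi.

    h_sigma is the probability that the winner of any one vacancy is
    locally born; w_phi_sigma is the probability that one particular
    native offspring stays home *and* wins one of the n vacancies
    (infinite-fecundity lottery, so slots are independent draws).
    """
    O, I = offspring_pools(f, params, env)
    h = O / (O + I)
    w_phi = (1.0 - params.d) * params.n / (O + I)
    return h, w_phi


def build_fitness_matrix(
    f: np.ndarray, params: ModelParams, env: EnvironmentProcess
) -> np.ndarray:
    """Expected recruits per parent class into each child class.

    A parent of quality rho in a type-pi patch has f[rho, pi] offspring;
    each stays with probability 1-d and then wins one of the n home
    vacancies with probability n/(O_pi + I), or disperses, survives with
    probability 1-c, lands on a type-sigma' patch with probability
    pi_sigma' and wins there with probability n/(O_sigma' + I).  Winners
    are assigned high or low quality with probability 1/2 each, and the
    patch then transitions type (so the child's patch type is drawn from
    the forward chain of the patch it settled in).
    """
    O, I = offspring_pools(f, params, env)
    pi = env.stationary
    n = params.n
    d, c = params.d, params.c
    # per-offspring settlement probability by current patch type
    stay = (1.0 - d) * n / (O + I)                    # settle at home, type pi
    land = d * (1.0 - c) * pi * n / (O + I)           # settle on random type
    w = np.zeros((4, 4))
    for parent_type in (0, 1):
        # distribution over the *pre-transition* type of the patch the
        # offspring settles in
        settle = np.zeros(2)
        settle[parent_type] += stay[parent_type]
        settle += land
        # apply the patch-type transition, then the 1/2 quality draw
        child_type_prob = settle @ env.forward
        for parent_q in (0, 1):
            row = class_index(parent_q, parent_type)
            for child_type in (0, 1):
                for child_q in (0, 1):
                    col = class_index(child_q, child_type)
                    w[row, col] = (
                        f[parent_q, parent_type]
                        * child_type_prob[child_type]
                        * 0.5
                    )
    return w


def eigen_quantities(
    w: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stable class frequencies u, reproductive values v, leading eigenvalue.

    Uses a dense eigendecomposition (the matrix may be reducible at the
    correlation extremes, where power iteration would be unreliable).
    If the leading eigenvalue is shared by several disconnected class
    blocks (e.g. d = 0 with a frozen environment), each block is solved
    separately and blocks are weighted by ``class_weights`` (default
    uniform); within each block v is scaled so block-wise sum(u*v)
    matches the block's share, making the global normalisation
    sum(u*v) = 1 hold.
    """
    n_comp, labels = connected_components(w > 0, directed=True, connection="strong")
    if class_weights is None:
        class_weights = np.full(w.shape[0], 1.0 / w.shape[0])

    def leading(mat: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        vals, vl, vr = scipy.linalg.eig(mat, left=True, right=True)
        i = int(np.argmax(vals.real))
        lam = float(vals[i].real)
        left = np.abs(vl[:, i].real)
        right = np.abs(vr[:, i].real)
        return lam, left, right

    if n_comp == 1:
        lam, left, right = leading(w)
        u = left / left.sum()
        v = right / float(u @ right)
        return u, v, lam

    # reducible: solve per strongly connected component
    lams, lefts, rights = {}, {}, {}
    for k in range(n_comp):
        idx = np.flatnonzero(labels == k)
        lam_k, l_k, r_k = leading(w[np.ix_(idx, idx)])
        lams[k], lefts[k], rights[k] = lam_k, l_k, r_k
    lam = max(lams.values())
    winners = [k for k in range(n_comp) if lams[k] > lam - 1e-9]
    u = np.zeros(w.shape[0])
    v = np.zeros(w.shape[0])
    for k in winners:
        idx = np.flatnonzero(labels == k)
        share = class_weights[idx].sum()
        u_k = lefts[k] / lefts[k].sum() * share
        u[idx] = u_k
        v[idx] = rights[k] / float(u_k @ rights[k]) * share
    u /= u.sum()
    v /= float(u @ v)
    return u, v, float(lam)


def value_components(
    f: np.ndarray,
    v: np.ndarray,
    params: ModelParams,
    env: EnvironmentProcess,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Settled-breeder values s, offspring values V, philopatric parts v_phi.

    s_sigma averages next-generation breeder values over the patch-type
    transition and the fifty-fifty quality draw.  V_sigma combines the
    home route (win a natal vacancy) with the dispersal route and is the
    same for offspring of both qualities.  v_phi[rho, sigma] is the slice
    of a breeder's reproductive value flowing through offspring that stay
    and win at home — the currency of kin competition.
    """
    O, I = offspring_pools(f, params, env)
    h, w_phi = settlement(f, params, env)
    pi = env.stationary
    v_by = v.reshape(2, 2)  # [patch type, quality]
    s = env.forward @ (0.5 * (v_by[:, 0] + v_by[:, 1]))
    disperse = params.d * (1.0 - params.c) * float(
        np.sum(pi * params.n / (O + I) * s)
    )
    V = w_phi * s + disperse
    v_phi = f * (w_phi * s)[None, :]
    return s, V, v_phi


def resident_demography(
    f: np.ndarray, params: ModelParams, env: EnvironmentProcess
) -> DemographicState:
    """Full demographic equilibrium for a resident fecundity table."""
    O, I = offspring_pools(f, params, env)
    h, w_phi = settlement(f, params, env)
    w = build_fitness_matrix(f, params, env)
    # analytic stationary class weights (used only to apportion mass if
    # the matrix decouples at the correlation extremes)
    weights = np.repeat(env.stationary, 2) / 2.0
    u, v, lam = eigen_quantities(w, class_weights=weights)
    s, V, v_phi = value_components(f, v, params, env)
    return DemographicState(
        f=f, w=w, u=u, v=v, lam=lam, O=O, I=float(I), h=h,
        w_phi=w_phi, s=s, V=V, v_phi=v_phi,
    )
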