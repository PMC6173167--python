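"""Individual-based simulator of the exact life cycle.

A finite number of patches replaces the infinite-island expectation:
every generation each breeder's fecundity is computed from the patch's
current efforts, offspring pools are formed with philopatric weight
(1-d)f and a global migrant pool weight d(1-c)f, each patch's n
vacancies are filled by independent weighted draws (with replacement,
the infinite-fecundity analogue), winners take quality roles, traits
mutate, and patch types follow the forward environment chain.  Neutral
infinite-allele markers ride along to estimate realised relatedness.

The simulator is the stochastic oracle for the analytical pipeline:
evolved class-mean traits should match the convergence-stable z* and
marker relatedness should match the recursion's r, both within
Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import TRAIT_FLOOR
from .params import ModelParams, make_env_process

__all__ = ["SimConfig", "SimResult", "simulate", "estimate_relatedness"]

TRAIT_NAMES = ("z_HR", "z_LR", "z_HP", "z_LP")


@dataclass(frozen=True)
class SimConfig:
    """Run-length, population-size and mutation settings.

    Mutation is per trait per birth with a reflected-Gaussian kernel,
    small enough to keep the population near-monomorphic so the
    weak-selection analysis applies.  ``n_markers`` neutral
    infinite-allele loci (mutation rate ``marker_mu``) track identity
    by descent.
    """

    n_patches: int = 2000
    generations: int = 20_000
    burn_in: int | None = None          # default: generations // 2
    mutation_rate: float = 0.01
    mutation_sd: float = 0.02
    marker_mu: float = 1e-3
    n_markers: int = 8
    seed: int = 0
    record_every: int = 10
    init_trait: float = 0.5
    model: str = "fixed-roles"          # or "early-quality"

    def __post_init__(self) -> None:
        if self.n_patches < 100:
            raise ValueError("use at least 100 patches for oracle-quality runs")
        if self.model not in ("fixed-roles", "early-quality"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SimResult:
    """Trajectories, relatedness estimates and the final snapshot."""

    traj: pd.DataFrame                  # per-record generation stats
    trait_mean: np.ndarray              # time-averaged post-burn-in means
    trait_se: np.ndarray                # batch-mean standard errors
    r_hat: np.ndarray                   # (2,) realised relatedness by type
    r_se: np.ndarray
    snapshot: dict = field(default_factory=dict)
    config: SimConfig | None = None


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] (mutation kernel reflection)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def _weighted_slot_draws(
    f: np.ndarray, philo: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Parent (patch, index) for every vacancy.

    ``f`` has shape (patches, n).  Philopatric vacancies draw a local
    parent with probability proportional to fecundity; immigrant
    vacancies draw from the global fecundity distribution (uniform
    landing over patches is equivalent to one well-mixed migrant pool).
    """
    P, n = f.shape
    F = f.sum(axis=1)
    # local choice via inverse-cdf within each patch
    cdf_local = np.cumsum(f, axis=1) / F[:, None]
    u = rng.random((P, n))
    local_idx = (u[:, :, None] > cdf_local[:, None, :]).sum(axis=2)
    # global choice over all parents, fecundity-weighted
    flat = f.ravel()
    cdf_flat = np.cumsum(flat)
    g = np.searchsorted(cdf_flat, rng.random((P, n)) * cdf_flat[-1], side="right")
    g = np.minimum(g, P * n - 1)
    own_patch = np.broadcast_to(np.arange(P)[:, None], (P, n))
    parent_patch = np.where(philo, own_patch, g // n)
    parent_idx = np.where(philo, local_idx, g % n)
    return parent_patch, parent_idx


def simulate(params: ModelParams, sim: SimConfig) -> SimResult:
    """Run the finite-population life cycle; reproducible given the seed."""
    rng = np.random.default_rng(sim.seed)
    env = make_env_process(params.tau, params.p)
    P, n = sim.n_patches, params.n
    half = n // 2
    early = sim.model == "early-quality"
    n_traits = 8 if early else 4

    ptype = (rng.random(P) >= params.p).astype(np.int64)  # 0=R, 1=P
    if early:
        quality = (rng.random((P, n)) >= params.Q).astype(np.int64)
    else:
        quality = np.broadcast_to(
            np.array([0] * half + [1] * half), (P, n)
        ).copy()
    init = np.broadcast_to(np.asarray(sim.init_trait, dtype=float), (n_traits,))
    genome = np.tile(init, (P, n, 1)).copy()
    markers = np.arange(P * n * sim.n_markers, dtype=np.int64).reshape(
        P, n, sim.n_markers
    )
    marker_counter = markers.size

    burn_in = sim.burn_in if sim.burn_in is not None else sim.generations // 2
    records = []

    for gen in range(sim.generations):
        # expressed effort: trait index depends on own quality, patch
        # type, and (early-quality model, pairs only) the partner quality
        if early:
            partner_q = quality[:, ::-1]
            tidx = (2 * quality + partner_q) * 2 + ptype[:, None]
        else:
            tidx = 2 * ptype[:, None] + quality
        x = np.take_along_axis(genome, tidx[:, :, None], axis=2)[:, :, 0]
        xbar = x.mean(axis=1)
        theta = (1.0 - xbar) / xbar
        mu = params.mu[ptype]
        q_base = params.q[quality, ptype[:, None]]
        f = mu[:, None] * (q_base + x * theta[:, None])
        f = np.maximum(f, 0.0)

        F = f.sum(axis=1)
        O = (1.0 - params.d) * F
        I = params.d * (1.0 - params.c) * F.mean()
        if O.max() + I <= 0.0:
            raise RuntimeError("demographic collapse: no offspring compete")
        philo = rng.random((P, n)) < (O / (O + I))[:, None]
        # philopatric lottery weights are (1-d)f locally and d(1-c)f/P
        # per migrant source; conditioning on origin leaves fecundity-
        # proportional draws on both branches
        parent_patch, parent_idx = _weighted_slot_draws(f, philo, rng)

        genome = genome[parent_patch, parent_idx]
        markers = markers[parent_patch, parent_idx]

        mut = rng.random(genome.shape) < sim.mutation_rate
        n_mut = int(mut.sum())
        if n_mut:
            genome[mut] = _reflect(
                genome[mut] + rng.normal(0.0, sim.mutation_sd, n_mut),
                TRAIT_FLOOR, 1.0,
            )
        mmut = rng.random(markers.shape) < sim.marker_mu
        n_mm = int(mmut.sum())
        if n_mm:
            markers[mmut] = marker_counter + np.arange(n_mm)
            marker_counter += n_mm

        if early:
            quality = (rng.random((P, n)) >= params.Q).astype(np.int64)
        # fixed roles: slot < n/2 is high quality; winners are
        # exchangeable draws, so role assignment is uniform

        stay = rng.random(P) < env.forward[ptype, ptype]
        ptype = np.where(stay, ptype, 1 - ptype)

        if gen % sim.record_every == 0:
            row = {"generation": gen}
            means = genome.reshape(-1, n_traits).mean(axis=0)
            sds = genome.reshape(-1, n_traits).std(axis=0)
            for k in range(n_traits):
                row[f"trait{k}_mean"] = means[k]
                row[f"trait{k}_sd"] = sds[k]
            for t, nm in ((0, "R"), (1, "P")):
                sel = ptype == t  # type after transition; cheap proxy stats
                row[f"frac_{nm}"] = sel.mean()
            records.append(row)

    traj = pd.DataFrame(records)
    post = traj[traj["generation"] >= burn_in]
    mean_cols = [f"trait{k}_mean" for k in range(n_traits)]
    trait_mean = post[mean_cols].mean().to_numpy()
    trait_se = _batch_se(post[mean_cols].to_numpy())

    r_hat, r_se = estimate_relatedness(markers, ptype, rng=rng)
    snapshot = {
        "genome": genome, "markers": markers,
        "ptype": ptype, "quality": quality, "fecundity": f,
    }
    return SimResult(
        traj=traj, trait_mean=trait_mean, trait_se=trait_se,
        r_hat=r_hat, r_se=r_se, snapshot=snapshot, config=sim,
    )


def _integrated_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time of a scalar series (Sokal window).

    tau = 1 + 2 sum_k rho_k, truncated adaptively at the smallest M with
    M >= c * tau(M).  The variance of the series mean is var * tau / m.
    """
    m = x.size
    if m < 4:
        return float(m)
    y = x - x.mean()
    n_fft = int(2 ** np.ceil(np.log2(2 * m)))
    f = np.fft.rfft(y, n=n_fft)
    acov = np.fft.irfft(f * np.conjugate(f), n=n_fft)[:m].real
    if acov[0] <= 0.0:
        return 1.0
    rho = acov / acov[0]
    tau = 2.0 * np.cumsum(rho) - 1.0
    window = np.arange(m) >= c * tau
    M = int(np.argmax(window)) if window.any() else m - 1
    return float(max(tau[M], 1.0))


def _batch_se(series: np.ndarray) -> np.ndarray:
    """Monte-Carlo standard error of each column's time average.

    Consecutive records are strongly autocorrelated (trait means wander
    on a drift timescale of thousands of generations), so the SE is
    sd * sqrt(tau / m) with tau the integrated autocorrelation time.
    """
    m = series.shape[0]
    se = np.empty(series.shape[1])
    for j in range(series.shape[1]):
        tau = min(_integrated_time(series[:, j]), float(m))
        se[j] = series[:, j].std(ddof=1) * np.sqrt(tau / m)
    return se


def estimate_relatedness(
    markers: np.ndarray,
    ptype: np.ndarray,
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Realised relatedness per patch type from neutral markers.

    Uses the identity-based estimator r = (Qw - Qb) / (1 - Qb), where
    Qw is the within-patch pair identity (averaged over loci and member
    pairs) by current patch type and Qb the population-wide identity of
    two random individuals; bootstrap over patches gives the SEs.
    """
    rng = rng or np.random.default_rng()
    P, n, K = markers.shape
    # within-patch identity over all unordered member pairs
    pair_id = np.zeros(P)
    n_pairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            pair_id += (markers[:, i, :] == markers[:, j, :]).mean(axis=1)
    pair_id /= n_pairs
    # population identity from allele counts per locus
    flat = markers.reshape(-1, K)
    N = flat.shape[0]
    qb = 0.0
    for k in range(K):
        _, counts = np.unique(flat[:, k], return_counts=True)
        qb += float((counts * (counts - 1)).sum()) / (N * (N - 1))
    qb /= K

    r_hat = np.full(2, np.nan)
    r_se = np.full(2, np.nan)
    for t in (0, 1):
        idx = np.flatnonzero(ptype == t)
        if idx.size == 0:
            continue
        qw = pair_id[idx].mean()
        r_hat[t] = (qw - qb) / (1.0 - qb)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.integers(0, idx.size, idx.size)
            boots[b] = (pair_id[idx[take]].mean() - qb) / (1.0 - qb)
        r_se[t] = boots.std(ddof=1)
    return r_hat, r_se
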