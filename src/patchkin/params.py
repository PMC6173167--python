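"""Model parameters and the two-state patch environment.

The population lives on an infinite set of patches, each of which is
either resource-rich (R) or resource-poor (P).  Patch type follows a
stationary two-state Markov chain parameterised by the stationary
frequency ``p`` of rich patches and the lag-1 temporal autocorrelation
``tau``.  ``tau = 1`` means patch types never change, ``tau = 0`` means
types are redrawn independently each generation, and ``tau < 0`` means
types tend to alternate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "EnvironmentProcess",
    "ParameterError",
    "make_env_process",
    "validate_params",
    "load_config",
    "tau_lower_bound",
    "CAPTION_PARAMS",
]

# patch-type index order used everywhere: 0 = R (rich), 1 = P (poor)
RICH, POOR = 0, 1
# quality index order: 0 = H (high), 1 = L (low)
HIGH, LOW = 0, 1
# breeder-class order for 4-class state vectors: HR, LR, HP, LP
CLASS_LABELS = ("HR", "LR", "HP", "LP")


class ParameterError(ValueError):
    """A model parameter violates its domain or an invariant."""


def tau_lower_bound(p: float) -> float:
    """Smallest feasible temporal correlation for rich-patch frequency ``p``.

    Negative correlation is limited by the requirement that the
    transition probabilities p_R->R = p + (1-p)*tau and
    p_P->P = (1-p) + p*tau stay in [0, 1].
    """
    return -min(p, 1.0 - p) / max(p, 1.0 - p)


@dataclass(frozen=True)
class ModelParams:
    """All ecological, demographic and genetic constants of a run.

    Parameters
    ----------
    d : float
        Offspring dispersal probability.
    c : float
        Mortality cost of dispersal (dispersers survive with prob 1-c).
    p : float
        Stationary frequency of resource-rich patches, in (0, 1).
    tau : float
        Lag-1 temporal autocorrelation of patch type, in [-1, 1]
        (bounded below by :func:`tau_lower_bound` when p != 1/2).
    mu_R, mu_P : float
        Resource levels of rich and poor patches; mu_R >= mu_P > 0.
    q_HR, q_LR, q_HP, q_LP : float
        Baseline (asocial) fecundity qualities by breeder quality and
        patch type; high-quality baselines dominate within each type.
    n : int
        Breeders per patch (even, >= 2); half high-, half low-quality
        in the fixed-roles model.
    Q : float
        Probability of acquiring high quality at birth (early-life
        quality-acquisition model only).
    """

    d: float
    c: float
    p: float
    tau: float
    mu_R: float = 1.0
    mu_P: float = 0.1
    q_HR: float = 1.0
    q_LR: float = 0.1
    q_HP: float = 1.0
    q_LP: float = 0.1
    n: int = 2
    Q: float = 0.5

    def __post_init__(self) -> None:
        for name in ("d", "c", "Q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v!r} must lie in [0, 1]")
        if not 0.0 < self.p < 1.0:
            raise ParameterError(f"p={self.p!r} must lie strictly in (0, 1)")
        if not -1.0 <= self.tau <= 1.0:
            raise ParameterError(f"tau={self.tau!r} must lie in [-1, 1]")
        lo = tau_lower_bound(self.p)
        if self.tau < lo - 1e-12:
            raise ParameterError(
                f"tau={self.tau!r} below feasibility bound {lo:.6g} for "
                f"p={self.p!r}: induced transition probabilities leave [0, 1]"
            )
        if not self.mu_P > 0.0:
            raise ParameterError(f"mu_P={self.mu_P!r} must be positive")
        if self.mu_R < self.mu_P:
            raise ParameterError(
                f"mu_R={self.mu_R!r} must be >= mu_P={self.mu_P!r}"
            )
        for nm in ("q_HR", "q_LR", "q_HP", "q_LP"):
            if getattr(self, nm) < 0.0:
                raise ParameterError(f"{nm}={getattr(self, nm)!r} must be >= 0")
        if self.q_HR < self.q_LR or self.q_HP < self.q_LP:
            raise ParameterError(
                "high-quality baselines must dominate: q_HR >= q_LR and q_HP >= q_LP"
            )
        if self.n < 2 or self.n % 2 != 0:
            raise ParameterError(f"n={self.n!r} must be an even integer >= 2")

    # convenience accessors in (quality, patch-type) index order -------
    @property
    def mu(self) -> np.ndarray:
        """Resource levels indexed by patch type (R, P)."""
        return np.array([self.mu_R, self.mu_P])

    @property
    def q(self) -> np.ndarray:
        """Baseline qualities, shape (2 qualities, 2 patch types)."""
        return np.array([[self.q_HR, self.q_HP], [self.q_LR, self.q_LP]])

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EnvironmentProcess:
    """Stationary two-state Markov chain over patch types {R, P}.

    ``forward[s, t]`` is the probability that a type-s patch is type t in
    the next generation; ``backward[g, s]`` is the probability that a
    patch currently of type s was of type g in the previous generation
    (Bayes at stationarity); ``stationary`` is (p, 1-p).
    """

    forward: np.ndarray
    backward: np.ndarray
    stationary: np.ndarray


def make_env_process(tau: float, p: float) -> EnvironmentProcess:
    """Build the patch-type transition process from (tau, p).

    The chain is the unique two-state Markov chain with stationary
    distribution (p, 1-p) and lag-1 autocorrelation tau:
    p_R->R = p + (1-p)*tau and p_P->P = (1-p) + p*tau.
    """
    if not 0.0 < p < 1.0:
        raise ParameterError(f"p={p!r} must lie strictly in (0, 1)")
    if not -1.0 <= tau <= 1.0:
        raise ParameterError(f"tau={tau!r} must lie in [-1, 1]")
    if tau < tau_lower_bound(p) - 1e-12:
        raise ParameterError(
            f"tau={tau!r} below feasibility bound {tau_lower_bound(p):.6g} "
            f"for p={p!r}"
        )
    p_rr = p + (1.0 - p) * tau
    p_pp = (1.0 - p) + p * tau
    forward = np.array([[p_rr, 1.0 - p_rr], [1.0 - p_pp, p_pp]])
    forward = np.clip(forward, 0.0, 1.0)  # guard rounding at tau bounds
    pi = np.array([p, 1.0 - p])
    # backward[g, s] = pi_g * forward[g, s] / pi_s
    backward = pi[:, None] * forward / pi[None, :]
    return EnvironmentProcess(forward=forward, backward=backward, stationary=pi)


_REQUIRED_KEYS = ("d", "c", "p", "tau")
_FIELD_NAMES = tuple(f.name for f in fields(ModelParams))


def validate_params(raw: dict) -> ModelParams:
    """Validate a flat key-value map into a :class:`ModelParams`.

    Missing optional fields take their defaults (n=2, Q=0.5, caption
    resource/quality values).  Unknown keys, missing required keys,
    non-numeric values and invariant violations raise
    :class:`ParameterError` naming the offending field.
    """
    unknown = sorted(set(raw) - set(_FIELD_NAMES))
    if unknown:
        raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
    missing = sorted(set(_REQUIRED_KEYS) - set(raw))
    if missing:
        raise ParameterError(f"missing required parameter(s): {', '.join(missing)}")
    clean = {}
    for key, value in raw.items():
        try:
            clean[key] = int(value) if key == "n" else float(value)
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"parameter {key}={value!r} is not numeric") from exc
    return ModelParams(**clean)


def load_config(path, overrides: dict | None = None) -> ModelParams:
    """Read a YAML config file of ModelParams keys; overrides win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a flat key-value mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return validate_params(raw)


#: The parameter set used throughout the worked examples: strong dispersal
#: cost, rare dispersal, equal patch-type frequencies and a ten-fold
#: spread both in individual baseline quality and in patch resources.
CAPTION_PARAMS = ModelParams(
    d=0.1, c=0.9, p=0.5, tau=0.0,
    mu_R=1.0, mu_P=0.1, q_HR=1.0, q_LR=0.1, q_HP=1.0, q_LP=0.1,
)
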