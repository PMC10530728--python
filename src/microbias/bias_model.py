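"""Main-effect and taxon-taxon interaction bias structures.

The multiplicative measurement-bias model of marker-gene sequencing says that
the observed relative abundance of taxon ``j`` in sample ``i`` is its true
relative abundance times a taxon-specific bias factor ``exp(gamma_j)``,
renormalized within the sample.  This module extends that model with
*interaction* biases: the log bias of taxon ``j`` is additionally perturbed by
``eta_ij = sum_{j' != j} theta[j, j'] * pi[i, j']``, where ``pi[i, j']`` is the
true relative abundance of the interacting taxon ``j'``.

The interaction coefficients are generated relative to the main-effect biases,

    theta[j, j'] = -sign(gamma[j']) * phi * epsilon[j, j'] * |gamma[j]|,

so that (a) a taxon that is over-measured (``gamma[j'] > 0``) depresses the
measured abundance of other taxa, consistent with a roughly constant amplicon
budget; (b) the perturbation magnitude scales with the main bias of the
affected taxon; and (c) ``phi`` is a single dial for the overall strength of
interaction biases relative to main-effect biases.  ``epsilon`` is a
non-negative unit-mean noise term whose distribution defines three scenarios:

* ``S-nondiff``   -- ``epsilon/2 ~ N(0.5, sd^2)`` for every ordered pair.
* ``S-diff-causal`` -- rows belonging to trait-associated (causal) taxa use
  ``epsilon/2 ~ Beta(a, b)`` instead, giving trait-related extra variability.
* ``S-diff-half`` -- a random half of all rows use the beta distribution,
  giving large but trait-unrelated variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCENARIOS",
    "MainEffectBias",
    "InteractionConfig",
    "EpsilonDraws",
    "InteractionMatrix",
    "draw_main_biases",
    "draw_epsilon",
    "build_interaction_matrix",
    "interaction_bias_field",
    "phi_from_presence_ratios",
]

S_NONDIFF = "S-nondiff"
S_DIFF_CAUSAL = "S-diff-causal"
S_DIFF_HALF = "S-diff-half"
SCENARIOS = (S_NONDIFF, S_DIFF_CAUSAL, S_DIFF_HALF)


@dataclass(frozen=True)
class MainEffectBias:
    """Per-taxon log-scale main-effect bias factors.

    ``gamma[j]`` is the log fold change between the expected observed and the
    true relative abundance of taxon ``j`` (before renormalization).
    """

    gamma: np.ndarray
    sigma_gamma: float = 0.8

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("gamma must be a non-empty 1-d vector")
        if not np.all(np.isfinite(g)):
            raise ValueError("gamma entries must be finite")
        object.__setattr__(self, "gamma", g)

    @property
    def n_taxa(self) -> int:
        return self.gamma.size


@dataclass(frozen=True)
class InteractionConfig:
    """Configuration of the interaction-bias generator.

    Parameters
    ----------
    phi
        Non-negative magnitude of interaction biases relative to main-effect
        biases; ``phi = 0`` disables interactions entirely.
    scenario
        One of ``S-nondiff``, ``S-diff-causal``, ``S-diff-half``.
    causal_set
        Taxon indices whose epsilon rows switch to the beta distribution under
        ``S-diff-causal``.
    half_set
        Taxon indices (typically a random half) whose rows switch to the beta
        distribution under ``S-diff-half``.
    epsilon_normal_sd
        Standard deviation of the half-scale normal error ``epsilon/2``.
    epsilon_beta_params
        ``(a, b)`` of the half-scale beta error.
    """

    phi: float
    scenario: str = S_NONDIFF
    causal_set: tuple[int, ...] | None = None
    half_set: tuple[int, ...] | None = None
    epsilon_normal_sd: float = 0.1
    epsilon_beta_params: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError(f"phi must be non-negative, got {self.phi}")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.scenario == S_DIFF_CAUSAL and not self.causal_set:
            raise ValueError("S-diff-causal requires a non-empty causal_set")
        if self.scenario == S_DIFF_HALF and not self.half_set:
            raise ValueError("S-diff-half requires a non-empty half_set")

    def beta_rows(self, n_taxa: int) -> np.ndarray:
        """Boolean mask of rows whose epsilon uses the beta distribution."""
        mask = np.zeros(n_taxa, dtype=bool)
        if self.scenario == S_DIFF_CAUSAL:
            mask[np.asarray(self.causal_set, dtype=int)] = True
        elif self.scenario == S_DIFF_HALF:
            mask[np.asarray(self.half_set, dtype=int)] = True
        return mask


@dataclass(frozen=True)
class EpsilonDraws:
    """J x J matrix of non-negative, unit-mean error terms epsilon[j, j']."""

    epsilon: np.ndarray
    beta_rows: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        e = np.asarray(self.epsilon, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("epsilon must be a square matrix")
        if np.any(e < 0):
            raise ValueError("epsilon entries must be non-negative")
        object.__setattr__(self, "epsilon", e)


@dataclass(frozen=True)
class InteractionMatrix:
    """Interaction-bias coefficients theta[j, j'].

    ``theta[j, j']`` is the extent to which the relative abundance of taxon
    ``j'`` perturbs the log bias of taxon ``j``.  The diagonal is identically
    zero (no self-interaction) and each ``theta[j, j']`` opposes the sign of
    ``gamma[j']``.  The matrix need not be symmetric.
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("theta must be a square matrix")
        object.__setattr__(self, "theta", t)


def draw_main_biases(
    J: int, sigma_gamma: float = 0.8, rng: np.random.Generator | None = None
) -> MainEffectBias:
    """Draw per-taxon main-effect biases gamma_j ~ N(0, sigma_gamma^2).

    At the default ``sigma_gamma = 0.8`` the central 95% of the implied bias
    fold changes ``exp(gamma)`` spans roughly 0.2 to 5.
    """
    if J < 1:
        raise ValueError(f"J must be a positive integer, got {J}")
    if sigma_gamma < 0:
        raise ValueError("sigma_gamma must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    gamma = rng.normal(0.0, sigma_gamma, size=J)
    return MainEffectBias(gamma=gamma, sigma_gamma=sigma_gamma)


def draw_epsilon(
    config: InteractionConfig,
    J: int,
    seeds: np.random.SeedSequence | int,
) -> EpsilonDraws:
    """Draw the J x J unit-mean error matrix epsilon.

    Row ``j`` (all interactions *received* by taxon ``j``) is drawn on the
    half scale: ``epsilon/2 ~ N(0.5, sd^2)`` for normal rows, clamped at zero,
    or ``epsilon/2 ~ Beta(a, b)`` for rows selected by the scenario.  Each row
    uses its own child random stream of ``seeds``, so switching a subset of
    rows between distributions (e.g. ``S-nondiff`` vs ``S-diff-causal``) leaves
    the draws of every unswitched row bit-for-bit unchanged.  Diagonal entries
    are drawn for stream alignment but are never used downstream (the
    interaction matrix zeroes its diagonal).
    """
    if J < 1:
        raise ValueError(f"J must be a positive integer, got {J}")
    if not isinstance(seeds, np.random.SeedSequence):
        seeds = np.random.SeedSequence(seeds)
    beta_rows = config.beta_rows(J)
    a, b = config.epsilon_beta_params
    eps = np.empty((J, J), dtype=float)
    for j, child in enumerate(seeds.spawn(J)):
        row_rng = np.random.default_rng(child)
        if beta_rows[j]:
            half = row_rng.beta(a, b, size=J)
        else:
            half = row_rng.normal(0.5, config.epsilon_normal_sd, size=J)
        eps[j] = 2.0 * half
    # N(0.5, 0.1^2) has ~3e-7 mass below zero; clamp to keep the stated
    # non-negative support.
    np.clip(eps, 0.0, None, out=eps)
    return EpsilonDraws(epsilon=eps, beta_rows=beta_rows)


def build_interaction_matrix(
    gamma: MainEffectBias,
    config: InteractionConfig,
    epsilon: EpsilonDraws,
) -> InteractionMatrix:
    """Assemble theta[j, j'] = -sign(gamma[j']) * phi * epsilon[j, j'] * |gamma[j]|.

    ``sign(0)`` is taken as 0, so a taxon with exactly zero main bias induces
    no interaction bias in others; the diagonal is forced to zero.
    """
    g = gamma.gamma
    if epsilon.epsilon.shape != (g.size, g.size):
        raise ValueError(
            f"epsilon shape {epsilon.epsilon.shape} does not match {g.size} taxa"
        )
    theta = -np.sign(g)[None, :] * config.phi * epsilon.epsilon * np.abs(g)[:, None]
    np.fill_diagonal(theta, 0.0)
    return InteractionMatrix(theta=theta)


def interaction_bias_field(
    theta: InteractionMatrix | np.ndarray,
    Pi: np.ndarray,
    *,
    atol: float = 1e-6,
) -> np.ndarray:
    """Total interaction-bias contribution eta[i, j] = sum_{j'!=j} theta[j, j'] Pi[i, j'].

    ``Pi`` holds true relative abundances, one sample per row (rows must sum
    to one).  Because each contribution is weighted by a relative abundance
    and contributions carry both signs, eta averages out near zero across
    samples, while its per-taxon variance grows with ``|gamma[j]|``.
    """
    t = theta.theta if isinstance(theta, InteractionMatrix) else np.asarray(theta, float)
    Pi = np.asarray(Pi, dtype=float)
    if Pi.ndim == 1:
        Pi = Pi[None, :]
    if Pi.shape[1] != t.shape[0]:
        raise ValueError("Pi and theta disagree on the number of taxa")
    row_sums = Pi.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > atol):
        raise ValueError("rows of Pi must sum to 1 (relative abundances)")
    # the diagonal of theta is zero, so the full matrix product realizes the
    # j' != j sum
    return Pi @ t.T


def phi_from_presence_ratios(
    mean_abs_ratio: float, mean_relative_abundance: float
) -> float:
    """Convert a presence-model interaction/main-effect ratio to phi.

    Mock-community fits of a presence-based interaction model report
    ``theta~[j, j']``, the shift in taxon ``j``'s log bias caused by the mere
    presence of ``j'``.  In the abundance-weighted model used here that shift
    corresponds to ``theta[j, j'] * pi[i, j']``, so when community members
    have a common relative abundance ``p`` the magnitudes relate by
    ``phi = mean|theta~/gamma| / p``.  For example, a mean presence-scale
    ratio of 0.204 in three-member equal-proportion communities (p = 1/3)
    gives ``phi = 0.612``.
    """
    if mean_abs_ratio <= 0:
        raise ValueError("mean_abs_ratio must be positive")
    if mean_relative_abundance <= 0:
        raise ValueError("mean_relative_abundance must be positive")
    return mean_abs_ratio / mean_relative_abundance
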