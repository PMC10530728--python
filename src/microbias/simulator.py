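"""Replicate data generator: communities, traits, spike-ins, biases, counts.

One replicate dataset is produced by a fixed chain of steps, each consuming a
named child stream of the replicate seed:

1. baseline relative abundances ``Pi0`` drawn per sample from a Dirichlet
   with mean ``pi_bar`` and overdispersion ``theta_DM``;
2. a binary (balanced, randomly ordered) or continuous (U[-1, 1]) trait, plus
   an optional binary confounder correlated with the binary trait;
3. *true* abundances ``Pi``: an exponential tilt of ``Pi0`` by the trait and
   confounder log fold changes, renormalized per sample;
4. *observed* expected abundances ``P``: a further tilt by the bias factor
   ``exp(gamma_j + eta_ij)`` with ``eta`` the interaction-bias field;
5. read counts: one multinomial draw per sample at a library size from a
   left-truncated normal.

Because every step has its own substream, disabling a step (e.g. ``phi = 0``
skips the interaction draws) leaves all other draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bias_model import (
    InteractionConfig,
    InteractionMatrix,
    MainEffectBias,
    S_DIFF_CAUSAL,
    S_DIFF_HALF,
    S_NONDIFF,
    build_interaction_matrix,
    draw_epsilon,
    draw_main_biases,
    interaction_bias_field,
)

__all__ = [
    "CommunityProfile",
    "StudyDesign",
    "EffectSpec",
    "LibrarySizeModel",
    "ReplicateSpec",
    "SimulatedDataset",
    "URT_TOP5",
    "synthesize_mean_abundances",
    "draw_baseline_abundances",
    "select_causal_taxa",
    "select_confounder_taxa",
    "draw_traits",
    "true_abundances",
    "observed_abundances",
    "draw_library_sizes",
    "draw_counts",
    "simulate_replicate",
]

#: Mean relative abundances of the five most abundant taxa in the upper
#: respiratory tract profile that the default community emulates.
URT_TOP5 = (0.105, 0.062, 0.054, 0.050, 0.049)

# named substreams of a replicate seed
_K_CAUSAL, _K_CONF, _K_BASELINE, _K_TRAITS, _K_GAMMA, _K_EPS, _K_HALF, _K_LIB, _K_COUNTS = range(9)


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class CommunityProfile:
    """Mean relative abundances and Dirichlet overdispersion of a community."""

    pi_bar: np.ndarray
    overdispersion: float = 0.02

    def __post_init__(self) -> None:
        p = np.asarray(self.pi_bar, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("pi_bar must be a 1-d vector with at least 2 taxa")
        if np.any(p < 0):
            raise ValueError("pi_bar entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("pi_bar must sum to 1")
        if not 0.0 < self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in (0, 1)")
        object.__setattr__(self, "pi_bar", p)

    @property
    def n_taxa(self) -> int:
        return self.pi_bar.size


@dataclass(frozen=True)
class StudyDesign:
    """Sample size and trait/confounder layout."""

    n: int = 100
    trait_type: str = "binary"
    confounded: bool = False
    confounder_prob_when_T0: float = 0.2
    confounder_prob_when_T1: float = 0.8

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError("trait_type must be 'binary' or 'continuous'")
        if self.n < 2:
            raise ValueError("need at least 2 samples")
        if self.trait_type == "binary" and self.n % 2:
            raise ValueError("binary designs need an even n (equal group sizes)")
        if self.confounded and self.trait_type == "continuous":
            raise ValueError("a confounder is only supported with a binary trait")
        for p in (self.confounder_prob_when_T0, self.confounder_prob_when_T1):
            if not 0.0 <= p <= 1.0:
                raise ValueError("confounder probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Trait and confounder log fold effects on absolute abundances.

    ``beta`` is the common trait effect beta_{j,1} shared by all causal taxa;
    ``beta_confounder`` holds per-taxon confounder effects beta_{j,2} aligned
    with ``confounder_set``.  Effects are zero off the respective sets.
    """

    causal_set: np.ndarray
    beta: float = 0.0
    confounder_set: np.ndarray | None = None
    beta_confounder: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.causal_set, dtype=int).ravel()
        object.__setattr__(self, "causal_set", c)
        if self.confounder_set is not None:
            f = np.asarray(self.confounder_set, dtype=int).ravel()
            object.__setattr__(self, "confounder_set", f)
            if self.beta_confounder is None:
                object.__setattr__(
                    self, "beta_confounder", default_confounder_effects(f, self.beta)
                )
            else:
                b2 = np.asarray(self.beta_confounder, dtype=float).ravel()
                if b2.size != f.size:
                    raise ValueError("beta_confounder must align with confounder_set")
                object.__setattr__(self, "beta_confounder", b2)
        elif self.beta_confounder is not None:
            raise ValueError("beta_confounder given without confounder_set")


def default_confounder_effects(confounder_set: np.ndarray, beta: float) -> np.ndarray:
    """Default confounder effect sizes: magnitude ``beta``, alternating signs."""
    k = np.asarray(confounder_set).size
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return beta * signs


@dataclass(frozen=True)
class LibrarySizeModel:
    """Left-truncated normal model for per-sample read depth."""

    mean: float = 10_000.0
    sd: float = 10_000.0 / 3.0
    lower_truncation: float = 2_000.0

    def __post_init__(self) -> None:
        if self.lower_truncation <= 0:
            raise ValueError("lower_truncation must be positive")
        if self.mean <= self.lower_truncation:
            raise ValueError("mean must exceed the truncation point")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class SimulatedDataset:
    """One replicate: abundance matrices, counts, design and truth labels."""

    counts: np.ndarray
    Pi0: np.ndarray
    Pi: np.ndarray
    P: np.ndarray
    log_norm: np.ndarray
    library_sizes: np.ndarray
    T: np.ndarray
    C: np.ndarray | None
    causal_set: np.ndarray
    confounder_set: np.ndarray
    gamma: np.ndarray
    eta: np.ndarray
    replicate_seed: int

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def null_mask(self) -> np.ndarray:
        """Boolean mask of taxa with no trait association (beta_{j,1} = 0)."""
        m = np.ones(self.n_taxa, dtype=bool)
        m[self.causal_set] = False
        return m


def synthesize_mean_abundances(
    J: int,
    rng: np.random.Generator | None = None,
    pinned_top: tuple[float, ...] | None = None,
) -> CommunityProfile:
    """Synthesize a heavy-tailed, sorted, normalized mean-abundance vector.

    The vector emulates the rank-abundance shape of an upper-respiratory-tract
    community: a handful of dominant taxa and a long tail of rare ones.  Ranks
    decay as a power law with log-normal noise, then are sorted and
    normalized.  When ``pinned_top`` is given, the leading entries equal the
    pinned values exactly and the tail is rescaled (and capped below the last
    pinned value to keep the vector non-increasing) to fill the remainder.
    """
    if J < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng() if rng is None else rng

    def _tail(m: int) -> np.ndarray:
        ranks = np.arange(1, m + 1, dtype=float)
        raw = ranks**-1.0 * rng.lognormal(0.0, 0.5, size=m)
        return np.sort(raw)[::-1]

    if pinned_top is None:
        pi = _tail(J)
        pi = pi / pi.sum()
        return CommunityProfile(pi_bar=pi)

    top = np.asarray(pinned_top, dtype=float)
    if np.any(top <= 0) or np.any(np.diff(top) > 0):
        raise ValueError("pinned_top must be positive and non-increasing")
    if top.sum() >= 1.0:
        raise ValueError("pinned_top values must sum to less than 1")
    k = top.size
    if k >= J:
        raise ValueError("pinned_top must leave room for a tail (len < J)")
    remainder = 1.0 - top.sum()
    tail = _tail(J - k)
    tail = tail / tail.sum() * remainder
    # cap strictly below the last pinned value so the pinned head stays the
    # unambiguous top of the profile (no ties with the tail)
    cap = top[-1] * 0.999
    if remainder > cap * (J - k):
        raise ValueError("too few taxa to fit the remainder under the last pinned value")
    # water-fill: clip entries above the cap and push the excess into the
    # unclipped part so the profile stays sorted with the pinned head on top
    for _ in range(100):
        over = tail > cap
        if not over.any():
            break
        excess = (tail[over] - cap).sum()
        tail[over] = cap
        free = ~over
        tail[free] += excess * tail[free] / tail[free].sum()
    tail = np.sort(tail)[::-1]
    # no final renormalization: the head must stay bit-exact at the pinned
    # values, and head + tail already sum to 1 up to float error
    return CommunityProfile(pi_bar=np.concatenate([top, tail]))


def dirichlet_concentration(profile: CommunityProfile) -> np.ndarray:
    """Concentration alpha_j = pi_bar_j (1 - theta_DM) / theta_DM.

    With this parameterization ``Var(pi_j) = pi_bar_j (1 - pi_bar_j) theta_DM``.
    """
    th = profile.overdispersion
    return profile.pi_bar * (1.0 - th) / th


def draw_baseline_abundances(
    profile: CommunityProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n baseline relative-abundance vectors from the Dirichlet."""
    if n < 1:
        raise ValueError("n must be positive")
    return rng.dirichlet(dirichlet_concentration(profile), size=n)


def select_causal_taxa(
    profile: CommunityProfile, scheme: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Select trait-associated taxa under scheme M1 or M2.

    M1 draws 20 taxa uniformly from those with mean relative abundance above
    0.005, excluding the single most abundant taxon; M2 deterministically
    takes the five most abundant taxa.
    """
    pi = profile.pi_bar
    if scheme == "M2":
        return np.sort(np.argsort(pi)[::-1][:5])
    if scheme != "M1":
        raise ValueError(f"unknown causal-set scheme {scheme!r}")
    pool = np.flatnonzero(pi > 0.005)
    pool = pool[pool != int(np.argmax(pi))]
    if pool.size < 20:
        raise ValueError(
            f"M1 needs at least 20 eligible taxa (mean abundance > 0.005), got {pool.size}"
        )
    rng = np.random.default_rng() if rng is None else rng
    return np.sort(rng.choice(pool, size=20, replace=False))


def select_confounder_taxa(
    causal_set: np.ndarray,
    null_pool: np.ndarray,
    scheme: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Select confounder-associated taxa: 10+10 under M1, 2 causal + 3 null under M2."""
    n_causal, n_null = {"M1": (10, 10), "M2": (2, 3)}.get(scheme, (None, None))
    if n_causal is None:
        raise ValueError(f"unknown causal-set scheme {scheme!r}")
    causal_set = np.asarray(causal_set, dtype=int)
    null_pool = np.asarray(null_pool, dtype=int)
    if causal_set.size < n_causal or null_pool.size < n_null:
        raise ValueError("pools too small for the requested confounder set")
    picked_c = rng.choice(causal_set, size=n_causal, replace=False)
    picked_n = rng.choice(null_pool, size=n_null, replace=False)
    return np.sort(np.concatenate([picked_c, picked_n]))


def draw_traits(
    design: StudyDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw the trait vector T and, for confounded binary designs, C.

    Binary traits are balanced (n/2 per group) and randomly ordered so sample
    index carries no information; continuous traits are i.i.d. U[-1, 1].
    The confounder is Bernoulli(0.2) when T=0 and Bernoulli(0.8) when T=1.
    """
    n = design.n
    if design.trait_type == "binary":
        T = np.repeat([0.0, 1.0], n // 2)
        T = rng.permutation(T)
        C = None
        if design.confounded:
            p = np.where(
                T == 1.0,
                design.confounder_prob_when_T1,
                design.confounder_prob_when_T0,
            )
            C = rng.binomial(1, p).astype(float)
        return T, C
    if design.confounded:
        raise ValueError("a confounder is only supported with a binary trait")
    return rng.uniform(-1.0, 1.0, size=n), None


def _log_tilt(
    n_taxa: int, effects: EffectSpec, T: np.ndarray, C: np.ndarray | None
) -> np.ndarray:
    """Per-sample, per-taxon log fold change beta_{j,1} T_i + beta_{j,2} C_i."""
    n = T.size
    lt = np.zeros((n, n_taxa))
    if effects.causal_set.size and effects.beta != 0.0:
        lt[:, effects.causal_set] += effects.beta * T[:, None]
    if effects.confounder_set is not None and effects.confounder_set.size:
        if C is None:
            raise ValueError("confounder effects specified but no confounder drawn")
        lt[:, effects.confounder_set] += effects.beta_confounder[None, :] * C[:, None]
    return lt


def true_abundances(
    Pi0: np.ndarray, effects: EffectSpec, T: np.ndarray, C: np.ndarray | None = None
) -> np.ndarray:
    """True relative abundances: exponential tilt of the baseline, renormalized.

    pi_ij = exp(beta_{j,1} T_i + beta_{j,2} C_i) pi0_ij / sum_j* (...)
    """
    Pi0 = np.asarray(Pi0, dtype=float)
    W = Pi0 * np.exp(_log_tilt(Pi0.shape[1], effects, T, C))
    return W / W.sum(axis=1, keepdims=True)


def observed_abundances(
    Pi0: np.ndarray,
    Pi: np.ndarray,
    gamma: MainEffectBias,
    theta: InteractionMatrix | np.ndarray,
    effects: EffectSpec,
    T: np.ndarray,
    C: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected observed relative abundances under main + interaction biases.

    p_ij is proportional to exp(gamma_j + eta_ij + beta_{j,1} T_i +
    beta_{j,2} C_i) pi0_ij, renormalized per sample; ``eta`` is evaluated at
    the *true* (post-spike) abundances ``Pi``.  Returns ``(P, log_norm)``
    where ``log_norm[i]`` is the log of the per-sample normalizing
    denominator (the implicit normalization constant of the log-linear bias
    model, up to sign convention).
    """
    Pi0 = np.asarray(Pi0, dtype=float)
    eta = interaction_bias_field(theta, Pi)
    return _observed_from_eta(Pi0, eta, gamma, effects, T, C)


def _observed_from_eta(
    Pi0: np.ndarray,
    eta: np.ndarray,
    gamma: MainEffectBias,
    effects: EffectSpec,
    T: np.ndarray,
    C: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    logw = gamma.gamma[None, :] + eta + _log_tilt(Pi0.shape[1], effects, T, C)
    W = Pi0 * np.exp(logw)
    denom = W.sum(axis=1)
    return W / denom[:, None], np.log(denom)


def draw_library_sizes(
    model: LibrarySizeModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw integer library sizes from the left-truncated normal by rejection.

    At the defaults (mean 10,000, sd 10,000/3, truncation 2,000) about 99.2%
    of proposals are accepted.  Draws are rounded to the nearest integer.
    """
    if model.sd == 0.0:
        return np.full(n, int(round(model.mean)), dtype=np.int64)
    out = np.empty(0)
    while out.size < n:
        batch = rng.normal(model.mean, model.sd, size=max(n, 1024))
        out = np.concatenate([out, batch[batch >= model.lower_truncation]])
    return np.rint(out[:n]).astype(np.int64)


def draw_counts(
    P: np.ndarray, library_sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read counts, one draw per sample at its library size."""
    P = np.asarray(P, dtype=float)
    P = P / P.sum(axis=1, keepdims=True)
    return rng.multinomial(np.asarray(library_sizes, dtype=np.int64), P)


@dataclass(frozen=True)
class ReplicateSpec:
    """Full configuration of one simulated replicate.

    ``causal_set``/``confounder_set`` may be pinned (e.g. fixed across the
    replicates of a grid cell); when ``None`` they are drawn from the
    replicate's own streams.  ``fixed_gamma`` pins the main-effect biases
    instead of redrawing them per replicate.
    """

    profile: CommunityProfile
    design: StudyDesign = field(default_factory=StudyDesign)
    scheme: str = "M1"
    beta: float = 0.0
    sigma_gamma: float = 0.8
    phi: float = 0.0
    scenario: str = S_NONDIFF
    epsilon_normal_sd: float = 0.1
    epsilon_beta_params: tuple[float, float] = (0.5, 0.5)
    library: LibrarySizeModel = field(default_factory=LibrarySizeModel)
    causal_set: np.ndarray | None = None
    confounder_set: np.ndarray | None = None
    beta_confounder: np.ndarray | None = None
    fixed_gamma: np.ndarray | None = None


def simulate_replicate(spec: ReplicateSpec, replicate_seed: int) -> SimulatedDataset:
    """Generate one replicate dataset; deterministic in (spec, replicate_seed)."""
    J = spec.profile.n_taxa
    seed = int(replicate_seed)

    causal = spec.causal_set
    if causal is None:
        causal = select_causal_taxa(spec.profile, spec.scheme, _stream(seed, _K_CAUSAL))
    causal = np.asarray(causal, dtype=int)

    conf: np.ndarray | None = spec.confounder_set
    if spec.design.confounded and conf is None:
        null_pool = np.setdiff1d(np.arange(J), causal)
        conf = select_confounder_taxa(causal, null_pool, spec.scheme, _stream(seed, _K_CONF))
    conf = None if conf is None else np.asarray(conf, dtype=int)

    effects = EffectSpec(
        causal_set=causal,
        beta=spec.beta,
        confounder_set=conf if spec.design.confounded else None,
        beta_confounder=spec.beta_confounder if spec.design.confounded else None,
    )

    Pi0 = draw_baseline_abundances(spec.profile, spec.design.n, _stream(seed, _K_BASELINE))
    T, C = draw_traits(spec.design, _stream(seed, _K_TRAITS))
    Pi = true_abundances(Pi0, effects, T, C)

    if spec.fixed_gamma is not None:
        gamma = MainEffectBias(np.asarray(spec.fixed_gamma, float), spec.sigma_gamma)
    else:
        gamma = draw_main_biases(J, spec.sigma_gamma, _stream(seed, _K_GAMMA))

    if spec.phi > 0.0:
        half_set: tuple[int, ...] | None = None
        if spec.scenario == S_DIFF_HALF:
            half = _stream(seed, _K_HALF).choice(J, size=J // 2, replace=False)
            half_set = tuple(int(j) for j in half)
        icfg = InteractionConfig(
            phi=spec.phi,
            scenario=spec.scenario,
            causal_set=tuple(int(j) for j in causal)
            if spec.scenario == S_DIFF_CAUSAL
            else None,
            half_set=half_set,
            epsilon_normal_sd=spec.epsilon_normal_sd,
            epsilon_beta_params=spec.epsilon_beta_params,
        )
        eps = draw_epsilon(icfg, J, np.random.SeedSequence(seed, spawn_key=(_K_EPS,)))
        theta = build_interaction_matrix(gamma, icfg, eps).theta
        eta = interaction_bias_field(theta, Pi)
    else:
        eta = np.zeros((spec.design.n, J))
    P, log_norm = _observed_from_eta(Pi0, eta, gamma, effects, T, C)
    libs = draw_library_sizes(spec.library, spec.design.n, _stream(seed, _K_LIB))
    counts = draw_counts(P, libs, _stream(seed, _K_COUNTS))

    return SimulatedDataset(
        counts=counts,
        Pi0=Pi0,
        Pi=Pi,
        P=P,
        log_norm=log_norm,
        library_sizes=libs,
        T=T,
        C=C,
        causal_set=causal if spec.beta != 0.0 else np.empty(0, dtype=int),
        confounder_set=conf if conf is not None else np.empty(0, dtype=int),
        gamma=gamma.gamma,
        eta=eta,
        replicate_seed=seed,
    )
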