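"""Reference differential-abundance tests, rare-taxon filters, method registry.

The bundled reference procedure is the Wilcoxon rank-sum test applied to
additive-log-ratio (alr) transformed counts: a pseudocount (0.5 or 1) is
added to every count, each taxon's counts are log-ratioed against a fixed
reference taxon -- the most abundant *null* taxon, which is known in
simulated data -- and a two-sided rank-sum test of the binary trait is run
per taxon, followed by Benjamini-Hochberg adjustment at a nominal FDR level
(default 20%).  Taxa present (count > 0) in fewer than a stated fraction of
samples are filtered out beforehand.

External compositional methods (LOCOM, ANCOM, ANCOM-BC, fastANCOM, ALDEx2,
DACOMP, WRENCH, LinDA) are not reimplemented; they plug in through the
method registry via the same callable contract as the bundled tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FilterSpec",
    "TestResult",
    "filter_rare_taxa",
    "alr_transform",
    "choose_reference_taxon",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "run_wilcox_alr",
    "register_method",
    "get_method",
    "registered_methods",
]


@dataclass(frozen=True)
class FilterSpec:
    """Presence filter: keep taxa observed in >= presence_fraction of samples.

    0.20 is the stringent cutoff recommended for LOCOM-style analyses; 0.10
    matches the laxer filter several methods apply by default.
    """

    presence_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.presence_fraction <= 1.0:
            raise ValueError("presence_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class TestResult:
    """Per-taxon p/q-values and the detected set for one method on one dataset."""

    taxon_ids: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    detected: np.ndarray
    method_name: str
    nominal_level: float = 0.20
    reference_taxon: int | None = None

    def __post_init__(self) -> None:
        for name in ("taxon_ids", "detected"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("p_values", "q_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.isin(self.detected, self.taxon_ids)):
            raise ValueError("detected taxa must be a subset of the tested taxa")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: taxon, p, q, detected flag, method, level."""
        return pd.DataFrame(
            {
                "taxon": self.taxon_ids,
                "p_value": self.p_values,
                "q_value": self.q_values,
                "detected": np.isin(self.taxon_ids, self.detected),
                "method": self.method_name,
                "level": self.nominal_level,
            }
        )


def filter_rare_taxa(counts: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Indices of taxa present (count > 0) in at least the stated fraction of samples."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    presence = (counts > 0).mean(axis=0)
    kept = np.flatnonzero(presence >= spec.presence_fraction)
    if kept.size == 0:
        raise ValueError("presence filter removed every taxon")
    return kept


def choose_reference_taxon(
    counts: np.ndarray, kept: np.ndarray, null_mask: np.ndarray
) -> int:
    """Most abundant null (non-causal) taxon among the kept taxa.

    Abundance is the mean within-sample relative abundance; ties break to the
    lowest taxon index.  Raises if no null taxon survived the filter.
    """
    counts = np.asarray(counts, dtype=float)
    kept = np.asarray(kept, dtype=int)
    null_mask = np.asarray(null_mask, dtype=bool)
    candidates = kept[null_mask[kept]]
    if candidates.size == 0:
        raise ValueError("no null taxon among the kept taxa to use as reference")
    rel = counts / counts.sum(axis=1, keepdims=True)
    mean_rel = rel[:, candidates].mean(axis=0)
    return int(candidates[np.argmax(mean_rel)])  # argmax keeps the lowest index on ties


def alr_transform(
    counts: np.ndarray, pseudocount: float, reference_taxon: int
) -> np.ndarray:
    """Additive log-ratio transform against a fixed reference taxon.

    Entry (i, j) is ``log(counts[i, j] + c) - log(counts[i, ref] + c)`` for
    every taxon ``j`` other than the reference; the reference column is
    dropped, giving an n x (J-1) matrix.
    """
    counts = np.asarray(counts, dtype=float)
    J = counts.shape[1]
    if not 0 <= reference_taxon < J:
        raise ValueError("reference taxon out of range")
    logs = np.log(counts + pseudocount)
    out = logs - logs[:, [reference_taxon]]
    return np.delete(out, reference_taxon, axis=1)


def wilcoxon_rank_sum(values: np.ndarray, groups: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a binary grouping.

    Uses exact enumeration when the smaller group has at most 10 samples and
    the data are tie-free, and the normal approximation with mid-ranks,
    tie-corrected variance and continuity correction otherwise.  Data that
    are constant across all samples give p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    x1 = values[groups == 1]
    x0 = values[groups == 0]
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(values == values[0]):
        return 1.0
    has_ties = np.unique(values).size < values.size
    if min(x1.size, x0.size) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x1, x0, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _binary_groups(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T)
    levels = np.unique(T)
    if levels.size != 2 or not np.all(np.isin(levels, [0, 1])):
        raise ValueError(
            "the Wilcoxon-alr tests require a binary 0/1 trait with both groups present"
        )
    return T.astype(int)


def run_wilcox_alr(
    dataset,
    pseudocount: float = 0.5,
    filter_spec: FilterSpec = FilterSpec(0.20),
    level: float = 0.20,
) -> TestResult:
    """Run the Wilcoxon-alr reference test on one simulated dataset.

    Pipeline: presence filter -> reference = most abundant kept null taxon ->
    alr transform with the pseudocount -> per-taxon two-sided rank-sum test
    of the binary trait -> BH adjustment -> detection at q <= level.  The
    reference taxon itself is not tested (and is excluded from the result).
    """
    groups = _binary_groups(dataset.T)
    counts = np.asarray(dataset.counts)
    kept = filter_rare_taxa(counts, filter_spec)
    ref = choose_reference_taxon(counts, kept, dataset.null_mask())
    sub = counts[:, kept]
    ref_pos = int(np.flatnonzero(kept == ref)[0])
    alr = alr_transform(sub, pseudocount, ref_pos)
    tested = np.delete(kept, ref_pos)

    x1, x0 = alr[groups == 1], alr[groups == 0]
    if min(x1.shape[0], x0.shape[0]) > 10:
        # columns vectorized; same asymptotic statistic as the scalar routine
        p = np.asarray(
            stats.mannwhitneyu(
                x1, x0, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=0,
            ).pvalue,
            dtype=float,
        )
        constant = np.all(alr == alr[0, :], axis=0)
        p[constant] = 1.0
    else:
        p = np.array([wilcoxon_rank_sum(alr[:, k], groups) for k in range(alr.shape[1])])
    q = bh_adjust(p)
    detected = tested[q <= level]
    return TestResult(
        taxon_ids=tested,
        p_values=p,
        q_values=q,
        detected=detected,
        method_name=f"wilcox-alr-{ {0.5: 'half', 1.0: 'one'}.get(pseudocount, pseudocount) }",
        nominal_level=level,
        reference_taxon=ref,
    )


class DAMethod(Protocol):
    """Callable contract for a registered differential-abundance method."""

    def __call__(self, dataset, level: float, filter_spec: FilterSpec) -> TestResult: ...


_REGISTRY: dict[str, DAMethod] = {}


def register_method(name: str, fn: DAMethod, *, overwrite: bool = False) -> None:
    """Register a method under a unique name for use in evaluation grids."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"method {name!r} is already registered")
    _REGISTRY[name] = fn


def get_method(name: str) -> DAMethod:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; registered methods: {sorted(_REGISTRY)}"
        ) from None


def registered_methods() -> list[str]:
    return sorted(_REGISTRY)


def _wilcox_half(dataset, level: float, filter_spec: FilterSpec) -> TestResult:
    return run_wilcox_alr(dataset, 0.5, filter_spec, level)


def _wilcox_one(dataset, level: float, filter_spec: FilterSpec) -> TestResult:
    return run_wilcox_alr(dataset, 1.0, filter_spec, level)


register_method("wilcox-alr-half", _wilcox_half)
register_method("wilcox-alr-one", _wilcox_one)
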