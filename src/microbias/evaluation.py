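"""Replicate grids, empirical FDR/sensitivity, and interaction-bias diagnostics.

A grid cell is one combination of (scenario, phi, beta); each cell is run for
a number of replicates and each registered method/filter combination is
applied to the same replicate datasets.  Per replicate, the false discovery
proportion (FDP) is the fraction of detected taxa that are not causal (0 when
nothing is detected) and the sensitivity is the fraction of truly causal taxa
detected.  The empirical FDR of a cell is the mean FDP over replicates; at
beta = 0 (the global null, no causal taxa) sensitivity is undefined and
reported as missing.

Seed discipline: replicate r of every cell uses a seed derived only from
(base_seed, r), so cells share baseline communities, traits and bias draws
(common random numbers).  Together with the per-row epsilon substreams this
makes the S-nondiff and S-diff-causal scenarios produce identical
interaction-bias fields at the null taxa of matching replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .da_tests import FilterSpec, get_method
from .simulator import (
    CommunityProfile,
    LibrarySizeModel,
    ReplicateSpec,
    StudyDesign,
    select_causal_taxa,
    select_confounder_taxa,
    simulate_replicate,
)

__all__ = [
    "ExperimentGrid",
    "EvalSummary",
    "fdp_and_sensitivity",
    "replicate_seed_for",
    "run_grid",
    "eta_diagnostics",
    "summarize_to_table",
    "plot_summary",
]

logger = logging.getLogger(__name__)

_CELL_STREAM, _REPLICATE_STREAM = 0, 1


@dataclass(frozen=True)
class ExperimentGrid:
    """Specification of a replicate grid over (scenario, phi, beta) cells."""

    profile: CommunityProfile
    design: StudyDesign = field(default_factory=StudyDesign)
    scheme: str = "M1"
    phi_values: tuple[float, ...] = (0.0, 0.612, 1.0, 2.0, 4.0)
    beta_values: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    scenarios: tuple[str, ...] = ("S-nondiff",)
    sigma_gamma: float = 0.8
    library: LibrarySizeModel = field(default_factory=LibrarySizeModel)
    replicates: int = 200
    base_seed: int = 0
    methods: tuple[str, ...] = ("wilcox-alr-half",)
    filters: dict | None = None  # method name -> FilterSpec; default 20% presence
    nominal_level: float = 0.20
    redraw_causal_per_replicate: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def filter_for(self, method: str) -> FilterSpec:
        if self.filters and method in self.filters:
            return self.filters[method]
        return FilterSpec(0.20)


@dataclass(frozen=True)
class EvalSummary:
    """Long-format per-cell, per-method summary of a grid run."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EvalSummary":
        return cls(pd.read_csv(path, sep="\t"))


def fdp_and_sensitivity(
    detected, causal, tested
) -> tuple[float, float]:
    """False discovery proportion and sensitivity for one replicate.

    FDP is 0 when nothing is detected; sensitivity is NaN when there are no
    causal taxa (the global null), so that cell averages do not mix an
    undefined quantity with zeros.
    """
    detected = set(np.asarray(detected, dtype=int).ravel())
    causal = set(np.asarray(causal, dtype=int).ravel())
    tested = set(np.asarray(tested, dtype=int).ravel())
    if not detected <= tested:
        raise ValueError("detected taxa must be a subset of tested taxa")
    fdp = len(detected - causal) / len(detected) if detected else 0.0
    sens = len(detected & causal) / len(causal) if causal else float("nan")
    return fdp, sens


def replicate_seed_for(base_seed: int, r: int) -> int:
    """Deterministic per-replicate seed shared by all grid cells."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(_REPLICATE_STREAM, r))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _grid_truth_sets(grid: ExperimentGrid) -> tuple[np.ndarray, np.ndarray | None]:
    """Causal and confounder sets, drawn once per grid from the cell stream."""
    rng = np.random.default_rng(
        np.random.SeedSequence(grid.base_seed, spawn_key=(_CELL_STREAM,))
    )
    causal = select_causal_taxa(grid.profile, grid.scheme, rng)
    conf = None
    if grid.design.confounded:
        null_pool = np.setdiff1d(np.arange(grid.profile.n_taxa), causal)
        conf = select_confounder_taxa(causal, null_pool, grid.scheme, rng)
    return causal, conf


def run_grid(grid: ExperimentGrid) -> EvalSummary:
    """Run every (scenario, phi, beta) cell and aggregate FDR/sensitivity.

    Replicates that raise inside a method adapter are logged and excluded
    from that method's averages; the replicate counts actually used are
    reported per cell.
    """
    causal, conf = _grid_truth_sets(grid)
    methods = {m: (get_method(m), grid.filter_for(m)) for m in grid.methods}
    rows = []
    for scenario in grid.scenarios:
        for phi in grid.phi_values:
            for beta in grid.beta_values:
                acc = {m: {"fdp": [], "sens": [], "ndet": []} for m in methods}
                for r in range(grid.replicates):
                    seed = replicate_seed_for(grid.base_seed, r)
                    spec = ReplicateSpec(
                        profile=grid.profile,
                        design=grid.design,
                        scheme=grid.scheme,
                        beta=beta,
                        sigma_gamma=grid.sigma_gamma,
                        phi=phi,
                        scenario=scenario,
                        library=grid.library,
                        causal_set=None if grid.redraw_causal_per_replicate else causal,
                        confounder_set=None if grid.redraw_causal_per_replicate else conf,
                    )
                    ds = simulate_replicate(spec, seed)
                    for name, (fn, fspec) in methods.items():
                        try:
                            res = fn(ds, level=grid.nominal_level, filter_spec=fspec)
                        except Exception:
                            logger.exception(
                                "method %s failed on replicate %d of cell "
                                "(scenario=%s, phi=%g, beta=%g); excluding it",
                                name, r, scenario, phi, beta,
                            )
                            continue
                        fdp, sens = fdp_and_sensitivity(
                            res.detected, ds.causal_set, res.taxon_ids
                        )
                        acc[name]["fdp"].append(fdp)
                        acc[name]["sens"].append(sens)
                        acc[name]["ndet"].append(res.detected.size)
                for name in methods:
                    a = acc[name]
                    n_used = len(a["fdp"])
                    sens_arr = np.asarray(a["sens"], dtype=float)
                    rows.append(
                        {
                            "scenario": scenario,
                            "scheme": grid.scheme,
                            "phi": phi,
                            "beta": beta,
                            "method": name,
                            "filter": methods[name][1].presence_fraction,
                            "empirical_fdr": float(np.mean(a["fdp"])) if n_used else float("nan"),
                            "sensitivity": float(np.nanmean(sens_arr))
                            if n_used and not np.all(np.isnan(sens_arr))
                            else float("nan"),
                            "mean_detected": float(np.mean(a["ndet"])) if n_used else float("nan"),
                            "n_replicates_used": n_used,
                        }
                    )
    return EvalSummary(pd.DataFrame(rows))


def eta_diagnostics(datasets) -> pd.DataFrame:
    """Per-taxon summary of the interaction-bias field across replicates.

    Returns one row per taxon with the pooled mean and variance of eta over
    all samples and replicates, and the mean |gamma| of the taxon.  Under the
    generating model the pooled mean is near zero (contributions of both
    signs average out) while the variance grows with |gamma| at fixed phi.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    eta = np.concatenate([ds.eta for ds in datasets], axis=0)
    abs_gamma = np.mean([np.abs(ds.gamma) for ds in datasets], axis=0)
    return pd.DataFrame(
        {
            "taxon": np.arange(eta.shape[1]),
            "mean_eta": eta.mean(axis=0),
            "var_eta": eta.var(axis=0),
            "abs_gamma": abs_gamma,
        }
    )


def summarize_to_table(summary: EvalSummary) -> pd.DataFrame:
    """Long-format report keyed by (scenario, scheme, phi, beta, method, filter)."""
    if summary.table.empty:
        raise ValueError("summary is empty")
    key = ["scenario", "scheme", "phi", "beta", "method", "filter"]
    if summary.table.duplicated(subset=key).any():
        raise ValueError("summary rows are not unique on the cell/method key")
    return summary.table.loc[
        :, key + ["empirical_fdr", "sensitivity", "mean_detected", "n_replicates_used"]
    ].copy()


def plot_summary(summary: EvalSummary, out_path) -> None:
    """FDR and sensitivity vs beta, one panel column per phi, rows per metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = summary.table
    phis = sorted(tab["phi"].unique())
    fig, axes = plt.subplots(
        2, len(phis), figsize=(3.2 * len(phis), 6), squeeze=False, sharey="row"
    )
    for col, phi in enumerate(phis):
        sub = tab[tab["phi"] == phi]
        for method, ms in sub.groupby("method"):
            ms = ms.sort_values("beta")
            axes[0][col].plot(ms["beta"], ms["empirical_fdr"], marker="o", label=method)
            axes[1][col].plot(ms["beta"], ms["sensitivity"], marker="o", label=method)
        axes[0][col].axhline(0.2, ls=":", c="k", lw=1)
        axes[0][col].set_title(f"phi = {phi:g}")
        axes[1][col].set_xlabel("beta")
    axes[0][0].set_ylabel("empirical FDR")
    axes[1][0].set_ylabel("sensitivity")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
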