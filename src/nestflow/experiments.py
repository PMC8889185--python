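"""End-to-end experiment orchestration and condition summaries.

Three experiments cover the pipeline:

i.   *Condition vs triangle transitivity*: for each behavioural condition a
     batch of simulations is run; each run is assigned one target network
     density from the 150..1500 schedule (blocked assignment: consecutive
     runs share a target), its log is grown to that density and ``t_tri`` is
     recorded.
ii.  *Activity decomposition*: uniform and activity-variable populations are
     crossed with four interaction rule variants — initiation by activity or
     by fair coin, direction by activity or by fair coin — a 2 x 2 factorial
     of initiation and direction mechanisms. Networks are built at a fixed
     1000 edges.
iii. *Information diffusion*: time-ordered diffusion over the logs of each
     condition, with 20% of interactions removed beforehand in conditions
     whose activity levels are uniform.

Because every cell of these designs is balanced and simulated i.i.d., plain
cell means, mean contrasts against the uniform reference cell, and ordinary
least-squares fits estimate the condition effects directly; ``nestflow``
reports those instead of variance-weighted regression coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .abm import DirectionRule, InitiationRule, SimConfig, run_simulation
from .diffusion import run_diffusion_experiment
from .errors import ConfigurationError, DensityNotReachedError
from .motifs import TriadCensus, triangle_census, triangle_transitivity
from .netbuild import DENSITY_TARGETS, grow_to_density
from .traits import Condition

__all__ = [
    "ALL_CONDITIONS",
    "EXPERIMENT_II_VARIANTS",
    "ExperimentPlan",
    "derive_seed",
    "run_experiment_i",
    "run_experiment_ii",
    "run_experiment_iii",
    "make_null_ensemble",
    "summarize_contrasts",
    "fit_condition_density_ols",
    "interaction_contrast",
]

ALL_CONDITIONS: tuple[Condition, ...] = tuple(Condition)

#: The four interaction rule variants of the activity-decomposition
#: experiment, as (initiation label, direction label, rules) records.
#: "activity"-determined direction means the initiator signals when
#: initiation is gated by activity, and relative-activity-weighted direction
#: when initiation is a fair coin.
EXPERIMENT_II_VARIANTS: tuple[tuple[str, str, InitiationRule, DirectionRule], ...] = (
    ("activity", "activity", InitiationRule.BY_ACTIVITY, DirectionRule.ACTIVE_OUTGOING),
    ("activity", "random", InitiationRule.BY_ACTIVITY, DirectionRule.RANDOM),
    ("random", "activity", InitiationRule.RANDOM_HALF, DirectionRule.RELATIVE_ACTIVITY),
    ("random", "random", InitiationRule.RANDOM_HALF, DirectionRule.RANDOM),
)


@dataclass(frozen=True)
class ExperimentPlan:
    """Replication plan for one experiment."""

    experiment: str  # "conditions_vs_ttri" | "activity_decomposition" | "diffusion"
    n_runs: int = 100
    master_seed: int = 0
    target_edges: int = 1000
    density_targets: tuple[int, ...] = DENSITY_TARGETS

    def __post_init__(self) -> None:
        if self.experiment not in (
            "conditions_vs_ttri", "activity_decomposition", "diffusion",
        ):
            raise ConfigurationError(f"unknown experiment {self.experiment!r}")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")


def derive_seed(master_seed: int, *key: int) -> int:
    """Counter-based per-run seed derivation.

    Any single run can be re-created in isolation from the master seed and
    its (experiment, cell, run, retry) coordinates; results are recorded
    alongside the derived seed.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _density_for_run(run: int, n_runs: int, targets: Sequence[int]) -> int:
    """Blocked run-to-density assignment: runs 0..b-1 get the first target,
    the next block the second, and so on (b = n_runs / len(targets))."""
    return targets[run * len(targets) // n_runs]


def _ttri_run(
    config: SimConfig,
    target_edges: int,
    master_seed: int,
    key: tuple[int, ...],
    max_retries: int = 5,
) -> dict:
    """One simulate -> grow-to-density -> census run, with fresh-seed retries
    when the log cannot support the target density."""
    last: DensityNotReachedError | None = None
    for retry in range(max_retries + 1):
        seed = derive_seed(master_seed, *key, retry)
        cfg = config.with_(seed=seed)
        log = run_simulation(cfg)
        try:
            net = grow_to_density(log, target_edges)
        except DensityNotReachedError as err:
            last = err
            continue
        census = triangle_census(net)
        tt = triangle_transitivity(census)
        return {
            "seed": seed,
            "retries": retry,
            "n_events": len(log),
            "t_end": net.t_end,
            "n_edges": net.n_edges(),
            "census": census,
            "n_transitive": tt.n_transitive,
            "n_cyclic": tt.n_cyclic,
            "p_t": tt.p_t,
            "t_tri": tt.t_tri,
        }
    raise DensityNotReachedError(target_edges, last.achieved if last else 0)


def run_experiment(plan: ExperimentPlan) -> pd.DataFrame:
    """Execute a full experiment matrix described by an :class:`ExperimentPlan`."""
    if plan.experiment == "conditions_vs_ttri":
        return run_experiment_i(
            n_runs=plan.n_runs,
            master_seed=plan.master_seed,
            density_targets=plan.density_targets,
        )
    if plan.experiment == "activity_decomposition":
        return run_experiment_ii(
            n_runs=plan.n_runs,
            master_seed=plan.master_seed,
            target_edges=plan.target_edges,
        )
    return run_experiment_iii(n_runs=plan.n_runs, master_seed=plan.master_seed)


def run_experiment_i(
    conditions: Iterable[Condition | str] = ALL_CONDITIONS,
    n_runs: int = 100,
    master_seed: int = 0,
    density_targets: Sequence[int] = DENSITY_TARGETS,
    config_overrides: dict | None = None,
    keep_census: bool = False,
) -> pd.DataFrame:
    """Condition-vs-transitivity experiment; one binary network per run.

    Returns a tidy table with one row per run: condition, density target,
    achieved window, triangle counts and ``t_tri``, plus the standardised
    density ``z_density`` used by the OLS summary.
    """
    overrides = dict(config_overrides or {})
    rows = []
    for ci, cond in enumerate(Condition(c) for c in conditions):
        for run in range(n_runs):
            target = _density_for_run(run, n_runs, density_targets)
            config = SimConfig(condition=cond, **overrides)
            rec = _ttri_run(config, target, master_seed, (1, ci, run))
            if not keep_census:
                rec.pop("census")
            rows.append(
                {"condition": cond.value, "run": run, "density": target, **rec}
            )
    df = pd.DataFrame(rows)
    sd = df["density"].std(ddof=1)
    df["z_density"] = (df["density"] - df["density"].mean()) / (sd if sd > 0 else 1.0)
    return df


def run_experiment_ii(
    conditions: Iterable[Condition | str] = (
        Condition.UNIFORM, Condition.ACTIVITY_VARIABLE,
    ),
    variants: Sequence[tuple[str, str, InitiationRule, DirectionRule]] = EXPERIMENT_II_VARIANTS,
    n_runs: int = 100,
    master_seed: int = 0,
    target_edges: int = 1000,
    config_overrides: dict | None = None,
    keep_census: bool = False,
) -> pd.DataFrame:
    """Activity-decomposition experiment at a fixed network density.

    One row per run with the cell labels ``condition``, ``initiation``
    ("activity"/"random") and ``direction`` ("activity"/"random").
    """
    overrides = dict(config_overrides or {})
    rows = []
    for ci, cond in enumerate(Condition(c) for c in conditions):
        for vi, (init_label, dir_label, init_rule, dir_rule) in enumerate(variants):
            config = SimConfig(
                condition=cond,
                initiation_rule=init_rule,
                direction_rule=dir_rule,
                **overrides,
            )
            for run in range(n_runs):
                rec = _ttri_run(config, target_edges, master_seed, (2, ci, vi, run))
                if not keep_census:
                    rec.pop("census")
                rows.append(
                    {
                        "condition": cond.value,
                        "initiation": init_label,
                        "direction": dir_label,
                        "run": run,
                        **rec,
                    }
                )
    return pd.DataFrame(rows)


def run_experiment_iii(
    conditions: Iterable[Condition | str] = ALL_CONDITIONS,
    n_runs: int = 100,
    master_seed: int = 0,
    thin_fraction: float = 0.2,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Information-diffusion experiment across behavioural conditions."""
    frames = [
        run_diffusion_experiment(
            cond,
            n_runs,
            config_overrides=config_overrides,
            master_seed=master_seed,
            thin_fraction=thin_fraction,
        )
        for cond in conditions
    ]
    return pd.concat(frames, ignore_index=True)


def make_null_ensemble(
    n_networks: int,
    config: SimConfig | None = None,
    target_edges: int = 1000,
    master_seed: int = 0,
    max_retries: int = 5,
) -> list[TriadCensus]:
    """Triangle censuses of independent uniform-condition networks.

    The uniform condition — identical mean activity and turning across
    agents, moving in the same bounded nest — is the spatially explicit null
    against which motif over-representation is judged; the ensemble is
    matched to the observed networks in size and density.
    """
    if n_networks < 2:
        raise ConfigurationError("an ensemble needs at least 2 networks")
    config = config or SimConfig()
    out = []
    for k in range(n_networks):
        rec = _ttri_run(config, target_edges, master_seed, (0, k), max_retries)
        out.append(rec["census"])
    return out


def summarize_contrasts(
    per_run: pd.DataFrame,
    value: str,
    cell_cols: Sequence[str],
    reference: dict[str, str],
) -> pd.DataFrame:
    """Cell means, sds and mean differences against a reference cell.

    Rows with a missing value (undefined ``t_tri`` or unreached ``T50``) are
    excluded from the means; their count is reported per cell as ``n_undefined``.
    """
    cell_cols = list(cell_cols)
    missing = [c for c in cell_cols if c not in per_run.columns]
    if missing:
        raise ConfigurationError(f"missing cell columns {missing}")
    g = per_run.groupby(cell_cols, sort=False)[value]
    summary = g.agg(mean="mean", sd="std", n="count").reset_index()
    summary["n_undefined"] = (
        g.apply(lambda s: int(s.isna().sum())).to_numpy()
    )
    ref_mask = np.ones(len(summary), dtype=bool)
    for col, val in reference.items():
        ref_mask &= summary[col] == val
    if ref_mask.sum() != 1:
        raise ConfigurationError(
            f"reference {reference} matches {int(ref_mask.sum())} cells, expected 1"
        )
    ref_mean = float(summary.loc[ref_mask, "mean"].iloc[0])
    summary["contrast"] = summary["mean"] - ref_mean
    return summary


def fit_condition_density_ols(per_run: pd.DataFrame, value: str = "t_tri"):
    """OLS of the response on condition, standardised density and their
    interaction, with the uniform condition as the treatment reference.

    On the balanced simulated design these coefficients estimate the same
    condition contrasts as variance-weighted alternatives.
    """
    import statsmodels.formula.api as smf

    df = per_run.dropna(subset=[value]).copy()
    formula = (
        f"{value} ~ C(condition, Treatment(reference='uniform')) * z_density"
    )
    return smf.ols(formula, data=df).fit()


def interaction_contrast(
    per_run: pd.DataFrame,
    value: str = "t_tri",
    factor_a: str = "condition",
    a_level: str = "activity_variable",
    a_ref: str = "uniform",
    factor_b: str = "direction",
    b_level: str = "random",
    b_ref: str = "activity",
    within: dict[str, str] | None = None,
) -> float:
    """Two-factor interaction as the difference of differences of cell means:
    (m[a1,b1] - m[a1,b0]) - (m[a0,b1] - m[a0,b0])."""
    df = per_run
    for col, val in (within or {}).items():
        df = df[df[col] == val]

    def cell(a, b):
        sel = df[(df[factor_a] == a) & (df[factor_b] == b)][value].dropna()
        if sel.empty:
            raise ConfigurationError(f"empty cell ({a}, {b})")
        return float(sel.mean())

    return (cell(a_level, b_level) - cell(a_level, b_ref)) - (
        cell(a_ref, b_level) - cell(a_ref, b_ref)
    )
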