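"""Parameter-sensitivity machinery.

A random design samples parameter combinations uniformly within declared
ranges, appends a dummy noise parameter (uniform in {1, 2, 3}, never passed
to the simulator), runs replicate simulations of the two-phase protocol per
combination, and summarises each combination by the fraction of replicates
in which phage survive (free particles or prophages in living cells).  A
random-forest regressor of the response on the parameters then ranks them by
permutation importance (%IncMSE): the percentage increase in out-of-bag mean
squared error when a parameter's values are randomly permuted.  The dummy
parameter provides the noise floor.

Also provides the survival heatmaps over a p_gt grid crossed with genome
size, burst size, or lysate sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core import InvalidParameterError
from .lattice import OutcomeSummary, SimulationParams
from .scenarios import ScenarioConfig, run_two_phase, scenario_config

__all__ = [
    "ParamRange",
    "DEFAULT_RANGES",
    "ParameterDesign",
    "sample_parameter_designs",
    "response_phage_survival",
    "run_design",
    "rfa_importance",
    "rfa_pipeline",
    "sweep_heatmap",
    "DEFAULT_P_GT_GRID",
    "DEFAULT_AXIS_LEVELS",
]


@dataclass(frozen=True)
class ParamRange:
    """A continuous interval, an integer interval, or categorical levels."""

    lo: float = 0.0
    hi: float = 0.0
    integer: bool = False
    levels: Optional[tuple[float, ...]] = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.levels is not None:
            if not len(self.levels):
                raise InvalidParameterError("empty categorical level set")
            return rng.choice(np.asarray(self.levels, dtype=float), size=n)
        if self.hi < self.lo:
            raise InvalidParameterError(f"empty range [{self.lo}, {self.hi}]")
        if self.integer:
            return rng.integers(int(self.lo), int(self.hi) + 1, size=n)
        return rng.uniform(self.lo, self.hi, size=n)


#: ranges explored by the default design.  Phage-biology parameters span
#: their full off-to-strong regimes; environment-level rates vary around
#: their calibrated defaults so that the protocol itself stays functional
#: (the lysate is neither exhausted before sampling nor undeliverable) and
#: the analysis probes the biology rather than the plumbing.  The decay
#: range keeps free virions from persisting to the 100-iteration horizon
#: without hosts, so "phage survival" means lysogenic persistence rather
#: than inert particles.  Donor genome size is not part of the default
#: design; it is the extra axis of the survival heatmaps.
DEFAULT_RANGES: dict[str, ParamRange] = {
    "p_gt": ParamRange(0.0, 0.3),
    # lysogenization propensity takes named levels (none / middle / high):
    # the response saturates in p_lys away from zero, so a continuous column
    # would carry almost no variance
    "p_lys": ParamRange(levels=(0.0, 0.4, 0.8)),
    "burst_size": ParamRange(10, 100, integer=True),
    "n_sample": ParamRange(200, 1000, integer=True),
    "p_ads": ParamRange(0.2, 0.4),
    "p_decay": ParamRange(0.15, 0.25),
    "antibiotic_iteration": ParamRange(3, 15, integer=True),
}

DUMMY_LEVELS = (1, 2, 3)


@dataclass
class ParameterDesign:
    """Random parameter combinations plus the dummy noise column."""

    rows: pd.DataFrame  # one column per parameter, plus "dummy"
    n_reps: int
    seed: int

    @property
    def n_combos(self) -> int:
        return len(self.rows)

    @property
    def parameter_names(self) -> list[str]:
        return [c for c in self.rows.columns]


def sample_parameter_designs(
    ranges: Mapping[str, ParamRange],
    n_combos: int,
    n_reps: int,
    rng: np.random.Generator | int,
    seed_label: int = 0,
) -> ParameterDesign:
    """Sample ``n_combos`` parameter combinations uniformly within ``ranges``
    and append the dummy column (uniform in {1, 2, 3})."""
    if not ranges:
        raise InvalidParameterError("at least one parameter range is required")
    if isinstance(rng, (int, np.integer)):
        seed_label = int(rng)
        rng = np.random.default_rng(rng)
    cols = {name: r.sample(rng, n_combos) for name, r in ranges.items()}
    cols["dummy"] = rng.choice(DUMMY_LEVELS, size=n_combos)
    return ParameterDesign(rows=pd.DataFrame(cols), n_reps=n_reps, seed=seed_label)


def response_phage_survival(outcomes: Sequence[OutcomeSummary]) -> float:
    """Fraction of replicates in which phage are found alive at the end
    (free functional particles or prophages in living bacteria)."""
    if not len(outcomes):
        raise InvalidParameterError("empty outcome list")
    return sum(o.phage_survived for o in outcomes) / len(outcomes)


def _config_for_row(base: ScenarioConfig, row: Mapping[str, float]) -> ScenarioConfig:
    """Apply one design row to the base scenario configuration.  The dummy
    column is deliberately ignored: it must have no effect on any simulation."""
    kwargs: dict = {}
    params = base.params
    for name, value in row.items():
        if name == "dummy":
            continue
        elif name == "p_gt":
            kwargs["p_gt"] = float(value)
        elif name == "p_lys":
            kwargs["p_lys"] = float(value)
        elif name == "burst_size":
            kwargs["burst_size"] = int(value)
        elif name == "n_sample":
            kwargs["n_sample"] = int(value)
        elif name == "genome_size":
            kwargs["donor_genome_size"] = int(value)
        elif name == "antibiotic_iteration":
            kwargs["phase2_antibiotic_iteration"] = int(value)
        elif name == "p_ads":
            params = replace(params, p_ads=float(value))
        elif name == "p_decay":
            params = replace(params, p_decay=float(value))
        else:
            raise InvalidParameterError(f"unknown design parameter {name!r}")
    return replace(base, params=params, **kwargs)


def run_design(
    design: ParameterDesign,
    master_seed: int,
    base_config: Optional[ScenarioConfig] = None,
) -> np.ndarray:
    """Run the design: per row, ``n_reps`` replicate two-phase simulations;
    the response is the phage-survival fraction."""
    if base_config is None:
        base_config = scenario_config("S1_temperate_GT", width=30, height=30)
    responses = np.empty(design.n_combos)
    for i, row in enumerate(design.rows.to_dict("records")):
        cfg = _config_for_row(base_config, row)
        outcomes = []
        for k in range(design.n_reps):
            rng = np.random.default_rng(np.random.SeedSequence([master_seed, i, k]))
            outcomes.append(run_two_phase(cfg, rng, record=False).outcome)
        responses[i] = response_phage_survival(outcomes)
    return responses


def rfa_importance(
    design: ParameterDesign,
    responses: np.ndarray,
    n_trees: int = 10_000,
    random_state: int = 0,
) -> pd.DataFrame:
    """Random-forest permutation importance of each parameter (and the dummy).

    Fits a random-forest regressor of the response on the design columns and
    computes %IncMSE: for every tree, the mean squared error on its
    out-of-bag rows is compared with the error after randomly permuting one
    column within those rows; the per-tree increases are averaged and
    expressed as a percentage of the baseline out-of-bag error.  Returns a
    table sorted by decreasing importance with columns
    ``parameter, importance_pct_inc_mse, rank``.
    """
    X = design.rows.to_numpy(dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(y) != len(X):
        raise InvalidParameterError("one response per design row is required")
    if np.allclose(y, y[0]):
        warnings.warn("constant response: all importances will be ~0", stacklevel=2)
    n, p = X.shape
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, p // 3),  # regression-forest convention
        bootstrap=True,
        n_jobs=1,
        random_state=random_state,
    )
    forest.fit(X, y)
    rng = np.random.default_rng(random_state)
    base_sum = 0.0
    perm_sum = np.zeros(p)
    n_unsampled = 0
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        m = int(oob.sum())
        if m == 0:
            n_unsampled += 1
            continue
        Xo = X[oob]
        yo = y[oob]
        pred = est.predict(Xo)
        base = float(np.mean((yo - pred) ** 2))
        base_sum += base
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(m), j]
            perm = est.predict(Xp)
            perm_sum[j] += float(np.mean((yo - perm) ** 2))
    n_used = n_trees - n_unsampled
    base_mse = base_sum / n_used
    perm_mse = perm_sum / n_used
    if base_mse == 0.0:
        pct = np.zeros(p)
    else:
        pct = 100.0 * (perm_mse - base_mse) / base_mse
    table = pd.DataFrame(
        {"parameter": design.parameter_names, "importance_pct_inc_mse": pct}
    ).sort_values("importance_pct_inc_mse", ascending=False, ignore_index=True)
    table["rank"] = np.arange(1, p + 1)
    return table


def rfa_pipeline(
    n_combos: int = 300,
    n_reps: int = 10,
    n_trees: int = 10_000,
    master_seed: int = 0,
    ranges: Optional[Mapping[str, ParamRange]] = None,
    base_config: Optional[ScenarioConfig] = None,
) -> tuple[ParameterDesign, np.ndarray, pd.DataFrame]:
    """Design -> simulations -> importance table, all seeded from one master
    seed.  Defaults are the desk-scale design (300 x 10 on a 30x30 lattice);
    the full-scale 5000 x 20 design is the same call with larger arguments."""
    ranges = dict(ranges or DEFAULT_RANGES)
    design = sample_parameter_designs(
        ranges, n_combos, n_reps, np.random.default_rng(master_seed), master_seed
    )
    responses = run_design(design, master_seed, base_config)
    importance = rfa_importance(design, responses, n_trees, random_state=master_seed)
    return design, responses, importance


# ---------------------------------------------------------------------------
# survival heatmaps
# ---------------------------------------------------------------------------

DEFAULT_P_GT_GRID: tuple[float, ...] = (0.0, 0.02, 0.05, 0.1, 0.2)

#: heatmap axis levels, spanning each mechanism's active region: marker
#: capture falls as headful/genome_size; at low burst sizes the phase-1
#: lysate is smaller than the 500-virion sample, so fewer transducing
#: particles reach phase 2; tiny samples are unlikely to contain a
#: marker-bearing particle at all, large ones saturate.
DEFAULT_AXIS_LEVELS: dict[str, tuple[int, ...]] = {
    "genome_size": (50, 150, 400, 1000, 2400),
    "burst_size": (2, 5, 15, 50, 150),
    "n_sample": (10, 50, 150, 500, 1000),
}


def sweep_heatmap(
    p_gt_grid: Sequence[float],
    axis: str,
    axis_levels: Sequence[int],
    n_reps: int,
    master_seed: int,
    base_config: Optional[ScenarioConfig] = None,
) -> pd.DataFrame:
    """Joint bacteria+phage survival fraction of the two-phase protocol over
    a p_gt x axis grid (axis one of genome_size / burst_size / n_sample).

    In the surviving regime bacterial and phage survival coincide (survivors
    are resistant lysogens), so the joint fraction is reported.  Returns a
    DataFrame indexed by p_gt with one column per axis level.
    """
    if axis not in DEFAULT_AXIS_LEVELS:
        raise InvalidParameterError(
            f"axis must be one of {tuple(DEFAULT_AXIS_LEVELS)}, got {axis!r}"
        )
    if not len(p_gt_grid) or not len(axis_levels):
        raise InvalidParameterError("grids must be nonempty")
    if base_config is None:
        # the heatmaps run at the reference scenario scale: on smaller
        # lattices the phase-1 lysate shrinks below the sample sizes being
        # compared and the sample-size axis cannot reach its plateau
        base_config = scenario_config("S1_temperate_GT")
    out = np.empty((len(p_gt_grid), len(axis_levels)))
    for i, p_gt in enumerate(p_gt_grid):
        for j, level in enumerate(axis_levels):
            cfg = _config_for_row(base_config, {"p_gt": p_gt, axis: level})
            survived = 0
            for k in range(n_reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence([master_seed, i, j, k])
                )
                o = run_two_phase(cfg, rng, record=False).outcome
                survived += o.joint_survival
            out[i, j] = survived / n_reps
    df = pd.DataFrame(out, index=list(p_gt_grid), columns=list(axis_levels))
    df.index.name = "p_gt"
    df.columns.name = axis
    return df
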