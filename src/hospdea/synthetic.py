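"""Synthetic hospital-panel generator with a known frontier and known effects.

The generator emulates the structure of a two-group survey of maternal and
child health hospitals: a district group (33 units) and a county group (84
units), five inputs, four outputs and six environmental covariates at
realistic scales.  The data-generating process mirrors the second-stage
estimating model so that every stage of the pipeline has recoverable ground
truth:

* inputs ``x`` and covariates ``z`` are drawn from per-group normal scales,
  floored at a small positive value (all quantities are physically
  nonnegative);
* the frontier is Cobb-Douglas, ``g_m(x) = c_m * prod_k x_k^alpha_k`` with
  ``alpha_k >= 0`` and ``sum alpha_k <= 1``;
* the Farrell inefficiency is ``delta_i = z~_i . beta + eps_i`` with
  ``eps ~ N(0, sigma^2)`` left-truncated so that ``delta_i >= 1`` (``z~`` are
  the covariates standardised by their configured scales, intercept first);
* observed outputs are the frontier outputs deflated by the inefficiency,
  ``y_i = g(x_i) / delta_i``.

The true ``delta_i`` is stored on the panel for recovery tests but is never
read by the estimation path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import DMUPanel

__all__ = [
    "SyntheticConfig",
    "simulate_panel",
    "default_table2_config",
    "coverage_benchmark_config",
    "recovery_benchmark_config",
    "standardize_covariates",
]

logger = logging.getLogger(__name__)

#: negative draws of inputs/covariates are floored at this fraction of their mean
FLOOR_FRACTION = 1e-6


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


def _as_group_dict(value, groups, shape, what):
    """Normalise shared-or-per-group parameters to a dict keyed by group."""
    if isinstance(value, dict):
        out = {g: np.asarray(value[g], dtype=float) for g in groups}
    else:
        arr = np.asarray(value, dtype=float)
        out = {g: arr.copy() for g in groups}
    for g, arr in out.items():
        if arr.shape != shape:
            raise SyntheticConfigError(
                f"{what} for group {g!r} has shape {arr.shape}, expected {shape}"
            )
    return out


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic DMU-panel generator.

    ``input_scales`` and ``covariate_scales`` are (mean, sd) pairs, either
    shared across groups or a dict keyed by group label.  ``output_multipliers``
    are the per-output Cobb-Douglas constants ``c_m`` (again shared or
    per-group; per-group multipliers give each group its own frontier, the
    ``pooled_frontier`` flag overrides them with their across-group mean).
    ``covariate_effects`` is the inefficiency coefficient vector on the
    standardised-covariate scale, intercept first, in Farrell units (positive
    values increase inefficiency).
    """

    n_per_group: dict[str, int]
    n_inputs: int
    n_outputs: int
    frontier_exponents: np.ndarray
    output_multipliers: dict | np.ndarray
    covariate_effects: np.ndarray
    sigma_true: float
    input_scales: dict | np.ndarray
    covariate_scales: dict | np.ndarray | None = None
    input_names: list[str] | None = None
    output_names: list[str] | None = None
    covariate_names: list[str] | None = None
    pooled_frontier: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        groups = list(self.n_per_group)
        if not groups:
            raise SyntheticConfigError("n_per_group must name at least one group")
        p, q = int(self.n_inputs), int(self.n_outputs)
        if p < 1 or q < 1:
            raise SyntheticConfigError("need at least one input and one output")
        self.frontier_exponents = np.asarray(self.frontier_exponents, dtype=float)
        if self.frontier_exponents.shape != (p,):
            raise SyntheticConfigError("frontier_exponents must have one entry per input")
        if np.any(self.frontier_exponents < 0):
            raise SyntheticConfigError("frontier_exponents must be nonnegative")
        if self.frontier_exponents.sum() > 1 + 1e-12:
            raise SyntheticConfigError("frontier_exponents must sum to at most 1")
        if self.sigma_true < 0:
            raise SyntheticConfigError("sigma_true must be nonnegative")
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        r = self.covariate_effects.size - 1
        if r < 0:
            raise SyntheticConfigError("covariate_effects needs at least an intercept")

        self.input_scales = _as_group_dict(self.input_scales, groups, (p, 2), "input_scales")
        self.output_multipliers = _as_group_dict(
            self.output_multipliers, groups, (q,), "output_multipliers"
        )
        if r > 0:
            if self.covariate_scales is None:
                raise SyntheticConfigError("covariate_scales required with covariate effects")
            self.covariate_scales = _as_group_dict(
                self.covariate_scales, groups, (r, 2), "covariate_scales"
            )
        else:
            self.covariate_scales = None

        for g in groups:
            if int(self.n_per_group[g]) < 1:
                raise SyntheticConfigError(f"group {g!r} must have at least one unit")
            for name, scales in (
                ("input_scales", self.input_scales[g]),
                ("covariate_scales", None if r == 0 else self.covariate_scales[g]),
            ):
                if scales is None:
                    continue
                if np.any(scales[:, 0] <= 0) or np.any(scales[:, 1] <= 0):
                    raise SyntheticConfigError(
                        f"{name} for group {g!r} must be strictly positive"
                    )
            if int(self.n_per_group[g]) < p + q + 1:
                logger.warning(
                    "group %r has %d units, below the DEA dimensionality floor p+q+1=%d",
                    g, int(self.n_per_group[g]), p + q + 1,
                )

        if self.input_names is None:
            self.input_names = [f"x{k + 1}" for k in range(p)]
        if self.output_names is None:
            self.output_names = [f"y{m + 1}" for m in range(q)]
        if r > 0 and self.covariate_names is None:
            self.covariate_names = [f"z{j + 1}" for j in range(r)]

    @property
    def n_covariates(self) -> int:
        return self.covariate_effects.size - 1

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)

    def multipliers_for(self, group: str) -> np.ndarray:
        if self.pooled_frontier:
            stacked = np.stack([self.output_multipliers[g] for g in self.groups])
            return stacked.mean(axis=0)
        return self.output_multipliers[group]

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        return {
            "n_per_group": {g: int(n) for g, n in self.n_per_group.items()},
            "n_inputs": int(self.n_inputs),
            "n_outputs": int(self.n_outputs),
            "frontier_exponents": conv(self.frontier_exponents),
            "output_multipliers": conv(self.output_multipliers),
            "covariate_effects": conv(self.covariate_effects),
            "sigma_true": float(self.sigma_true),
            "input_scales": conv(self.input_scales),
            "covariate_scales": conv(self.covariate_scales),
            "input_names": self.input_names,
            "output_names": self.output_names,
            "covariate_names": self.covariate_names,
            "pooled_frontier": bool(self.pooled_frontier),
            "seed": int(self.seed),
        }


def _positive_draws(rng, means, sds, n):
    """Column-wise normal draws floored at FLOOR_FRACTION of the mean."""
    draws = rng.normal(means, sds, size=(n, means.size))
    return np.maximum(draws, FLOOR_FRACTION * means)


def simulate_panel(config: SyntheticConfig, seed: int | None = None) -> DMUPanel:
    """Generate a DMU panel from the configured data-generating process.

    The optional ``seed`` overrides ``config.seed``.  Same seed, same panel,
    bit for bit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p, q, r = config.n_inputs, config.n_outputs, config.n_covariates
    beta0, beta = config.covariate_effects[0], config.covariate_effects[1:]

    ids, groups, X_rows, Y_rows, Z_rows, delta_rows = [], [], [], [], [], []
    for g in config.groups:
        n_g = int(config.n_per_group[g])
        scales = config.input_scales[g]
        X = _positive_draws(rng, scales[:, 0], scales[:, 1], n_g)
        if r > 0:
            zsc = config.covariate_scales[g]
            Z = _positive_draws(rng, zsc[:, 0], zsc[:, 1], n_g)
            z_std = (Z - zsc[:, 0]) / zsc[:, 1]
            mu = beta0 + z_std @ beta
        else:
            Z = None
            mu = np.full(n_g, beta0)

        if config.sigma_true == 0.0:
            delta = np.maximum(mu, 1.0)
        else:
            a = (1.0 - mu) / config.sigma_true
            delta = stats.truncnorm.rvs(
                a, np.inf, loc=mu, scale=config.sigma_true, random_state=rng
            )
        delta = np.maximum(delta, 1.0)

        frontier = np.exp(np.log(X) @ config.frontier_exponents)
        Y = frontier[:, None] * config.multipliers_for(g)[None, :] / delta[:, None]

        ids.extend(f"{g}-{i + 1:03d}" for i in range(n_g))
        groups.extend([g] * n_g)
        X_rows.append(X)
        Y_rows.append(Y)
        if Z is not None:
            Z_rows.append(Z)
        delta_rows.append(delta)

    return DMUPanel(
        ids=np.array(ids),
        groups=np.array(groups),
        X=np.vstack(X_rows),
        Y=np.vstack(Y_rows),
        Z=np.vstack(Z_rows) if Z_rows else None,
        input_names=list(config.input_names),
        output_names=list(config.output_names),
        covariate_names=list(config.covariate_names) if r > 0 else None,
        true_delta=np.concatenate(delta_rows),
        meta={"config": config.to_dict()},
    )


def standardize_covariates(panel: DMUPanel, config: SyntheticConfig) -> np.ndarray:
    """Covariates on the scale the generating effects are defined on.

    Standardises each unit's raw covariates by the (mean, sd) its group was
    generated with, so regressing scores on the result recovers
    ``config.covariate_effects`` directly.
    """
    if panel.Z is None or config.covariate_scales is None:
        raise ValueError("panel or config has no covariates")
    out = np.empty_like(panel.Z)
    for g in config.groups:
        mask = panel.groups == g
        sc = config.covariate_scales[g]
        out[mask] = (panel.Z[mask] - sc[:, 0]) / sc[:, 1]
    return out


# ---------------------------------------------------------------------------
# ready-made configurations
# ---------------------------------------------------------------------------

_TABLE2_INPUTS = {
    "district": [(9942.15, 791.14), (18.64, 10.97), (14.18, 7.08), (31.81, 9.84), (45.76, 6.51)],
    "county": [(8650.51, 118.19), (15.52, 9.86), (12.61, 11.55), (27.03, 11.23), (31.90, 11.40)],
}
_TABLE2_OUTPUT_TARGETS = {
    "district": [11060.88, 2190.44, 27175.58, 13756.32],
    "county": [9269.32, 990.03, 18558.79, 13087.94],
}
_TABLE2_COVARIATES = {
    "district": [
        (444967.42, 197.25), (41566.27, 224.18), (7021.21, 454.33),
        (42.63, 3.71), (35.24, 2.50), (1313.87, 126.74),
    ],
    "county": [
        (251604.0, 132.10), (26179.51, 145.50), (6864.05, 767.72),
        (40.34, 3.56), (26.67, 3.74), (1106.42, 162.56),
    ],
}
_INPUT_NAMES = ["expenditure", "doctors", "nurses", "beds", "devices"]
_OUTPUT_NAMES = ["revenue", "discharges", "visits", "examinations"]
_COVARIATE_NAMES = [
    "population", "gdp_per_capita", "financial_subsidy",
    "prop_health_professionals", "trained_workers", "avg_staff_income",
]
# Farrell-scale inefficiency effects on the standardised covariates: a better
# professional mix, more trained staff and more subsidy reduce inefficiency;
# population, local GDP and staff income carry no effect.
_DEFAULT_EFFECTS = np.array([1.5, 0.0, 0.0, -0.05, -0.15, -0.15, 0.0])
_DEFAULT_EXPONENTS = np.array([0.35, 0.20, 0.15, 0.20, 0.10])  # sums to 1 (CRS frontier)
_DEFAULT_SIGMA = 0.15


def _frontier_mean(scales: np.ndarray, exponents: np.ndarray, n: int = 4000) -> float:
    """Monte-Carlo mean of the Cobb-Douglas kernel under the input draws.

    Uses a fixed internal seed: this is a deterministic calibration constant
    of the configuration, not part of the simulation randomness.
    """
    rng = np.random.default_rng(20170101)
    X = _positive_draws(rng, scales[:, 0], scales[:, 1], n)
    return float(np.exp(np.log(X) @ exponents).mean())


def default_table2_config(seed: int = 0, pooled_frontier: bool = False) -> SyntheticConfig:
    """The survey-shaped configuration: 33 district + 84 county hospitals.

    Five inputs and four outputs at the published per-group descriptive
    scales, six covariates (three external: population, GDP per capita,
    financial subsidy; three internal: professional mix, trained workers,
    staff income).  Output multipliers are calibrated so that per-group mean
    *frontier* outputs (before inefficiency deflation) match the published
    output means.
    """
    exponents = _DEFAULT_EXPONENTS
    multipliers = {}
    for g, targets in _TABLE2_OUTPUT_TARGETS.items():
        scales = np.asarray(_TABLE2_INPUTS[g], dtype=float)
        kernel = _frontier_mean(scales, exponents)
        multipliers[g] = np.asarray(targets, dtype=float) / kernel
    return SyntheticConfig(
        n_per_group={"district": 33, "county": 84},
        n_inputs=5,
        n_outputs=4,
        frontier_exponents=exponents,
        output_multipliers=multipliers,
        covariate_effects=_DEFAULT_EFFECTS.copy(),
        sigma_true=_DEFAULT_SIGMA,
        input_scales={g: np.asarray(v, float) for g, v in _TABLE2_INPUTS.items()},
        covariate_scales={g: np.asarray(v, float) for g, v in _TABLE2_COVARIATES.items()},
        input_names=list(_INPUT_NAMES),
        output_names=list(_OUTPUT_NAMES),
        covariate_names=list(_COVARIATE_NAMES),
        pooled_frontier=pooled_frontier,
        seed=seed,
    )


def coverage_benchmark_config(
    n_units: int = 50,
    seed: int = 0,
    sigma_true: float = 0.2,
) -> SyntheticConfig:
    """Homogeneous-inefficiency configuration for interval-calibration studies.

    Intercept-only inefficiency (``delta = 1 + |N(0, sigma)|`` in
    distribution, boundary-peaked) because the homogeneous bootstrap is
    defined under the assumption that inefficiency is identically
    distributed across units; a curved (decreasing-returns) Cobb-Douglas
    frontier with two inputs and one output.  The true Farrell score of
    every unit is its stored ``true_delta``.
    """
    return SyntheticConfig(
        n_per_group={"all": int(n_units)},
        n_inputs=2,
        n_outputs=1,
        frontier_exponents=np.array([0.40, 0.45]),
        output_multipliers=np.array([10.0]),
        covariate_effects=np.array([1.0]),
        sigma_true=sigma_true,
        input_scales=np.array([[100.0, 30.0], [50.0, 15.0]]),
        seed=seed,
    )


def recovery_benchmark_config(
    n_units: int = 100,
    seed: int = 0,
    sigma_true: float = _DEFAULT_SIGMA,
) -> SyntheticConfig:
    """Small-dimension single-group configuration for Monte-Carlo studies.

    Two inputs, one output, a constant-returns Cobb-Douglas frontier and
    three covariates with effects (+0.4, -0.3, 0.0) on the Farrell scale:
    one inefficiency-increasing effect, one inefficiency-reducing effect and
    one null.  Low input/output dimension keeps the DEA frontier bias small
    at moderate sample sizes, which is what makes second-stage parameter
    recovery a sharp test.
    """
    return SyntheticConfig(
        n_per_group={"all": int(n_units)},
        n_inputs=2,
        n_outputs=1,
        frontier_exponents=np.array([0.45, 0.55]),
        output_multipliers=np.array([10.0]),
        covariate_effects=np.array([1.4, 0.4, -0.3, 0.0]),
        sigma_true=sigma_true,
        input_scales=np.array([[100.0, 30.0], [50.0, 15.0]]),
        covariate_scales=np.array([[10.0, 2.0], [5.0, 1.0], [8.0, 1.6]]),
        seed=seed,
    )
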