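"""Observing-system simulation experiments (OSSEs).

A twin experiment with deliberate model error: the "truth" tumor evolves
under the two-phenotype model with nominal parameters, while the forecast
ensemble uses the simpler logistic Swanson model with per-member
parameters drawn uniformly from experiment-specific intervals (growth
rate α, carrying capacity T_max, white-matter diffusion D_w; gray-matter
and CSF diffusion stay at their nominal values).  Three experiments widen
the intervals progressively:

    Experiment 1:  α ∈ [0.01767, 0.035347]  (260–520-day 1%→99% logistic
                   transition), D_w ∈ [2e-3, 2e-2]
    Experiment 2:  α ∈ [0.0153, 0.0612]     (150–600 days), D_w ∈ [2e-4, 2e-2]
    Experiment 3:  α ∈ [0.0153, 0.10]       (90–600 days),  D_w ∈ [2e-4, 2e-1]

with T_max ∈ [8000, 12000] throughout.

Protocol: the truth is seeded with 100 proliferating + 10 migrating cells
in one voxel and spun up 365 days; each member seeds a uniform U[50, 150]
cell count in a voxel within 3 mm (Euclidean) of the truth seed and spins
up 365 days under its own parameters.  A noisy synthetic MR image of the
truth is assimilated by the LETKF at t = 0, 60, ..., 360 days (seven
assimilations, six 60-day forecast cycles).  The whole experiment is a
pure function of its configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import DomainError, FilterError
from .letkf import LETKFConfig, letkf_global
from .observation_model import Observation, build_R, predicted_observation, synth_observe
from .tissue_geometry import TissueGrid, default_seed_voxel
from .tumor_models import (
    SwansonParams,
    TumorState,
    TwoPhenotypeParams,
    integrate,
    integrate_swanson_ensemble,
    seed_tumor,
)


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling intervals for the forecast-model parameters."""

    alpha: tuple[float, float]
    T_max: tuple[float, float]
    D_white: tuple[float, float]
    D_gray: float = 0.0013
    D_csf: float = 0.001

    def __post_init__(self):
        for lo, hi in (self.alpha, self.T_max, self.D_white):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < lo <= hi")


#: the three experiments' parameter intervals
EXPERIMENT_RANGES: dict[int, ParameterRanges] = {
    1: ParameterRanges(alpha=(0.01767, 0.035347), T_max=(8000.0, 12000.0),
                       D_white=(2.0e-3, 2.0e-2)),
    2: ParameterRanges(alpha=(0.0153, 0.0612), T_max=(8000.0, 12000.0),
                       D_white=(2.0e-4, 2.0e-2)),
    3: ParameterRanges(alpha=(0.0153, 0.10), T_max=(8000.0, 12000.0),
                       D_white=(2.0e-4, 2.0e-1)),
}

NOMINAL_T_MAX = 10_000.0


@dataclass
class ExperimentConfig:
    """Full OSSE configuration; with the seeds, it determines the run."""

    experiment_id: int = 2
    ranges: ParameterRanges | None = None
    k: int = 50
    cycle_days: float = 60.0
    n_assimilations: int = 7
    dt: float = 0.1
    local_halfwidth: int = 3
    rho_inflation: float = 0.1
    seeds: dict = field(
        default_factory=lambda: {"truth": 0, "params": 1, "init": 2, "obs": 3}
    )
    truth_seed_voxel: tuple[int, int] | None = None
    ensemble_seed_radius_mm: float = 3.0
    spinup_days: float = 365.0
    noise_bound: float = 0.1
    obs_mode: str = "noise_free"

    def __post_init__(self):
        if self.n_assimilations < 1 or self.cycle_days <= 0:
            raise ValueError("need n_assimilations >= 1 and cycle_days > 0")
        if self.ranges is None:
            self.ranges = EXPERIMENT_RANGES[self.experiment_id]
        for name in ("truth", "params", "init", "obs"):
            if name not in self.seeds:
                raise ValueError(f"missing seed {name!r}")

    @property
    def letkf_config(self) -> LETKFConfig:
        return LETKFConfig(
            k=self.k,
            local_halfwidth=self.local_halfwidth,
            rho_inflation=self.rho_inflation,
        )

    @property
    def assimilation_times(self) -> list[float]:
        return [i * self.cycle_days for i in range(self.n_assimilations)]


def load_experiment_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file mirroring its keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "ranges" in data and data["ranges"] is not None:
        data["ranges"] = ParameterRanges(**{
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in data["ranges"].items()
        })
    if data.get("truth_seed_voxel") is not None:
        data["truth_seed_voxel"] = tuple(data["truth_seed_voxel"])
    return ExperimentConfig(**data)


@dataclass
class Ensemble:
    """k member states, each with its own fixed Swanson parameters."""

    members: list[TumorState]
    params: list[SwansonParams]

    def __post_init__(self):
        if len(self.members) != len(self.params):
            raise ValueError("one parameter set per member required")

    @property
    def k(self) -> int:
        return len(self.members)

    def copy(self) -> "Ensemble":
        return Ensemble([m.copy() for m in self.members], list(self.params))

    def params_digest(self) -> str:
        payload = [(p.alpha, p.T_max, dict(p.D)) for p in self.params]
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def mean_fraction(self) -> np.ndarray:
        """Pointwise ensemble mean of the fraction of carrying capacity."""
        return np.mean(
            [np.clip(m.g / p.T_max, 0.0, 1.0) for m, p in zip(self.members, self.params)],
            axis=0,
        )


@dataclass
class CycleRecord:
    """One forecast/assimilation cycle's fields and bookkeeping."""

    t: float
    background_mean: np.ndarray
    analysis_mean: np.ndarray
    truth_total: np.ndarray
    observation: Observation
    params_digest: str


def sample_ensemble_params(
    ranges: ParameterRanges, k: int, rng: np.random.Generator
) -> list[SwansonParams]:
    """Draw k independent parameter sets, fixed for the whole simulation."""
    out = []
    for _ in range(k):
        out.append(
            SwansonParams(
                alpha=float(rng.uniform(*ranges.alpha)),
                T_max=float(rng.uniform(*ranges.T_max)),
                D={
                    "white": float(rng.uniform(*ranges.D_white)),
                    "gray": ranges.D_gray,
                    "csf": ranges.D_csf,
                },
            )
        )
    return out


def make_truth(
    config: ExperimentConfig,
    grid: TissueGrid,
    params: TwoPhenotypeParams | None = None,
) -> list[TumorState]:
    """Truth trajectory: two-phenotype model, nominal parameters.

    Seeds 100 proliferating + 10 migrating cells in one voxel, spins up
    365 days, then integrates a further ``(n_assimilations − 1) × cycle``
    days recording snapshots at the cycle cadence.  The returned snapshot
    times are relabelled so t = 0 is the end of spin-up.
    """
    params = params or TwoPhenotypeParams()
    voxel = config.truth_seed_voxel or default_seed_voxel(grid)
    state = seed_tumor(grid, voxel, 100.0, 10.0, params, config.spinup_days, config.dt)
    state.t = 0.0
    horizon = (config.n_assimilations - 1) * config.cycle_days
    snaps = integrate(state, params, grid, horizon, config.dt,
                      snapshot_every=config.cycle_days)
    return snaps


def init_ensemble(
    config: ExperimentConfig,
    grid: TissueGrid,
    rng: np.random.Generator,
    params: list[SwansonParams] | None = None,
) -> Ensemble:
    """Initial forecast ensemble after the 365-day spin-up.

    Each member seeds a U[50, 150] cell count in one brain voxel within
    ``ensemble_seed_radius_mm`` (Euclidean, voxel centres) of the truth
    seed, then grows 365 days under its own parameters.
    """
    if params is None:
        params = sample_ensemble_params(
            config.ranges, config.k, np.random.default_rng(config.seeds["params"])
        )
    truth_voxel = config.truth_seed_voxel or default_seed_voxel(grid)
    rr, cc = np.nonzero(grid.brain_mask)
    dist_mm = grid.spacing_mm * np.hypot(rr - truth_voxel[0], cc - truth_voxel[1])
    candidates = np.flatnonzero(dist_mm <= config.ensemble_seed_radius_mm)
    if candidates.size == 0:
        raise DomainError(
            f"no brain voxel within {config.ensemble_seed_radius_mm} mm of {truth_voxel}"
        )
    h2 = grid.spacing_mm**2
    seeds = []
    for _ in params:
        i = candidates[rng.integers(candidates.size)]
        count = float(rng.uniform(50.0, 150.0))
        g = np.zeros(grid.shape)
        g[rr[i], cc[i]] = count / h2
        seeds.append(TumorState(g, t=0.0))
    members = integrate_swanson_ensemble(
        seeds, list(params), grid, config.spinup_days, config.dt
    )
    for m in members:
        m.t = 0.0
    return Ensemble(members, list(params))


def _assimilate(
    ensemble: Ensemble,
    obs: Observation,
    config: ExperimentConfig,
    grid: TissueGrid,
) -> Ensemble:
    """One LETKF update of a Swanson (single-field) ensemble."""
    fields = np.stack([m.g[None] for m in ensemble.members])        # k,1,R,C
    predicted = np.stack(
        [
            predicted_observation(m, p.T_max, mode="noise_free")
            for m, p in zip(ensemble.members, ensemble.params)
        ]
    )
    analysis = letkf_global(
        fields,
        predicted,
        obs,
        build_R(noise_bound=config.noise_bound),
        config.letkf_config,
        grid.brain_mask,
        var_bounds=((0.0, None),),
    )
    if not np.isfinite(analysis).all():
        raise FilterError((-1, -1), "filter divergence: non-finite analysis")
    new_members = []
    for i, m in enumerate(ensemble.members):
        s = m.copy()
        s.g = analysis[i, 0]
        new_members.append(s)
    return Ensemble(new_members, list(ensemble.params))


def run_cycles(
    config: ExperimentConfig,
    grid: TissueGrid,
    truth: list[TumorState] | None = None,
    ensemble: Ensemble | None = None,
) -> list[CycleRecord]:
    """Run the full forecast/assimilation cycle sequence.

    At each assimilation time (t = 0 included) a noisy image of the truth
    is synthesised and assimilated; between times every member integrates
    ``cycle_days`` under its own fixed parameters.  Pre-computed truth
    trajectories / initial ensembles may be passed in to share spin-up
    work between runs; they are not mutated.
    """
    if truth is None:
        truth = make_truth(config, grid)
    if len(truth) != config.n_assimilations:
        raise ValueError(
            f"truth trajectory has {len(truth)} snapshots, "
            f"need {config.n_assimilations}"
        )
    if ensemble is None:
        ensemble = init_ensemble(config, grid, np.random.default_rng(config.seeds["init"]))
    ensemble = ensemble.copy()
    obs_rng = np.random.default_rng(config.seeds["obs"])
    digest = ensemble.params_digest()

    records = []
    for cycle, t in enumerate(config.assimilation_times):
        obs = synth_observe(
            truth[cycle].total(),
            NOMINAL_T_MAX,
            obs_rng,
            noise_bound=config.noise_bound,
            mask=grid.brain_mask,
            t=t,
        )
        background_mean = ensemble.mean_fraction()
        try:
            ensemble = _assimilate(ensemble, obs, config, grid)
        except FilterError as exc:
            raise FilterError(exc.voxel, f"cycle {cycle}: {exc}") from exc
        records.append(
            CycleRecord(
                t=t,
                background_mean=background_mean,
                analysis_mean=ensemble.mean_fraction(),
                truth_total=np.clip(truth[cycle].total() / NOMINAL_T_MAX, 0.0, 1.0),
                observation=obs,
                params_digest=digest,
            )
        )
        if cycle + 1 < config.n_assimilations:
            ensemble.members = integrate_swanson_ensemble(
                ensemble.members, ensemble.params, grid, config.cycle_days, config.dt
            )
    return records


def free_run(
    ensemble: Ensemble,
    grid: TissueGrid,
    days: float,
    dt: float = 0.1,
) -> np.ndarray:
    """Ensemble mean fraction after ``days`` with no assimilation."""
    members = integrate_swanson_ensemble(
        [m.copy() for m in ensemble.members], list(ensemble.params), grid, days, dt
    )
    return Ensemble(members, list(ensemble.params)).mean_fraction()
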