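"""Simulation studies: noise model, recovery experiments, loss landscapes.

The harness mirrors three experimental scenarios for the constitutive
parameters (c1, c2) at known pressure -

1. a two time-point experiment without observation error,
2. a two time-point experiment with observation error (10 replicates),
3. a multiple time-point (N = 10) experiment with observation error -

and the analogous experiments 1-2 for the intra-ventricular pressure with the
constitutive parameters known.  Observation error is modelled as
``u_eps = (r / |r|) * eta`` with the components of ``r`` drawn U(0, 1) and
``eta ~ N(0, sigma)``, ``sigma = 1 mm`` by default (about two MRI pixels).
The literal U(0, 1) components confine directions to the positive octant;
a uniform-sphere alternative is available via the ``direction`` switch.

All runs of a study are optimised in lock-step by the batched engines of
:mod:`lvestim.inverse`; this is numerically identical to looping runs one by
one, since nothing couples them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mechanics
from .mechanics import GeometryParams, MaterialParams, Surface
from .inverse import (ContourObservation, FullFieldObservation,
                      MultiFrameObservation, OptimSchedule, _ContourBatch,
                      _FullFieldBatch, multi_frame_loss, optimise_inputs,
                      PARAM_RANGES)

__all__ = [
    "NoiseModel",
    "sample_noise_vector",
    "sample_noise_vectors",
    "perturb_observations",
    "ExperimentGrid",
    "make_full_field_observation",
    "make_contour_observation",
    "run_grid_experiment",
    "run_pressure_experiment",
    "summarize_relative_errors",
    "loss_landscape",
]


@dataclass(frozen=True)
class NoiseModel:
    """Random observation error: direction from ``r`` (components U(0, 1) in
    the literal 'octant' convention, or uniform on the sphere), magnitude
    ``eta ~ N(0, sigma)`` in mm."""

    sigma: float = 1.0
    direction: str = "octant"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.direction not in ("octant", "sphere"):
            raise ValueError("direction must be 'octant' or 'sphere'")


def sample_noise_vectors(noise: NoiseModel, n: int, rng) -> np.ndarray:
    """Draw ``n`` iid error vectors (n, 3) in mm."""
    rng = np.random.default_rng(rng)
    if noise.sigma == 0.0:
        return np.zeros((n, 3))
    if noise.direction == "octant":
        r = rng.random((n, 3))
    else:
        r = rng.standard_normal((n, 3))
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    eta = rng.normal(0.0, noise.sigma, size=(n, 1))
    return (r / norms) * eta


def sample_noise_vector(noise: NoiseModel, rng) -> np.ndarray:
    """Single error vector (3,)."""
    return sample_noise_vectors(noise, 1, rng)[0]


def perturb_observations(obs, noise: NoiseModel, rng):
    """Return a noisy copy of an observation.

    Full-field: every observed displacement vector receives an independent
    error.  Contour: every point of the *loaded* observed surfaces does; the
    reference surfaces are left untouched.  Multi-frame observations get
    independent errors per frame.
    """
    rng = np.random.default_rng(rng)
    if isinstance(obs, MultiFrameObservation):
        return MultiFrameObservation(
            [perturb_observations(f, noise, rng) for f in obs.frames])
    if isinstance(obs, FullFieldObservation):
        eps = sample_noise_vectors(noise, len(obs.points), rng)
        return FullFieldObservation(points=obs.points.copy(),
                                    displacements=obs.displacements + eps,
                                    pressure=obs.pressure)
    if isinstance(obs, ContourObservation):
        def noisy(surface: Surface) -> Surface:
            eps = sample_noise_vectors(noise, len(surface), rng)
            return Surface(label=surface.label, time_tag=surface.time_tag,
                           points=surface.points + eps)
        return ContourObservation(
            reference_endo=obs.reference_endo,
            reference_epi=obs.reference_epi,
            observed_endo=noisy(obs.observed_endo),
            observed_epi=noisy(obs.observed_epi),
            pressure=obs.pressure)
    raise TypeError(f"unsupported observation type {type(obs)!r}")


@dataclass(frozen=True)
class ExperimentGrid:
    """Ground-truth sweep for the recovery studies."""

    c1_values: tuple = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    c2_values: tuple = (4.0, 10.0, 16.0, 22.0, 28.0, 34.0, 40.0)
    p_true: float = 0.9
    n_replicates: int = 10
    n_frames: int = 10
    sigma: float = 1.0

    def __post_init__(self):
        for c1 in self.c1_values:
            if not PARAM_RANGES["c1"][0] <= c1 <= PARAM_RANGES["c1"][1]:
                raise ValueError(f"c1 truth {c1} outside training range")
        for c2 in self.c2_values:
            if not PARAM_RANGES["c2"][0] <= c2 <= PARAM_RANGES["c2"][1]:
                raise ValueError(f"c2 truth {c2} outside training range")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def cells(self):
        return [(c1, c2) for c1 in self.c1_values for c2 in self.c2_values]


def make_full_field_observation(geometry, material, pressures, points
                                ) -> MultiFrameObservation:
    """Noise-free tracked displacements of ``points`` along a pressure trace."""
    frames = []
    for p in np.atleast_1d(pressures):
        disp = mechanics.displacement_field(geometry, material, p, points)
        frames.append(FullFieldObservation(points=points,
                                           displacements=disp.vectors,
                                           pressure=float(p)))
    return MultiFrameObservation(frames)


def make_contour_observation(geometry, material, pressures, n_sparse,
                             n_dense, seed) -> MultiFrameObservation:
    """Noise-free contour observations along a pressure trace.

    The sparse reference surfaces (displaced by the surrogate during
    estimation) and the dense observed surfaces use independent seeded
    angular samples; the same material surface points are observed at every
    frame.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed)).spawn(4)
    ref = {lab: mechanics.sample_surface(geometry, lab, n_sparse,
                                         np.random.default_rng(s))
           for lab, s in zip(("endo", "epi"), ss[:2])}
    dense_ref = {lab: mechanics.sample_surface(geometry, lab, n_dense,
                                               np.random.default_rng(s))
                 for lab, s in zip(("endo", "epi"), ss[2:])}
    frames = []
    for p in np.atleast_1d(pressures):
        observed = {lab: mechanics.loaded_surface(geometry, material, float(p),
                                                  dense_ref[lab])
                    for lab in ("endo", "epi")}
        frames.append(ContourObservation(
            reference_endo=ref["endo"], reference_epi=ref["epi"],
            observed_endo=observed["endo"], observed_epi=observed["epi"],
            pressure=float(p)))
    return MultiFrameObservation(frames)


def _relative_errors(estimates, truths, names) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(names):
        rows.append(pd.DataFrame({
            "param": name,
            "estimate": estimates[:, j],
            "truth": truths[:, j],
            "rel_err_pct": 100.0 * np.abs(estimates[:, j] - truths[:, j])
                           / truths[:, j],
        }))
    return pd.concat(rows, ignore_index=True)


def summarize_relative_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell/per-parameter mean and SD of the relative error (%)."""
    if len(trials) == 0:
        raise ValueError("no trials to summarise")
    keys = [k for k in ("approach", "c1_true", "c2_true", "p_true", "param")
            if k in trials.columns]
    grouped = trials.groupby(keys, sort=False)["rel_err_pct"]
    out = grouped.agg(mean_rel_err_pct="mean",
                      std_rel_err_pct=lambda s: float(np.std(s)),
                      n_replicates="count").reset_index()
    return out


def _default_schedule() -> OptimSchedule:
    # desk-scale epoch budget: by epoch 1500 the decayed step size leaves
    # parameter jitter around 0.2% of the range, well under the noise floors
    return OptimSchedule(max_epochs=1500)


def run_grid_experiment(model, approach: str = "full-field",
                        grid: ExperimentGrid = ExperimentGrid(),
                        experiment: int = 3,
                        geometry: GeometryParams = GeometryParams(),
                        seed: int = 0,
                        n_wall_points: int = mechanics.N_WALL_POINTS,
                        n_sparse: int = 300, n_dense: int = 1500,
                        n_candidates: int | None = 16,
                        dense_first: bool = True,
                        schedule: OptimSchedule | None = None,
                        tail_average: int = 0,
                        noise_direction: str = "octant"):
    """Joint (c1, c2) recovery study over a ground-truth grid.

    ``experiment`` selects: 1 = noise-free two time-point (single replicate);
    2 = noisy two time-point; 3 = noisy multi-frame (N = ``grid.n_frames``).
    Returns ``(summary, trials)`` DataFrames.
    """
    if approach not in ("full-field", "contour"):
        raise ValueError("approach must be 'full-field' or 'contour'")
    if experiment not in (1, 2, 3):
        raise ValueError("experiment must be 1, 2 or 3")
    schedule = schedule or _default_schedule()
    names = ("c1", "c2")
    n_reps = 1 if experiment == 1 else grid.n_replicates
    sigma = 0.0 if experiment == 1 else grid.sigma
    pressures = (mechanics.make_pressure_trace(grid.p_true, grid.n_frames)
                 if experiment == 3 else np.array([grid.p_true]))
    noise = NoiseModel(sigma=sigma, direction=noise_direction)

    cells = grid.cells
    cell_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    run_truths, trial_meta = [], []
    if approach == "full-field":
        pts_runs, disp_runs = [], []
    else:
        sparse_runs = {"endo": [], "epi": []}
        dense_runs = {"endo": [], "epi": []}

    for (c1, c2), ss in zip(cells, cell_seeds):
        material = MaterialParams(c1=c1, c2=c2)
        obs_seed, noise_seed = ss.spawn(2)
        if approach == "full-field":
            points = mechanics.sample_wall_points(
                geometry, n_wall_points, np.random.default_rng(obs_seed))
            clean = make_full_field_observation(geometry, material, pressures,
                                                points)
        else:
            clean = make_contour_observation(
                geometry, material, pressures, n_sparse, n_dense,
                seed=obs_seed)
        rep_rngs = [np.random.default_rng(s) for s in noise_seed.spawn(n_reps)]
        for rep, rep_rng in enumerate(rep_rngs):
            noisy = (perturb_observations(clean, noise, rep_rng)
                     if sigma > 0 else clean)
            run_truths.append((c1, c2))
            trial_meta.append({"c1_true": c1, "c2_true": c2,
                               "p_true": grid.p_true, "replicate": rep})
            if approach == "full-field":
                pts_runs.append(np.stack([f.points for f in noisy.frames]))
                disp_runs.append(np.stack([f.displacements
                                           for f in noisy.frames]))
            else:
                sparse_runs["endo"].append(noisy.frames[0].reference_endo.points)
                sparse_runs["epi"].append(noisy.frames[0].reference_epi.points)
                dense_runs["endo"].append(
                    np.stack([f.observed_endo.points for f in noisy.frames]))
                dense_runs["epi"].append(
                    np.stack([f.observed_epi.points for f in noisy.frames]))

    if approach == "full-field":
        engine = _FullFieldBatch(model, np.stack(pts_runs),
                                 np.stack(disp_runs), pressures, names,
                                 fixed={})
    else:
        engine = _ContourBatch(
            model,
            {lab: np.stack(sparse_runs[lab]) for lab in ("endo", "epi")},
            {lab: np.stack(dense_runs[lab]) for lab in ("endo", "epi")},
            pressures, names, fixed={}, n_candidates=n_candidates,
            dense_first=dense_first)

    center, halfwidth = model.theta_normalisation()
    cols = [1, 2]  # c1, c2 components of the theta normalisation
    theta, _, _, _, conv, _ = optimise_inputs(
        engine, schedule, center[cols], halfwidth[cols],
        record_trajectory=False, tail_average=tail_average)

    truths = np.asarray(run_truths)
    trials = _relative_errors(theta, truths, names)
    meta = pd.DataFrame(trial_meta * 1)
    trials = pd.concat(
        [pd.concat([meta, meta], ignore_index=True), trials], axis=1)
    trials["approach"] = approach
    trials["converged"] = np.tile(conv, 2)
    return summarize_relative_errors(trials), trials


def run_pressure_experiment(model, approach: str = "full-field",
                            grid: ExperimentGrid = ExperimentGrid(),
                            noisy: bool = False,
                            geometry: GeometryParams = GeometryParams(),
                            seed: int = 0,
                            n_wall_points: int = mechanics.N_WALL_POINTS,
                            n_sparse: int = mechanics.N_PREDICTED_SURFACE,
                            n_dense: int = mechanics.N_OBSERVED_SURFACE,
                            n_candidates: int | None = 16,
                            dense_first: bool = True,
                            schedule: OptimSchedule | None = None,
                            tail_average: int = 0,
                            noise_direction: str = "octant"):
    """Pressure recovery with known constitutive parameters, from a single
    loaded frame (two time-point setting).  Returns ``(summary, trials)``."""
    if approach not in ("full-field", "contour"):
        raise ValueError("approach must be 'full-field' or 'contour'")
    schedule = schedule or _default_schedule()
    names = ("p",)
    n_reps = grid.n_replicates if noisy else 1
    noise = NoiseModel(sigma=grid.sigma if noisy else 0.0,
                       direction=noise_direction)
    pressures = np.array([grid.p_true])

    cells = grid.cells
    cell_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    run_truths, trial_meta, fixed_c1, fixed_c2 = [], [], [], []
    if approach == "full-field":
        pts_runs, disp_runs = [], []
    else:
        sparse_runs = {"endo": [], "epi": []}
        dense_runs = {"endo": [], "epi": []}

    for (c1, c2), ss in zip(cells, cell_seeds):
        material = MaterialParams(c1=c1, c2=c2)
        obs_seed, noise_seed = ss.spawn(2)
        if approach == "full-field":
            points = mechanics.sample_wall_points(
                geometry, n_wall_points, np.random.default_rng(obs_seed))
            clean = make_full_field_observation(geometry, material, pressures,
                                                points)
        else:
            clean = make_contour_observation(
                geometry, material, pressures, n_sparse, n_dense,
                seed=obs_seed)
        rep_rngs = [np.random.default_rng(s) for s in noise_seed.spawn(n_reps)]
        for rep, rep_rng in enumerate(rep_rngs):
            obs = (perturb_observations(clean, noise, rep_rng)
                   if noise.sigma > 0 else clean)
            run_truths.append((grid.p_true,))
            fixed_c1.append(c1)
            fixed_c2.append(c2)
            trial_meta.append({"c1_true": c1, "c2_true": c2,
                               "p_true": grid.p_true, "replicate": rep})
            if approach == "full-field":
                pts_runs.append(np.stack([f.points for f in obs.frames]))
                disp_runs.append(np.stack([f.displacements for f in obs.frames]))
            else:
                sparse_runs["endo"].append(obs.frames[0].reference_endo.points)
                sparse_runs["epi"].append(obs.frames[0].reference_epi.points)
                dense_runs["endo"].append(
                    np.stack([f.observed_endo.points for f in obs.frames]))
                dense_runs["epi"].append(
                    np.stack([f.observed_epi.points for f in obs.frames]))

    fixed = {"c1": np.asarray(fixed_c1), "c2": np.asarray(fixed_c2)}
    if approach == "full-field":
        engine = _FullFieldBatch(model, np.stack(pts_runs),
                                 np.stack(disp_runs), pressures, names, fixed)
    else:
        engine = _ContourBatch(
            model,
            {lab: np.stack(sparse_runs[lab]) for lab in ("endo", "epi")},
            {lab: np.stack(dense_runs[lab]) for lab in ("endo", "epi")},
            pressures, names, fixed, n_candidates=n_candidates,
            dense_first=dense_first)

    center, halfwidth = model.theta_normalisation()
    theta, _, _, _, conv, _ = optimise_inputs(
        engine, schedule, center[:1], halfwidth[:1],
        record_trajectory=False, tail_average=tail_average)

    truths = np.asarray(run_truths)
    trials = _relative_errors(theta, truths, names)
    trials = pd.concat([pd.DataFrame(trial_meta), trials], axis=1)
    trials["approach"] = approach
    trials["converged"] = conv
    return summarize_relative_errors(trials), trials


def loss_landscape(model, obs, param_names, scan_ranges=None, resolution=50,
                   theta=None, dense_first=True) -> pd.DataFrame:
    """Evaluate the observation loss on a regular grid of one or two
    parameters, the remaining inputs held at ``theta``.

    Returns a tidy DataFrame with one row per grid point (columns: the scanned
    parameter(s) and ``loss``), ready for CSV export or plotting.
    """
    param_names = tuple(param_names)
    if not 1 <= len(param_names) <= 2:
        raise ValueError("scan one or two parameters")
    theta = dict(theta or {})
    scan_ranges = dict(scan_ranges or {})
    axes = [np.linspace(*scan_ranges.get(n, PARAM_RANGES[n]), resolution)
            for n in param_names]
    mesh = np.meshgrid(*axes, indexing="ij")
    records = []
    for values in zip(*(m.ravel() for m in mesh)):
        point = dict(theta)
        point.update(dict(zip(param_names, map(float, values))))
        loss = multi_frame_loss(model, obs, point, dense_first=dense_first)
        records.append({**{n: v for n, v in zip(param_names, values)},
                        "loss": loss})
    return pd.DataFrame.from_records(records)
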