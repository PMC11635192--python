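"""Grid search over the two conductance DACs and the resulting fitness
landscape.

Sweeping the leak-conductance DAC against the inter-compartment-
conductance DAC maps how the empirical length constant ``lambda_emp``
and the first-compartment EPSP amplitude ``h0`` depend on the two
parameters: larger leak conductances shorten the length constant and
shrink the EPSP, larger coupling conductances lengthen the length
constant and also shrink the first-compartment EPSP.  The resulting maps
validate what the genetic algorithm finds: the two-observable fitness f2
evaluated on the grid shows the basin the GA solutions should fall into,
and iso-lambda contours mark the degenerate one-observable solution set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from . import experiment as xp
from .evolution import WORST_FITNESS, fitness_lambda_amplitude
from .experiment import (
    AttenuationFit,
    FitError,
    Observation,
    ProtocolConfig,
    TargetObservation,
)
from .substrate import SubstrateConfig

__all__ = ["GridResult", "grid_sweep", "fitness_landscape", "iso_lambda_contour"]


@dataclass
class GridResult:
    """lambda_emp and h0 maps over a (g_l DAC x g_ic DAC) grid.

    Map shape is (len(gl_axis), len(gic_axis)); cells whose attenuation
    fit was degenerate hold NaN and are listed in ``failed_cells``.
    """

    gl_axis: np.ndarray
    gic_axis: np.ndarray
    lambda_map: np.ndarray
    h0_map: np.ndarray
    failed_cells: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def grid_sweep(
    substrate_cfg: SubstrateConfig,
    protocol_cfg: ProtocolConfig,
    gl_values: Sequence[int],
    gic_values: Sequence[int],
    seed: int | None = None,
) -> GridResult:
    """Run the attenuation experiment at every (g_l, g_ic) DAC pair.

    Each cell uses a fresh measurement seed derived from ``seed`` (one
    independent run per setting); degenerate fits are recorded as failed
    cells rather than raised.
    """
    gl_axis = np.asarray([int(v) for v in gl_values])
    gic_axis = np.asarray([int(v) for v in gic_values])
    if gl_axis.size == 0 or gic_axis.size == 0:
        raise ValueError("grid axes must be non-empty")
    lam = np.full((gl_axis.size, gic_axis.size), np.nan)
    h0 = np.full_like(lam, np.nan)
    failed: list[tuple[int, int]] = []
    master = 0 if seed is None else int(seed)
    for i, dac_gl in enumerate(gl_axis):
        for j, dac_gic in enumerate(gic_axis):
            cell_seed = xp.stream_seed_int(master, i * gic_axis.size + j)
            try:
                obs = xp.run_attenuation_experiment(
                    (dac_gl, dac_gic), substrate_cfg, protocol_cfg, seed=cell_seed
                )
            except FitError:
                failed.append((i, j))
                continue
            lam[i, j] = obs.lambda_emp
            h0[i, j] = obs.h0
    return GridResult(
        gl_axis=gl_axis,
        gic_axis=gic_axis,
        lambda_map=lam,
        h0_map=h0,
        failed_cells=failed,
        meta={"seed": master},
    )


def fitness_landscape(grid: GridResult, target: TargetObservation) -> np.ndarray:
    """Apply the two-observable fitness f2 cell-wise to the grid maps.

    Failed cells carry the WORST_FITNESS sentinel so the landscape stays
    totally ordered.
    """
    out = np.full(grid.lambda_map.shape, WORST_FITNESS)
    for i in range(grid.lambda_map.shape[0]):
        for j in range(grid.lambda_map.shape[1]):
            lam = grid.lambda_map[i, j]
            h0 = grid.h0_map[i, j]
            if np.isnan(lam) or np.isnan(h0):
                continue
            obs = Observation(
                amplitudes=np.array([h0]),
                lambda_emp=lam,
                fit=AttenuationFit(a=np.nan, lambda_emp=lam, c=np.nan, residual=np.nan),
            )
            out[i, j] = fitness_lambda_amplitude(obs, target)
    return out


def iso_lambda_contour(grid: GridResult, level: float) -> list[np.ndarray]:
    """Contour segments of the lambda map at ``level``, in DAC coordinates.

    Uses marching squares on the grid; each returned array has shape
    (n_points, 2) with columns (dac_gl, dac_gic).  A level outside the
    map's range (or a constant map) yields an empty list.
    """
    lam = grid.lambda_map
    finite = lam[np.isfinite(lam)]
    if finite.size == 0 or not finite.min() < level < finite.max():
        return []
    contours = measure.find_contours(lam, level)
    out = []
    idx_gl = np.arange(grid.gl_axis.size)
    idx_gic = np.arange(grid.gic_axis.size)
    for c in contours:
        dac_gl = np.interp(c[:, 0], idx_gl, grid.gl_axis.astype(float))
        dac_gic = np.interp(c[:, 1], idx_gic, grid.gic_axis.astype(float))
        out.append(np.column_stack([dac_gl, dac_gic]))
    return out
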