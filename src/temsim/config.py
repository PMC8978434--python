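"""Plain-text (YAML) configuration for coefficient sets and scenario grids.

Keys mirror the generating-model symbol names (alpha0, alpha_m, alpha_mx1,
alpha_x, beta0, beta_t, beta_m, beta_tm, beta_mx1, beta_x, prev_m,
prev_x456, sigma_e1, sigma_y, n) so a config file doubles as a readable
record of the study conditions.  A written config re-read yields an
identical grid.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dgp import DGPCoefficients
from .simulation import ScenarioGrid

__all__ = ["grid_to_dict", "grid_from_dict", "save_config", "load_config"]


def grid_to_dict(grid: ScenarioGrid) -> dict:
    return {
        "grid": {
            "alpha_mx1_values": list(grid.alpha_mx1_values),
            "beta_mx1_values": list(grid.beta_mx1_values),
            "beta_tm_values": list(grid.beta_tm_values),
            "prev_m_values": list(grid.prev_m_values),
            "n_reps": grid.n_reps,
            "n": grid.n,
            "base_seed": grid.base_seed,
        },
        "coefficients": grid.base_coeffs.to_dict(),
    }


def grid_from_dict(d: dict) -> ScenarioGrid:
    g = d.get("grid", {})
    coeffs = DGPCoefficients.from_dict(d.get("coefficients", {}))
    kwargs = {}
    for key in ("alpha_mx1_values", "beta_mx1_values", "beta_tm_values", "prev_m_values"):
        if key in g:
            kwargs[key] = tuple(float(v) for v in g[key])
    for key in ("n_reps", "n", "base_seed"):
        if key in g:
            kwargs[key] = int(g[key])
    return ScenarioGrid(base_coeffs=coeffs, **kwargs)


def save_config(grid: ScenarioGrid, path) -> None:
    Path(path).write_text(yaml.safe_dump(grid_to_dict(grid), sort_keys=False))


def load_config(path) -> ScenarioGrid:
    with open(path) as fh:
        return grid_from_dict(yaml.safe_load(fh))
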