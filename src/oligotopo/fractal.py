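"""Surface fractal dimension from SASA--probe-radius scaling.

The surface area traced by probes of increasing radius shrinks faster on a
rough surface than on a smooth one; the roughness exponent is estimated as
``FD = 2 - slope`` of log SASA versus log probe radius over a ladder of
probe radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structio import StructureModel, sasa, select_chains

#: Probe-radius ladder (Å): 1.0 to 2.0 in steps of 0.2.
DEFAULT_PROBE_RADII: tuple[float, ...] = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)


@dataclass(frozen=True)
class FDProfile:
    """Probe ladder, SASA values, log-log regression slope and FD."""

    probe_radii: np.ndarray
    sasa_values: np.ndarray
    slope: float
    fd: float
    r_squared: float
    subject_label: str = ""

    def __post_init__(self) -> None:
        pr = np.asarray(self.probe_radii, float)
        sa = np.asarray(self.sasa_values, float)
        object.__setattr__(self, "probe_radii", pr)
        object.__setattr__(self, "sasa_values", sa)
        if len(pr) != len(sa) or len(pr) < 3:
            raise ValueError("need >= 3 matched (probe, SASA) points")
        if not np.all(np.diff(pr) > 0):
            raise ValueError("probe radii must be strictly increasing")
        if not np.all(sa > 0):
            raise ValueError("all SASA values must be positive")
        if self.fd != 2.0 - self.slope:
            raise ValueError("fd must equal 2 - slope exactly")


def sasa_profile(
    model: StructureModel,
    probe_radii: tuple[float, ...] | list[float] = DEFAULT_PROBE_RADII,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, np.ndarray]:
    """Total SASA at each probe radius, identical algorithm settings throughout."""
    probe_radii = np.asarray(probe_radii, dtype=float)
    if probe_radii.ndim != 1 or len(probe_radii) < 3:
        raise ValueError("need at least 3 probe radii")
    if not np.all(np.diff(probe_radii) > 0):
        raise ValueError("probe radii must be strictly increasing")
    values = np.array(
        [sasa(model, probe_radius=pr, n_sphere_points=n_sphere_points).total for pr in probe_radii]
    )
    return probe_radii, values


def fractal_dimension(
    probe_radii: np.ndarray,
    sasa_values: np.ndarray,
    subject_label: str = "",
) -> FDProfile:
    """Fit log(SASA) vs log(PR) by ordinary least squares; FD = 2 - slope.

    Natural logarithms are used; the slope of a log-log fit is base
    invariant.
    """
    probe_radii = np.asarray(probe_radii, float)
    sasa_values = np.asarray(sasa_values, float)
    if np.any(sasa_values <= 0):
        raise ValueError("SASA values must be positive for the log-log fit")
    res = stats.linregress(np.log(probe_radii), np.log(sasa_values))
    slope = float(res.slope)
    return FDProfile(
        probe_radii=probe_radii,
        sasa_values=sasa_values,
        slope=slope,
        fd=2.0 - slope,
        r_squared=float(res.rvalue) ** 2,
        subject_label=subject_label,
    )


def structure_fd(
    model: StructureModel,
    probe_radii: tuple[float, ...] | list[float] = DEFAULT_PROBE_RADII,
    n_sphere_points: int = 960,
    subject_label: str = "",
) -> FDProfile:
    """Convenience: SASA ladder plus regression in one call."""
    pr, sa = sasa_profile(model, probe_radii, n_sphere_points=n_sphere_points)
    return fractal_dimension(pr, sa, subject_label=subject_label or model.source_label)


def per_chain_fd(
    model: StructureModel,
    probe_radii: tuple[float, ...] | list[float] = DEFAULT_PROBE_RADII,
    n_sphere_points: int = 960,
) -> dict[str, FDProfile]:
    """FD of each chain analysed in isolation (own solvent accessibility)."""
    chains = model.chains
    if not chains:
        raise ValueError("model has no chains")
    out: dict[str, FDProfile] = {}
    for chain in chains:
        sub = select_chains(model, {chain})
        out[chain] = structure_fd(
            sub, probe_radii, n_sphere_points=n_sphere_points, subject_label=f"chain {chain}"
        )
    return out
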