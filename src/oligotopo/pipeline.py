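"""Config-driven orchestration of the analysis stages.

A run config is a nested mapping (usually parsed from YAML) naming the
input structure / data files, toggling stages, and setting stage
parameters.  Unknown keys are rejected before anything executes; every
run writes per-stage CSV/JSON outputs plus a manifest recording the
resolved config, package version, radii table and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, dls, ellipsoid, equilibrium, fractal, pcn, structio

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


_STAGE_KEYS: dict[str, set[str]] = {
    "fd": {"enabled", "chains", "per_chain", "probe_radii", "n_sphere_points"},
    "ellipsoid": {"enabled", "chains", "atoms"},
    "pcn": {"enabled", "frame", "k", "bc", "lower_cut", "upper_cut", "seed"},
    "equilibrium": {"enabled", "data", "scheme", "k2", "n_bootstrap", "seed"},
    "dls": {"enabled", "data", "fit_bimodal"},
}
_TOP_KEYS = {"structure", "output_dir", "stages", "altloc_policy", "model_policy"}


@dataclass
class RunConfig:
    structure: str | None
    output_dir: str
    stages: dict[str, dict[str, Any]]
    model_policy: str = "all"
    altloc_policy: str = "highest-occupancy"

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        stages_raw = raw.get("stages") or {}
        if not isinstance(stages_raw, Mapping):
            raise ConfigError("stages must be a mapping")
        stages: dict[str, dict[str, Any]] = {}
        for name, params in stages_raw.items():
            if name not in _STAGE_KEYS:
                raise ConfigError(
                    f"unknown stage {name!r}; valid stages: {sorted(_STAGE_KEYS)}"
                )
            params = dict(params or {})
            bad = set(params) - _STAGE_KEYS[name]
            if bad:
                raise ConfigError(f"unknown keys for stage {name!r}: {sorted(bad)}")
            if params.get("enabled", True):
                stages[name] = params
        structure_stages = {"fd", "ellipsoid", "pcn"} & set(stages)
        if structure_stages and not raw.get("structure"):
            raise ConfigError(
                f"stages {sorted(structure_stages)} need a 'structure' input path"
            )
        for name in ("equilibrium", "dls"):
            if name in stages and not stages[name].get("data"):
                raise ConfigError(f"stage {name!r} needs a 'data' input path")
        return cls(
            structure=raw.get("structure"),
            output_dir=str(raw["output_dir"]),
            stages=stages,
            model_policy=raw.get("model_policy", "all"),
            altloc_policy=raw.get("altloc_policy", "highest-occupancy"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(raw)


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest mapping."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "radii_table": structio.DEFAULT_RADII_TABLE_NAME,
        "config": {
            "structure": config.structure,
            "output_dir": config.output_dir,
            "model_policy": config.model_policy,
            "altloc_policy": config.altloc_policy,
            "stages": config.stages,
        },
        "outputs": {},
    }

    model = None
    if config.structure:
        traj = structio.load_structure(
            config.structure,
            model_policy=config.model_policy,
            altloc_policy=config.altloc_policy,
        )
        model = traj[0]

    for name, params in config.stages.items():
        try:
            files = _STAGE_RUNNERS[name](model, params, out)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest["outputs"][name] = files
        logger.info("stage %s wrote %s", name, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_fd(model, params, out: Path) -> list[str]:
    probe = tuple(params.get("probe_radii", fractal.DEFAULT_PROBE_RADII))
    npts = int(params.get("n_sphere_points", 960))
    if params.get("chains"):
        model = structio.select_chains(model, params["chains"])
    profiles = {"assembly": fractal.structure_fd(model, probe, n_sphere_points=npts)}
    if params.get("per_chain"):
        for c, p in fractal.per_chain_fd(model, probe, n_sphere_points=npts).items():
            profiles[f"chain {c}"] = p
    rows = []
    for subject, p in profiles.items():
        for pr, sa in zip(p.probe_radii, p.sasa_values):
            rows.append(
                {
                    "subject": subject,
                    "probe_radius_A": pr,
                    "sasa_A2": sa,
                    "slope": p.slope,
                    "fd": p.fd,
                    "r_squared": p.r_squared,
                }
            )
    path = out / "fd.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path.name]


def _stage_ellipsoid(model, params, out: Path) -> list[str]:
    if params.get("chains"):
        model = structio.select_chains(model, params["chains"])
    if params.get("atoms", "all") == "CA":
        model = model.subset(model.atom_names == "CA")
    fit = ellipsoid.fit_ellipsoid(model.coords)
    summary = ellipsoid.spheroid_summary(fit)
    payload = {
        "coefficients": fit.coefficients.tolist(),
        "center": fit.center.tolist(),
        "radii": fit.radii.tolist(),
        "rotation": fit.rotation.tolist(),
        "rss": fit.rss,
        "r_polar": summary.r_polar,
        "r_equatorial": summary.r_equatorial,
        "shape_class": summary.shape_class,
        "axis_direction": summary.axis_direction.tolist(),
    }
    path = out / "ellipsoid.json"
    path.write_text(json.dumps(payload, indent=2))
    return [path.name]


def _stage_pcn(model, params, out: Path) -> list[str]:
    cal = structio.calpha_coordinates(model)
    net, coords = pcn.build_network(
        cal,
        lower_cut=float(params.get("lower_cut", 4.0)),
        upper_cut=float(params.get("upper_cut", 8.0)),
    )
    files = []
    edges = net.edge_table(coords)
    epath = out / "pcn_edges.csv"
    edges.to_csv(epath, index=False)
    files.append(epath.name)

    k = int(params.get("k", 2))
    part = pcn.spectral_clusters(net, k=k, seed=int(params.get("seed", 0)))
    cmap = pcn.cluster_color_map(part, net.nodes)
    cpath = out / "pcn_clusters.csv"
    cmap.to_csv(cpath, index=False)
    files.append(cpath.name)

    if params.get("bc", True):
        cent = pcn.betweenness(net)
        bc_df = pd.DataFrame(
            {
                "chain": [c for c, _ in net.nodes],
                "residue_number": [r for _, r in net.nodes],
                "bc": cent.bc,
                "tier": cent.tier,
            }
        )
        bpath = out / "pcn_bc.csv"
        bc_df.to_csv(bpath, index=False)
        files.append(bpath.name)

    if len(net.chains) >= 2:
        pairing = pcn.interchain_pairing(net)
        ppath = out / "pcn_pairing.json"
        ppath.write_text(
            json.dumps(
                {
                    "counts": {"-".join(p): c for p, c in pairing.counts.items()},
                    "dominant_pair": list(pairing.dominant_pair)
                    if pairing.dominant_pair
                    else None,
                    "asymmetry": pairing.asymmetry,
                },
                indent=2,
            )
        )
        files.append(ppath.name)
    return files


def _stage_equilibrium(model, params, out: Path) -> list[str]:
    data = equilibrium.TitrationDataset.from_csv(params["data"])
    scheme = {"t3m": "T3M", "t3d2m": "T3_D2_M"}.get(
        str(params.get("scheme", "T3M")).lower(), str(params.get("scheme", "T3M"))
    )
    fit = equilibrium.fit_dissociation(
        data,
        scheme=scheme,
        k2=params.get("k2"),
        n_bootstrap=int(params.get("n_bootstrap", 200)),
        seed=int(params.get("seed", 0)),
    )
    payload = {
        "scheme": fit.scheme,
        "kd_M2": fit.kd,
        "ci95_M2": [fit.ci_low, fit.ci_high],
        "rss": fit.rss,
        "residual_rms_by_technique": fit.residuals_by_technique,
        "n_bootstrap": fit.n_bootstrap,
        "seed": fit.seed,
        "units": {"kd": "M^2", "concentrations": "M"},
    }
    jpath = out / "equilibrium_fit.json"
    jpath.write_text(json.dumps(payload, indent=2))
    grid = np.logspace(
        np.log10(data.c_tot.min()), np.log10(data.c_tot.max()), 100
    )
    curve = equilibrium.monomer_fraction_curve(fit.model(), grid)
    cpath = out / "equilibrium_curve.csv"
    pd.DataFrame({"c_tot_M": grid, "f_monomer": curve}).to_csv(cpath, index=False)
    return [jpath.name, cpath.name]


def _stage_dls(model, params, out: Path) -> list[str]:
    dist = dls.SizeDistribution.from_csv(params["data"])
    payload: dict[str, Any] = {
        "mean_d_nm": dist.mean_d,
        "dispersity": dls.dispersity(dist),
    }
    if params.get("fit_bimodal", True):
        fit = dls.fit_bimodal(dist)
        payload["components"] = [
            {"label": lab, "mean_nm": m, "sd_nm": s, "fraction": f}
            for lab, m, s, f in zip(fit.labels, fit.means, fit.sds, fit.fractions)
        ]
        payload["converged"] = fit.converged
    path = out / "dls.json"
    path.write_text(json.dumps(payload, indent=2))
    return [path.name]


_STAGE_RUNNERS = {
    "fd": _stage_fd,
    "ellipsoid": _stage_ellipsoid,
    "pcn": _stage_pcn,
    "equilibrium": _stage_equilibrium,
    "dls": _stage_dls,
}
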