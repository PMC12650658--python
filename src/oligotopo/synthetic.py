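"""Deterministic synthetic fixtures for every pipeline stage.

Each generator takes an explicit integer seed, uses a single
``numpy.random.Generator`` throughout, and returns its inputs and seed as
machine-readable ground truth so tests can close the loop without any
external data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.spatial.transform import Rotation

from .dls import SizeDistribution
from .equilibrium import EquilibriumModel, TitrationDataset, species_fractions
from .structio import StructureModel


class GenerationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ellipsoid clouds


def gen_ellipsoid_cloud(
    radii: Sequence[float],
    euler_angles: Sequence[float] = (0.0, 0.0, 0.0),
    center: Sequence[float] = (0.0, 0.0, 0.0),
    n: int = 500,
    mode: str = "surface",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Point cloud on (or in) an ellipsoid with known ground truth.

    Surface mode samples area-uniformly (rejection against the surface
    element); filled mode is uniform in volume.  Gaussian noise of the
    requested standard deviation is added isotropically afterwards.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (3,) or np.any(radii <= 0):
        raise GenerationError(f"need 3 positive radii, got {radii}")
    if n < 20:
        raise GenerationError(f"need n >= 20 points, got {n}")
    if mode not in ("surface", "filled"):
        raise GenerationError("mode must be 'surface' or 'filled'")
    rng = np.random.default_rng(seed)
    a, b, c = radii
    if mode == "surface":
        weight_max = max(b * c, a * c, a * b)
        pts = np.empty((n, 3))
        got = 0
        while got < n:
            u = rng.normal(size=(4 * (n - got) + 16, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            w = np.sqrt(
                (b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2 + (a * b * u[:, 2]) ** 2
            )
            keep = rng.uniform(0, weight_max, size=len(u)) < w
            accepted = u[keep] * radii
            take = min(len(accepted), n - got)
            pts[got : got + take] = accepted[:take]
            got += take
    else:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
        pts = u * r * radii
    rot = Rotation.from_euler("xyz", euler_angles).as_matrix()
    pts = pts @ rot.T + np.asarray(center, dtype=float)
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    truth = {
        "kind": "ellipsoid_cloud",
        "radii_sorted": np.sort(radii).tolist(),
        "rotation": rot.tolist(),
        "center": list(map(float, center)),
        "mode": mode,
        "noise_sd": noise_sd,
        "n": n,
        "seed": seed,
    }
    return pts, truth


# ---------------------------------------------------------------------------
# Bead trimers with planted contact structure

_STEP = 3.8  # consecutive-residue Cα spacing, Å
_MIN_SEP = 4.05  # non-consecutive steric floor; keeps pairs out of the window edge


def _compact_walk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random Cα walk confined to a ball, centered at origin."""
    for _ in range(80):  # restarts
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(300):
                step = rng.normal(size=3)
                step *= _STEP / np.linalg.norm(step)
                cand = pts[-1] + step
                if np.linalg.norm(cand) > radius:
                    continue
                if len(pts) > 1:
                    d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                    if (d < _MIN_SEP).any():
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.asarray(pts)
            return arr - arr.mean(axis=0)
    raise GenerationError(
        f"could not grow a self-avoiding walk of {n} beads in radius {radius:.1f} Å"
    )


def _count_window(a: np.ndarray, b: np.ndarray, lo: float = 4.0, hi: float = 8.0) -> int:
    d = cdist(a, b)
    return int(((d > lo) & (d < hi)).sum())


def _triangle_centers(dab: float, dac: float, dbc: float) -> np.ndarray:
    """Centers A, B, C realizing the three pairwise distances (planar)."""
    x = (dab**2 + dac**2 - dbc**2) / (2.0 * dab)
    y2 = dac**2 - x**2
    y = np.sqrt(max(y2, 1e-9))
    return np.array([[0.0, 0.0, 0.0], [dab, 0.0, 0.0], [x, y, 0.0]])


@dataclass
class BeadTrimer:
    model: StructureModel
    planted_labels: np.ndarray  # chain index per residue
    interchain_counts: dict[tuple[str, str], int]
    intra_counts: dict[str, int]
    requested: dict[tuple[str, str], int]
    seed: int


def gen_bead_trimer(
    residues_per_chain: int = 40,
    interchain_contacts: Mapping[tuple[str, str], int] | None = None,
    intra_contact_density: float = 1.0,
    seed: int = 0,
    tolerance: float = 0.2,
) -> BeadTrimer:
    """Three Cα bead chains with approximately planted contact counts.

    Each chain is a compact self-avoiding walk (3.8 Å steps).  Chain
    centers sit on a triangle whose side lengths are adjusted iteratively
    until every requested inter-chain contact count (Cα pairs in the
    strict 4–8 Å window) is within ``tolerance`` relative error; exact
    planting is over-constrained in 3-D, so the achieved counts are
    returned as ground truth.
    """
    n = residues_per_chain
    if n < 20:
        raise GenerationError("need at least 20 residues per chain")
    if intra_contact_density <= 0:
        raise GenerationError("intra_contact_density must be positive")
    req = {("A", "B"): 10, ("A", "C"): 10, ("B", "C"): 10}
    if interchain_contacts:
        for pair, cnt in interchain_contacts.items():
            key = tuple(sorted(pair))
            if key not in req:
                raise GenerationError(f"unknown chain pair {pair}")
            if cnt < 0:
                raise GenerationError("contact counts must be non-negative")
            req[key] = int(cnt)
    if max(req.values()) > n * n // 4:
        raise GenerationError("infeasible contact request: counts too large for chain size")

    rng = np.random.default_rng(seed)
    radius = 3.17 * (n / intra_contact_density) ** (1.0 / 3.0)
    chains = {}
    for name in "ABC":
        walk = _compact_walk(n, radius, rng)
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        chains[name] = walk @ rot.T

    pairs = [("A", "B"), ("A", "C"), ("B", "C")]
    dist = {p: 2.0 * radius + 4.0 for p in pairs}
    best = None
    for _ in range(400):
        centers = _triangle_centers(dist[("A", "B")], dist[("A", "C")], dist[("B", "C")])
        placed = {name: chains[name] + centers[i] for i, name in enumerate("ABC")}
        counts = {
            p: _count_window(placed[p[0]], placed[p[1]]) for p in pairs
        }
        err = max(
            abs(counts[p] - req[p]) / max(req[p], 1) for p in pairs
        )
        if best is None or err < best[0]:
            best = (err, dict(counts), {k: v.copy() for k, v in placed.items()})
        if err <= tolerance:
            break
        for p in pairs:
            target = req[p]
            got = counts[p]
            if target == 0:
                if got > 0:
                    dist[p] *= 1.05
                continue
            if got < target:
                dist[p] *= 0.97 if got > 0 else 0.93
            elif got > target:
                dist[p] *= 1.03
        # keep the triangle realizable
        dab, dac, dbc = dist[("A", "B")], dist[("A", "C")], dist[("B", "C")]
        slack = 0.95 * (dab + dac)
        if dbc > slack:
            dist[("B", "C")] = slack
    err, counts, placed = best
    if err > max(0.5, tolerance):
        raise GenerationError(
            f"infeasible contact request: best achieved {counts} for targets {req}"
        )

    coords = np.concatenate([placed[name] for name in "ABC"])
    chain_ids = np.repeat(list("ABC"), n)
    res_numbers = np.tile(np.arange(1, n + 1), 3)
    model = StructureModel(
        chain_ids=chain_ids,
        residue_numbers=res_numbers,
        residue_names=["GLY"] * (3 * n),
        atom_names=["CA"] * (3 * n),
        elements=["C"] * (3 * n),
        coords=coords,
        vdw_radii=[1.87] * (3 * n),
        source_label=f"bead_trimer(seed={seed})",
    )
    intra = {}
    for name in "ABC":
        d = squareform(pdist(placed[name]))
        intra[name] = int(((d > 4.0) & (d < 8.0)).sum() // 2)
    return BeadTrimer(
        model=model,
        planted_labels=np.repeat(np.arange(3), n),
        interchain_counts=counts,
        intra_counts=intra,
        requested=req,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Titrations


def gen_titration(
    model: EquilibriumModel,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    technique: str = "synthetic",
) -> tuple[TitrationDataset, dict]:
    """Titration points on the model curve plus truncated Gaussian noise."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise GenerationError("all concentrations must be positive")
    rng = np.random.default_rng(seed)
    f = np.array([species_fractions(model, c).f_monomer for c in conc])
    if noise_sd > 0:
        f = np.clip(f + rng.normal(scale=noise_sd, size=len(f)), 0.0, 1.0)
    data = TitrationDataset(c_tot=conc, f_m=f, technique=[technique] * len(conc))
    truth = {
        "kind": "titration",
        "scheme": model.scheme,
        "kd": model.effective_kd,
        "noise_sd": noise_sd,
        "seed": seed,
        "concentrations": conc.tolist(),
    }
    return data, truth


def default_titration_concentrations(n: int = 12) -> np.ndarray:
    """Log-spaced ladder over the 2 nM – 20 µM titration span."""
    return np.logspace(np.log10(2e-9), np.log10(2e-5), n)


# ---------------------------------------------------------------------------
# Size distributions


def gen_size_distribution(
    components: Sequence[tuple[float, float, float]],
    bins: int = 40,
    span: tuple[float, float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[SizeDistribution, dict]:
    """Binned Gaussian-mixture histogram scaled to percent weights.

    ``components`` is a list of (mean nm, sd nm, fraction); fractions must
    sum to 1.  Relative Gaussian noise of amplitude ``noise`` (fraction of
    the peak weight) is added per bin, then weights are clipped at zero
    and renormalized.
    """
    comps = [(float(m), float(s), float(f)) for m, s, f in components]
    if not comps:
        raise GenerationError("need at least one component")
    if any(s <= 0 or m <= 0 for m, s, _ in comps):
        raise GenerationError("means and sds must be positive")
    if not np.isclose(sum(f for _, _, f in comps), 1.0, atol=1e-9):
        raise GenerationError("component fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if span is None:
        lo = min(m - 4 * s for m, s, _ in comps)
        hi = max(m + 4 * s for m, s, _ in comps)
        lo = max(lo, 1e-3)
    else:
        lo, hi = span
    centers = np.linspace(lo, hi, bins)
    w = np.zeros(bins)
    for m, s, f in comps:
        w += f * np.exp(-0.5 * ((centers - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    if noise > 0:
        w = w + rng.normal(scale=noise * w.max(), size=bins)
    w = np.clip(w, 0.0, None)
    dist = SizeDistribution.from_weights(centers, w)
    truth = {
        "kind": "size_distribution",
        "components": comps,
        "bins": bins,
        "noise": noise,
        "seed": seed,
    }
    return dist, truth
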