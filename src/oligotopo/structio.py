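"""Structure I/O, chain selection, SASA and RMSD time series.

Coordinates are read from (multi-model) PDB or mmCIF files into light
array-backed :class:`StructureModel` frames.  Solvent-accessible surface
area uses a deterministic Shrake--Rupley implementation with a fixed
golden-spiral point lattice so repeated runs are bit-stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: Default united-atom van der Waals radii (Å), heavy atoms only.
#: Hydrogens are folded into the heavy-atom radii and dropped at load.
DEFAULT_VDW_RADII: Mapping[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
}

DEFAULT_RADII_TABLE_NAME = "united-heavy-default"

_WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "SOL", "TIP3"})


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


@dataclass(frozen=True)
class Atom:
    """A single atom with chain/residue identity and coordinates."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    vdw_radius: float
    insertion_code: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite or malformed position: {pos!r}")
        object.__setattr__(self, "position", pos)
        if not self.vdw_radius > 0:
            raise StructureError(f"vdw_radius must be > 0, got {self.vdw_radius}")


class StructureModel:
    """One frame of atomic coordinates, stored as parallel arrays.

    Parameters mirror PDB ATOM records; (chain_id, residue_number,
    insertion_code, atom_name) must be unique within a frame.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        vdw_radii: Sequence[float],
        insertion_codes: Sequence[str] | None = None,
        frame_index: int = 0,
        source_label: str = "",
    ) -> None:
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U5")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.vdw_radii = np.asarray(vdw_radii, dtype=float)
        n = len(self.coords)
        if insertion_codes is None:
            insertion_codes = [""] * n
        self.insertion_codes = np.asarray(insertion_codes, dtype="U2")
        self.frame_index = int(frame_index)
        self.source_label = source_label
        self._validate()

    def _validate(self) -> None:
        n = len(self.coords)
        if n < 1:
            raise StructureError("structure has no atoms")
        for name, arr in (
            ("chain_ids", self.chain_ids),
            ("residue_numbers", self.residue_numbers),
            ("residue_names", self.residue_names),
            ("atom_names", self.atom_names),
            ("elements", self.elements),
            ("vdw_radii", self.vdw_radii),
            ("insertion_codes", self.insertion_codes),
        ):
            if len(arr) != n:
                raise StructureError(f"{name} length {len(arr)} != {n} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if not np.all(self.vdw_radii > 0):
            raise StructureError("all vdw radii must be > 0")
        keys = list(
            zip(
                self.chain_ids.tolist(),
                self.residue_numbers.tolist(),
                self.insertion_codes.tolist(),
                self.atom_names.tolist(),
            )
        )
        if len(set(keys)) != n:
            raise StructureError(
                "(chain, residue, insertion code, atom name) not unique in frame"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        """Unique chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                chain_id=str(self.chain_ids[i]),
                residue_number=int(self.residue_numbers[i]),
                residue_name=str(self.residue_names[i]),
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                position=self.coords[i].copy(),
                vdw_radius=float(self.vdw_radii[i]),
                insertion_code=str(self.insertion_codes[i]),
            )

    def subset(self, mask: np.ndarray, frame_index: int | None = None) -> "StructureModel":
        """New model keeping atoms where ``mask`` is true, order preserved."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise StructureError("selection removes every atom")
        return StructureModel(
            self.chain_ids[mask],
            self.residue_numbers[mask],
            self.residue_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.coords[mask],
            self.vdw_radii[mask],
            self.insertion_codes[mask],
            frame_index=self.frame_index if frame_index is None else frame_index,
            source_label=self.source_label,
        )

    def translated(self, shift: np.ndarray) -> "StructureModel":
        out = self.subset(np.ones(self.n_atoms, bool))
        out.coords = out.coords + np.asarray(shift, float)
        return out

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "StructureModel":
        out = self.subset(np.ones(self.n_atoms, bool))
        out.coords = out.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return out


@dataclass
class Trajectory:
    """Ordered frames with identical atom identity plus frame times."""

    frames: list[StructureModel]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory has no frames")
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise StructureError("times length must match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("times must be strictly increasing")
        first = self.frames[0]
        ident = _identity_tuple(first)
        for fr in self.frames[1:]:
            if fr.n_atoms != first.n_atoms or _identity_tuple(fr) != ident:
                raise StructureError("all frames must share atom count and identity")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> StructureModel:
        return self.frames[i]


def _identity_tuple(model: StructureModel):
    return (
        tuple(model.chain_ids.tolist()),
        tuple(model.residue_numbers.tolist()),
        tuple(model.atom_names.tolist()),
    )


# ---------------------------------------------------------------------------
# Loading / writing


def _assign_radii(
    elements: np.ndarray,
    radii: Mapping[str, float],
    default_radius: float | None,
) -> np.ndarray:
    out = np.empty(len(elements), dtype=float)
    for i, el in enumerate(elements):
        key = str(el).upper()
        if key in radii:
            out[i] = radii[key]
        elif default_radius is not None:
            out[i] = default_radius
        else:
            raise StructureError(
                f"no van der Waals radius for element {key!r} and no default given"
            )
    return out


def load_structure(
    path: str | Path,
    model_policy: str = "all",
    altloc_policy: str = "highest-occupancy",
    radii: Mapping[str, float] | None = None,
    default_radius: float | None = None,
    keep_hetero: bool = False,
    drop_hydrogens: bool = True,
) -> Trajectory:
    """Read a PDB (or mmCIF) file into a :class:`Trajectory`.

    One frame per MODEL record (``model_policy='all'``) or just the first
    (``'first'``).  Altloc duplicates are resolved to a single copy, by
    maximum occupancy (``'highest-occupancy'``, ties to the first listed
    altloc letter) or by taking the first altloc (``'A'``).  Water and,
    unless ``keep_hetero``, all HETATM records are stripped; hydrogens are
    dropped by default to match the united-atom radii table.
    """
    import biotite.structure as bst
    import biotite.structure.io.pdb as bpdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    if altloc_policy not in ("highest-occupancy", "A"):
        raise ValueError(
            f"altloc_policy must be 'highest-occupancy' or 'A', got {altloc_policy!r}"
        )
    altloc = "occupancy" if altloc_policy == "highest-occupancy" else "first"

    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        import biotite.structure.io.pdbx as bpdbx

        cif = bpdbx.CIFFile.read(str(path))
        stack = bpdbx.get_structure(cif, model=None, altloc=altloc)
    else:
        try:
            pdb = bpdb.PDBFile.read(str(path))
            stack = pdb.get_structure(model=None, altloc=altloc)
        except Exception as exc:  # unreadable / malformed
            raise StructureError(f"cannot parse {path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    if stack.array_length() == 0:
        raise StructureError(f"{path}: no ATOM records")

    mask = ~np.isin(stack.res_name, list(_WATER_RESNAMES))
    if not keep_hetero:
        mask &= ~stack.hetero
    if drop_hydrogens:
        mask &= ~np.isin(np.char.upper(stack.element), ["H", "D"])
    if not mask.any():
        raise StructureError(f"{path}: no atoms left after filtering")
    stack = stack[..., mask]

    n_models = stack.stack_depth()
    if model_policy == "first":
        n_models = 1
    radii_table = DEFAULT_VDW_RADII if radii is None else radii
    vdw = _assign_radii(stack.element, radii_table, default_radius)

    frames = []
    for m in range(n_models):
        arr = stack[m]
        frames.append(
            StructureModel(
                chain_ids=arr.chain_id,
                residue_numbers=arr.res_id,
                residue_names=arr.res_name,
                atom_names=arr.atom_name,
                elements=arr.element,
                coords=arr.coord,
                vdw_radii=vdw,
                insertion_codes=arr.ins_code,
                frame_index=m,
                source_label=path.name,
            )
        )
    logger.info("loaded %s: %d frame(s), %d atoms", path.name, len(frames), frames[0].n_atoms)
    return Trajectory(frames=frames)


def write_structure(traj: Trajectory | StructureModel, path: str | Path) -> None:
    """Write frames back out as a (multi-model) PDB file."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as bpdb

    if isinstance(traj, StructureModel):
        traj = Trajectory(frames=[traj])
    arrays = []
    for fr in traj.frames:
        arr = bst.AtomArray(fr.n_atoms)
        arr.chain_id = fr.chain_ids
        arr.res_id = fr.residue_numbers
        arr.res_name = fr.residue_names
        arr.atom_name = fr.atom_names
        arr.element = fr.elements
        arr.ins_code = fr.insertion_codes
        arr.coord = fr.coords
        arr.hetero = np.zeros(fr.n_atoms, dtype=bool)
        arrays.append(arr)
    pdb = bpdb.PDBFile()
    pdb.set_structure(bst.stack(arrays) if len(arrays) > 1 else arrays[0])
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections


def select_chains(model: StructureModel, chains: Iterable[str]) -> StructureModel:
    """Keep only atoms of the requested chains, preserving order."""
    chains = set(chains)
    present = set(model.chains)
    missing = chains - present
    if missing:
        raise StructureError(
            f"chain(s) {sorted(missing)} not present (available: {sorted(present)})"
        )
    return model.subset(np.isin(model.chain_ids, list(chains)))


def calpha_coordinates(
    model: StructureModel,
) -> list[tuple[str, int, np.ndarray]]:
    """(chain, residue number, position) for every residue with a CA atom.

    Residues lacking a CA are skipped with a warning; zero CA atoms is an
    error.
    """
    is_ca = model.atom_names == "CA"
    if not is_ca.any():
        raise StructureError("model contains no CA atoms")
    # Residues present but without CA -> warn.
    all_res = set(
        zip(model.chain_ids.tolist(), model.residue_numbers.tolist(), model.insertion_codes.tolist())
    )
    ca_res = set(
        zip(
            model.chain_ids[is_ca].tolist(),
            model.residue_numbers[is_ca].tolist(),
            model.insertion_codes[is_ca].tolist(),
        )
    )
    for chain, resnum, icode in sorted(all_res - ca_res):
        warnings.warn(
            f"residue {chain}{resnum}{icode} has no CA atom; skipped", stacklevel=2
        )
    idx = np.flatnonzero(is_ca)
    return [
        (str(model.chain_ids[i]), int(model.residue_numbers[i]), model.coords[i].copy())
        for i in idx
    ]


# ---------------------------------------------------------------------------
# SASA (deterministic Shrake-Rupley)


@lru_cache(maxsize=8)
def _golden_sphere(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere lattice of n points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = np.empty((n, 3))
    pts[:, 0] = np.cos(theta) * np.sin(phi)
    pts[:, 1] = np.sin(theta) * np.sin(phi)
    pts[:, 2] = np.cos(phi)
    return pts


class SasaResult(NamedTuple):
    total: float
    per_atom: np.ndarray


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaResult:
    """Shrake--Rupley solvent-accessible surface area (Å²).

    Total equals the sum of per-atom areas.  Deterministic: the test
    sphere is a fixed golden-spiral lattice, never randomized.
    """
    if not probe_radius > 0:
        raise ValueError(f"probe_radius must be > 0, got {probe_radius}")
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100")
    coords = model.coords
    expanded = model.vdw_radii + probe_radius
    n = len(coords)
    unit = _golden_sphere(n_sphere_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        touching = d < expanded[pairs[:, 0]] + expanded[pairs[:, 1]]
        for a, b in pairs[touching]:
            neighbors[a].append(b)
            neighbors[b].append(a)

    per_atom = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        nbr = neighbors[i]
        if nbr:
            nc = coords[nbr]
            nr2 = expanded[nbr] ** 2
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = ~(d2 < nr2[None, :]).any(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ri * ri
    return SasaResult(total=float(per_atom.sum()), per_atom=per_atom)


# ---------------------------------------------------------------------------
# RMSD time series


class RmsdSeries(NamedTuple):
    times: np.ndarray
    rmsd: np.ndarray
    smoothed: np.ndarray
    derivative: np.ndarray


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    # centered window, shrunk at the edges
    out = np.empty_like(y, dtype=float)
    half = window // 2
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def rmsd_series(
    traj: Trajectory,
    reference: int = 0,
    selection: str = "CA",
    superpose: bool = True,
    smooth_window: int = 5,
) -> RmsdSeries:
    """Per-frame RMSD to a reference frame plus a smoothed first derivative.

    With ``superpose=True`` each frame is optimally superposed on the
    reference (Kabsch least squares) before the deviation is measured.
    The derivative is central differences on a moving-average-smoothed
    series.
    """
    if len(traj) < 2:
        raise ValueError("rmsd_series needs at least 2 frames")
    if selection not in ("CA", "all"):
        raise ValueError("selection must be 'CA' or 'all'")
    ref = traj[reference]
    if selection == "CA":
        mask = ref.atom_names == "CA"
        if not mask.any():
            raise StructureError("no CA atoms for RMSD selection")
    else:
        mask = np.ones(ref.n_atoms, dtype=bool)
    ref_xyz = ref.coords[mask]
    n = len(ref_xyz)
    ref_centered = ref_xyz - ref_xyz.mean(axis=0)

    rmsd = np.empty(len(traj))
    for k, fr in enumerate(traj.frames):
        if fr.n_atoms != ref.n_atoms:
            raise StructureError("frame atom counts differ")
        xyz = fr.coords[mask]
        if superpose:
            mov = xyz - xyz.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_centered, mov)
            diff = ref_centered - rot.apply(mov)
            rmsd[k] = np.sqrt((diff**2).sum(axis=1).mean())
        else:
            rmsd[k] = np.sqrt(((xyz - ref_xyz) ** 2).sum(axis=1).mean())
    smoothed = _moving_average(rmsd, smooth_window)
    derivative = np.gradient(smoothed, traj.times)
    return RmsdSeries(times=traj.times.copy(), rmsd=rmsd, smoothed=smoothed, derivative=derivative)
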