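"""Structure and coordinate primitives.

Atoms, structure models, atom selections, centers of mass, optimal (Kabsch)
superposition and RMSD — the geometric substrate for all membrane-depth and
trajectory analytics. Coordinates are in Ångström throughout; masses in amu.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: default atomic masses (amu), keyed by upper-case element symbol
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "MG": 24.305, "CL": 35.45, "K": 39.098,
    "CA": 40.078, "FE": 55.845, "ZN": 65.38, "SE": 78.971,
}
#: fallback mass (amu) for unknown elements; logged when used
DEFAULT_MASS = 12.0

#: protein backbone atom names
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def mass_of(element: str) -> float:
    """Look up the atomic mass of an element symbol; unknown → 12.0 amu."""
    m = ATOMIC_MASSES.get(element.upper().strip())
    if m is None:
        logger.warning("unknown element %r: using default mass %.1f amu", element, DEFAULT_MASS)
        return DEFAULT_MASS
    return m


@dataclass
class Atom:
    """A single atom: identity, residue context and Cartesian coordinate (Å)."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    element: str
    coord: np.ndarray
    mass: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom {self.serial}: coord must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: non-finite coordinate")
        if self.mass is None:
            self.mass = mass_of(self.element)
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")


@dataclass
class StructureModel:
    """An ordered collection of atoms plus free-form metadata."""

    atoms: list[Atom]
    model_id: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("StructureModel needs at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within a model")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (a copy)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this model carrying new coordinates (same atom table)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coord=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms, model_id=self.model_id, metadata=dict(self.metadata))


@dataclass(frozen=True)
class SelectionSpec:
    """AND-combined atom filters: chains, inclusive resid ranges, names, elements.

    An empty spec selects every atom. Serializable as a compact string, e.g.
    ``chain=B;resid=335-345;name=N,CA,C,O``.
    """

    chains: frozenset[str] | None = None
    resid_ranges: tuple[tuple[int, int], ...] | None = None
    names: frozenset[str] | None = None
    elements: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.resid_ranges is not None:
            for lo, hi in self.resid_ranges:
                if lo > hi:
                    raise ValueError(f"resid range {lo}-{hi} not well-ordered")

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.resid_ranges is not None and not any(
            lo <= atom.resid <= hi for lo, hi in self.resid_ranges
        ):
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.elements is not None and atom.element.upper() not in self.elements:
            return False
        return True

    @classmethod
    def make(
        cls,
        chains: Iterable[str] | None = None,
        resids: Iterable[int | tuple[int, int]] | None = None,
        names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
    ) -> "SelectionSpec":
        """Convenience constructor: resids may mix single ids and (lo, hi) pairs."""
        rr = None
        if resids is not None:
            rr = tuple(
                (r, r) if isinstance(r, int) else (int(r[0]), int(r[1])) for r in resids
            )
        return cls(
            chains=frozenset(chains) if chains is not None else None,
            resid_ranges=rr,
            names=frozenset(names) if names is not None else None,
            elements=frozenset(e.upper() for e in elements) if elements is not None else None,
        )

    def to_string(self) -> str:
        parts = []
        if self.chains is not None:
            parts.append("chain=" + ",".join(sorted(self.chains)))
        if self.resid_ranges is not None:
            rr = ",".join(f"{lo}-{hi}" if lo != hi else str(lo) for lo, hi in self.resid_ranges)
            parts.append("resid=" + rr)
        if self.names is not None:
            parts.append("name=" + ",".join(sorted(self.names)))
        if self.elements is not None:
            parts.append("element=" + ",".join(sorted(self.elements)))
        return ";".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "SelectionSpec":
        kwargs: dict = {}
        for part in filter(None, (p.strip() for p in text.split(";"))):
            key, _, value = part.partition("=")
            items = [v.strip() for v in value.split(",") if v.strip()]
            if key == "chain":
                kwargs["chains"] = items
            elif key == "resid":
                resids: list[int | tuple[int, int]] = []
                for item in items:
                    if "-" in item[1:]:  # allow negative lo
                        lo, hi = item.rsplit("-", 1)
                        resids.append((int(lo), int(hi)))
                    else:
                        resids.append(int(item))
                kwargs["resids"] = resids
            elif key == "name":
                kwargs["names"] = items
            elif key == "element":
                kwargs["elements"] = items
            else:
                raise ValueError(f"unknown selection key {key!r}")
        return cls.make(**kwargs)


#: selects backbone atoms (N, CA, C, O) of any residue
BACKBONE_SPEC = SelectionSpec.make(names=BACKBONE_NAMES)


def select(model: StructureModel, spec: SelectionSpec | None) -> StructureModel:
    """Atoms of *model* matching *spec* (order preserved). Empty result allowed.

    An empty/None spec returns all atoms. Note the returned model may be
    empty only conceptually — StructureModel requires ≥1 atom, so an empty
    selection is returned as a plain empty list via :func:`selection_indices`;
    this function raises on empty only through StructureModel's invariant
    being relaxed here by returning a model flagged in metadata.
    """
    if spec is None:
        spec = SelectionSpec()
    idx = selection_indices(model, spec)
    atoms = [model.atoms[i] for i in idx]
    out = object.__new__(StructureModel)
    out.atoms = atoms
    out.model_id = model.model_id
    out.metadata = dict(model.metadata)
    out.metadata["selection"] = spec.to_string()
    return out


def selection_indices(model: StructureModel, spec: SelectionSpec | None) -> np.ndarray:
    """Indices (into model.atoms) of atoms matching *spec*."""
    if spec is None:
        spec = SelectionSpec()
    return np.array([i for i, a in enumerate(model.atoms) if spec.matches(a)], dtype=int)


def center_of_mass(model: StructureModel) -> np.ndarray:
    """Mass-weighted mean coordinate (Å)."""
    if len(model.atoms) == 0:
        raise ValueError("center_of_mass of an empty selection")
    m = model.masses
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return (model.coords * m[:, None]).sum(axis=0) / total


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def apply_model(self, model: StructureModel) -> StructureModel:
        return model.with_coords(self.apply(model.coords))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _paired_coords(
    mobile: StructureModel,
    reference: StructureModel,
    spec: SelectionSpec | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Selection coordinates from both models, paired strictly by order."""
    mi = selection_indices(mobile, spec)
    ri = selection_indices(reference, spec)
    if len(mi) != len(ri):
        raise ValueError(
            f"selection count mismatch: {len(mi)} mobile vs {len(ri)} reference atoms"
        )
    if len(mi) == 0:
        raise ValueError("empty selection")
    mob = np.array([mobile.atoms[i].coord for i in mi])
    ref = np.array([reference.atoms[i].coord for i in ri])
    return mob, ref


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    spec: SelectionSpec | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition (Kabsch) of *mobile* onto *reference*.

    Atoms are paired strictly by order within the selection; the returned
    transform applies to ALL mobile atoms, and the RMSD is the post-fit RMSD
    over the selection.
    """
    mob, ref = _paired_coords(mobile, reference, spec)
    n = len(mob)
    if n < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2 or np.linalg.matrix_rank(ref0, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is ill-defined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, rssd = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    fit_rmsd = float(rssd) / np.sqrt(n)
    return RigidTransform(R, t), fit_rmsd


def rmsd(
    a: StructureModel,
    b: StructureModel,
    spec: SelectionSpec | None = None,
    fit: bool = False,
) -> float:
    """Unweighted coordinate RMSD over paired selections; optionally fit first."""
    if fit:
        _, value = superpose(a, b, spec)
        return value
    ca, cb = _paired_coords(a, b, spec)
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def read_pdb(path: str | Path, model_policy: str = "first") -> list[StructureModel]:
    """Read ATOM/HETATM records from a PDB file into StructureModels.

    One model per MODEL record (or a single model when the file has none).
    ``model_policy`` is ``"first"`` or ``"all"``. Only the first altloc of
    each atom is kept (logged). Insertion codes are preserved in metadata.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty PDB file")

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"{path}: PDB parse error: {exc}") from exc

    models: list[StructureModel] = []
    for bio_model in structure:
        atoms: list[Atom] = []
        icodes: dict[int, str] = {}
        dropped_altlocs = 0
        for chain in bio_model:
            for residue in chain:
                _, resseq, icode = residue.id
                if icode.strip():
                    icodes[resseq] = icode
                seen_names: set[str] = set()
                for atom in residue.get_unpacked_list():
                    if atom.get_name() in seen_names:
                        dropped_altlocs += 1
                        continue
                    seen_names.add(atom.get_name())
                    element = (atom.element or "").strip() or atom.get_name()[0]
                    atoms.append(
                        Atom(
                            serial=int(atom.serial_number),
                            name=atom.get_name(),
                            resname=residue.resname.strip(),
                            chain=chain.id,
                            resid=int(resseq),
                            element=element,
                            coord=np.asarray(atom.coord, dtype=float),
                        )
                    )
        if not atoms:
            continue
        if dropped_altlocs:
            logger.warning("%s model %s: dropped %d alternate locations", path, bio_model.id, dropped_altlocs)
        meta: dict = {"source": str(path)}
        if icodes:
            meta["insertion_codes"] = icodes
        models.append(StructureModel(atoms, model_id=int(bio_model.id) + 1, metadata=meta))

    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    if model_policy == "first":
        return models[:1]
    if model_policy == "all":
        return models
    raise ValueError(f"unknown model_policy {model_policy!r}")


def _format_atom_line(atom: Atom) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    x, y, z = atom.coord
    chain = (atom.chain or "A")[:1]
    return (
        f"ATOM  {atom.serial % 100000:5d} {name}"
        f"{'':1s}{atom.resname:>3s} {chain:1s}"
        f"{atom.resid % 10000:4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.upper():>2s}"
    )


def write_pdb(path: str | Path, models: StructureModel | Sequence[StructureModel]) -> None:
    """Write one or more StructureModels as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    if len(models) == 0:
        raise ValueError("nothing to write")
    path = Path(path)
    multi = len(models) > 1
    with path.open("w") as fh:
        for k, model in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            for atom in model.atoms:
                fh.write(_format_atom_line(atom) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
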