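"""Membrane layer models and per-residue depth metrics.

A bilayer is summarized as flat z-levels: the phosphate (P) layer, the
acyl-chain carbon-5 (C5) layer and the carbonyl (CO) plane, one set per
leaflet. Depths of protein sites are measured as |Δz| between a site's Cα
and a layer's mean z — ``dist_P`` and ``dist_C5`` — with a separate flag for
whether the site lies beyond the layer on the membrane-core side.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import Atom, StructureModel, center_of_mass

#: default lipid atom names per layer class (config-driven: nomenclature
#: varies across force fields)
DEFAULT_CLASS_NAMES: dict[str, frozenset[str]] = {
    "P": frozenset({"P"}),
    "C5": frozenset({"C5"}),
    "CO": frozenset({"CO"}),
}

#: default distance-bin edges (Å); a 4 Å "close" variant is available by
#: passing edges=(4, 10, 15)
DEFAULT_BIN_EDGES: tuple[float, ...] = (5.0, 10.0, 15.0)
BIN_LABELS: tuple[str, ...] = ("close", "near", "intermediate", "far")


@dataclass(frozen=True)
class LayerModel:
    """One lipid layer of one leaflet, summarized as mean z ± spread (Å)."""

    leaflet: str            # "upper" | "lower"
    atom_class: str         # "P" | "C5" | "CO"
    z_mean: float
    z_sd: float
    n_atoms: int

    def __post_init__(self) -> None:
        if self.leaflet not in ("upper", "lower"):
            raise ValueError(f"leaflet must be upper|lower, got {self.leaflet!r}")
        if self.n_atoms < 1:
            raise ValueError("LayerModel needs at least one atom")
        if self.z_sd < 0:
            raise ValueError("z_sd must be non-negative")

    def core_side_sign(self) -> float:
        """+1 if the membrane core lies at larger z than this layer, else −1."""
        return 1.0 if self.leaflet == "lower" else -1.0


@dataclass
class MembraneSystem:
    """Per-leaflet layer models with the membrane normal fixed to z."""

    layers: list[LayerModel]
    proximal: str = "lower"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("MembraneSystem needs at least one layer")
        if self.proximal not in ("upper", "lower"):
            raise ValueError("proximal leaflet must be upper|lower")
        self._check_ordering()

    def _check_ordering(self) -> None:
        # when all three classes are present in a leaflet, P must be the
        # outermost and C5 the innermost relative to the bilayer mid-plane
        zs = [l.z_mean for l in self.layers]
        mid = 0.5 * (min(zs) + max(zs)) if len(zs) > 1 else zs[0]
        for leaflet in ("upper", "lower"):
            by_class = {l.atom_class: l for l in self.layers if l.leaflet == leaflet}
            if {"P", "CO", "C5"} <= set(by_class):
                d = {c: abs(by_class[c].z_mean - mid) for c in ("P", "CO", "C5")}
                if not (d["P"] >= d["CO"] >= d["C5"]):
                    raise ValueError(
                        f"{leaflet} leaflet: layer z-order must be P outermost, "
                        f"then CO, then C5 toward the core"
                    )

    def get_layer(self, leaflet: str, atom_class: str) -> LayerModel:
        for layer in self.layers:
            if layer.leaflet == leaflet and layer.atom_class == atom_class:
                return layer
        raise KeyError(f"no {atom_class} layer for {leaflet} leaflet")


@dataclass(frozen=True)
class DepthRecord:
    """Per-site membrane depths against the proximal leaflet's layers."""

    site: int
    dist_P: float
    dist_C5: float
    inserted_beyond_P: bool
    inserted_beyond_C5: bool

    def __post_init__(self) -> None:
        if self.dist_P < 0 or self.dist_C5 < 0:
            raise ValueError("distances must be non-negative")


def compute_layer(
    frame: StructureModel,
    atom_class: str,
    leaflet_split_z: float | None = None,
    class_names: dict[str, frozenset[str]] | None = None,
    leaflets: tuple[str, ...] | None = None,
) -> dict[str, LayerModel]:
    """Mean and sample-sd of z of the lipid atoms of one class, per leaflet.

    Leaflets are assigned by side of ``leaflet_split_z`` (default: the
    mass-weighted COM z of all lipid-layer atoms in the frame). Returns a dict
    keyed by leaflet; a requested leaflet with no matching atoms is an error.
    """
    names = (class_names or DEFAULT_CLASS_NAMES)[atom_class]
    all_layer_names = frozenset().union(*(class_names or DEFAULT_CLASS_NAMES).values())

    class_atoms = [a for a in frame.atoms if a.name in names]
    if not class_atoms:
        raise ValueError(f"no atoms of class {atom_class} in frame")

    if leaflet_split_z is None:
        lipid_atoms = [a for a in frame.atoms if a.name in all_layer_names]
        masses = np.array([a.mass for a in lipid_atoms])
        zs = np.array([a.coord[2] for a in lipid_atoms])
        leaflet_split_z = float((masses * zs).sum() / masses.sum())

    groups: dict[str, list[float]] = {"upper": [], "lower": []}
    for a in class_atoms:
        side = "upper" if a.coord[2] >= leaflet_split_z else "lower"
        groups[side].append(a.coord[2])

    if leaflets is None:
        leaflets = tuple(l for l in ("upper", "lower") if groups[l])

    out: dict[str, LayerModel] = {}
    for leaflet in leaflets:
        zs = groups[leaflet]
        if not zs:
            raise ValueError(f"no {atom_class} atoms in {leaflet} leaflet")
        arr = np.asarray(zs)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[leaflet] = LayerModel(leaflet, atom_class, float(arr.mean()), sd, len(arr))
    return out


def build_membrane_system(
    frame: StructureModel,
    protein: StructureModel | None = None,
    class_names: dict[str, frozenset[str]] | None = None,
    leaflet_split_z: float | None = None,
    proximal: str | None = None,
) -> MembraneSystem:
    """Compute all available P/CO/C5 layers of a frame.

    The proximal leaflet defaults to the one whose P layer lies nearest the
    protein's COM z (override with ``proximal``).
    """
    layers: list[LayerModel] = []
    for atom_class in (class_names or DEFAULT_CLASS_NAMES):
        try:
            per_leaflet = compute_layer(frame, atom_class, leaflet_split_z, class_names)
        except ValueError:
            continue
        layers.extend(per_leaflet.values())
    if not layers:
        raise ValueError("frame contains no recognizable lipid layer atoms")

    if proximal is None:
        if protein is None:
            raise ValueError("need a protein model (or explicit proximal=) to tag the proximal leaflet")
        com_z = center_of_mass(protein)[2]
        p_layers = [l for l in layers if l.atom_class == "P"]
        if not p_layers:
            raise ValueError("no P layers found; cannot determine proximal leaflet")
        proximal = min(p_layers, key=lambda l: abs(l.z_mean - com_z)).leaflet
    return MembraneSystem(layers, proximal=proximal)


def depth(site_atom: Atom, layer: LayerModel) -> tuple[float, bool]:
    """(|Δz| to the layer, inserted-beyond flag).

    The flag is true iff the atom lies strictly on the membrane-core side of
    the layer (an atom exactly at the layer counts as not inserted).
    """
    dz = site_atom.coord[2] - layer.z_mean
    inserted = dz * layer.core_side_sign() > 0
    return abs(float(dz)), bool(inserted)


def classify_distance_bin(d: float, edges: tuple[float, ...] = DEFAULT_BIN_EDGES) -> str:
    """Half-open, lower-inclusive distance bins: [0,5) close, [5,10) near,
    [10,15) intermediate, [15,∞) far (with the default edges)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    idx = int(np.searchsorted(edges, d, side="right"))
    if len(edges) == 3:
        return BIN_LABELS[idx]
    bounds = (0.0,) + edges + (np.inf,)
    return f"[{bounds[idx]:g},{bounds[idx+1]:g})"


def site_depth_map(
    frame: StructureModel,
    sites: list[int],
    membrane: MembraneSystem,
) -> list[DepthRecord]:
    """Dist_P / Dist_C5 of each site's Cα against the proximal leaflet."""
    p_layer = membrane.get_layer(membrane.proximal, "P")
    c5_layer = membrane.get_layer(membrane.proximal, "C5")
    ca_by_resid: dict[int, Atom] = {}
    for a in frame.atoms:
        if a.name == "CA" and a.resid not in ca_by_resid:
            ca_by_resid[a.resid] = a
    records: list[DepthRecord] = []
    for site in sites:
        ca = ca_by_resid.get(site)
        if ca is None:
            raise ValueError(f"site {site}: no Cα atom in frame")
        d_p, ins_p = depth(ca, p_layer)
        d_c5, ins_c5 = depth(ca, c5_layer)
        records.append(DepthRecord(site, d_p, d_c5, ins_p, ins_c5))
    return records


def depth_map_to_frame(
    records: list[DepthRecord],
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Tidy table: site, dist_P, dist_C5, bin_P, bin_C5, insertion flags."""
    return pd.DataFrame(
        {
            "site": [r.site for r in records],
            "dist_P": [r.dist_P for r in records],
            "dist_C5": [r.dist_C5 for r in records],
            "bin_P": [classify_distance_bin(r.dist_P, edges) for r in records],
            "bin_C5": [classify_distance_bin(r.dist_C5, edges) for r in records],
            "inserted_beyond_P": [r.inserted_beyond_P for r in records],
            "inserted_beyond_C5": [r.inserted_beyond_C5 for r in records],
        }
    )
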