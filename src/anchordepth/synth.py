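"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their spec (the seed lives inside the
spec): identical inputs give bit-identical outputs. They return ground-truth
objects alongside the data so analysis modules can be tested in closed loop.

What is emulated — and what is not: membranes are three pseudo-atoms per
lipid (P, CO, C5) on jittered flat z-layers of an 80 × 80 Å patch, with no
acyl-chain geometry, curvature or force-field energetics; the toy C-domain
is a Cα site panel plus an 11-residue anchor loop with two planted backbone
conformers, not a folded β-sandwich; trajectories are scripted rigid-body
z-paths with isotropic Gaussian coordinate noise, not dynamics; spectra are
single Gaussian bands with planted quenching factors and wavelength shifts
plus multiplicative noise and a deterministic instrument baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coords import Atom, SelectionSpec, StructureModel
from .fluor import EmissionSpectrum
from .membrane import LayerModel, MembraneSystem
from .trajectory import InsertionEvent, TrajectorySeries

# --------------------------------------------------------------------------
# Membrane
# --------------------------------------------------------------------------

#: default layer z-levels (Å): P outermost, then CO, then C5 toward the core,
#: for a bilayer centred at z = 0 (head-group–to–head-group span ≈ 40 Å)
DEFAULT_LAYER_Z: dict[str, dict[str, float]] = {
    "upper": {"P": 20.0, "CO": 17.5, "C5": 12.0},
    "lower": {"P": -20.0, "CO": -17.5, "C5": -12.0},
}


@dataclass(frozen=True)
class MembraneSpec:
    box: tuple[float, float] = (80.0, 80.0)
    lipids_per_leaflet: int = 100
    layer_z: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_LAYER_Z
    )
    jitter: float = 0.3         # per-atom z jitter σ, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        for leaflet, z in self.layer_z.items():
            mid = 0.0
            if not abs(z["P"] - mid) >= abs(z["CO"] - mid) >= abs(z["C5"] - mid):
                raise ValueError(f"{leaflet} leaflet: P must be outermost, C5 innermost")


def make_membrane_frame(spec: MembraneSpec) -> tuple[StructureModel, MembraneSystem]:
    """Pseudo-lipid atoms (P/CO/C5 per lipid) on jittered layers + ground truth.

    Ground-truth LayerModels carry the *planted* z and jitter, not the
    realized sample statistics.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    layers: list[LayerModel] = []
    serial = 1
    resid = 0
    for leaflet, chain in (("upper", "U"), ("lower", "L")):
        xy = rng.uniform([0, 0], spec.box, size=(spec.lipids_per_leaflet, 2))
        jz = {
            cls: rng.normal(0.0, spec.jitter, size=spec.lipids_per_leaflet)
            if spec.jitter > 0
            else np.zeros(spec.lipids_per_leaflet)
            for cls in ("P", "CO", "C5")
        }
        for i in range(spec.lipids_per_leaflet):
            resid += 1
            for cls, element in (("P", "P"), ("CO", "C"), ("C5", "C")):
                z = spec.layer_z[leaflet][cls] + jz[cls][i]
                atoms.append(
                    Atom(serial, cls, "SDP", chain, resid, element,
                         np.array([xy[i, 0], xy[i, 1], z]))
                )
                serial += 1
        for cls in ("P", "CO", "C5"):
            layers.append(
                LayerModel(leaflet, cls, spec.layer_z[leaflet][cls],
                           spec.jitter, spec.lipids_per_leaflet)
            )
    frame = StructureModel(atoms, metadata={
        "generator": "make_membrane_frame",
        "noise_model": f"isotropic-z Gaussian, sigma={spec.jitter} A",
        "seed": spec.seed,
    })
    return frame, MembraneSystem(layers, proximal="lower")


# --------------------------------------------------------------------------
# Toy C-domain with a site panel and two loop-conformer templates
# --------------------------------------------------------------------------

#: the 16-site mutant panel; offset = signed z distance from the proximal
#: (lower-leaflet) P layer, positive = beyond P toward the membrane core
DEFAULT_SITE_OFFSETS: dict[int, float] = {
    72: -25.0, 75: -28.0, 94: -30.0, 139: -11.0, 159: -14.0, 161: -13.0,
    163: -16.0, 197: 2.0, 229: -20.0, 230: -10.0, 251: -18.0, 271: -20.0,
    334: -10.0, 339: 1.5, 342: 2.5, 344: 1.0,
}

LOOP_RESIDS = tuple(range(335, 346))
#: CV selection: Cα of residues 338–342 (the anchor-loop centre of mass)
LOOP_CV_SPEC = SelectionSpec.make(resids=[(338, 342)], names=("CA",))
CORE_RESIDS = (300, 312)


@dataclass
class ToyCDomain:
    """A toy C-domain: Cα site panel + anchor loop with two conformers."""

    model: StructureModel           # full model, loop in the basal conformer
    basal_loop: StructureModel      # loop backbone, basal template
    preactive_loop: StructureModel  # loop backbone, pre-active template
    site_offsets: dict[int, float]
    p_layer_z: float
    loop_com_offset: float          # construction CV offset vs the P layer


def _loop_backbone(template: str, ca_pos: dict[int, np.ndarray]) -> dict[tuple[int, str], np.ndarray]:
    """N/CA/C/O positions for the loop; the two templates share Cα traces but
    differ non-rigidly in N/C/O placement (planted fit-RMSD ≥ 2 Å)."""
    coords: dict[tuple[int, str], np.ndarray] = {}
    for j, resid in enumerate(LOOP_RESIDS):
        ca = ca_pos[resid]
        sign = 1.0 if j % 2 == 0 else -1.0
        if template == "basal":
            offsets = {
                "N": np.array([-0.8, 0.9 * sign, 0.4]),
                "C": np.array([0.8, 0.9 * sign, -0.4]),
                "O": np.array([1.1, 1.8 * sign, -0.5]),
            }
        else:  # pre-active: flipped and splayed carbonyls
            offsets = {
                "N": np.array([-0.8, -2.4 * sign, 0.4]),
                "C": np.array([0.8, -2.4 * sign, -0.4]),
                "O": np.array([1.1, -4.0 * sign, -0.5]),
            }
        coords[(resid, "CA")] = ca
        for name, off in offsets.items():
            coords[(resid, name)] = ca + off
    return coords


def make_toy_cdomain(
    site_offsets: Mapping[int, float] | None = None,
    p_layer_z: float = DEFAULT_LAYER_Z["lower"]["P"],
) -> ToyCDomain:
    """Toy C-domain: one Cα per panel site at its planted depth, an anchor
    loop (residues 335–345, full backbone) with basal and pre-active
    templates, and a rigid core block (residues 300–312) for stability RMSD.
    """
    offsets = dict(site_offsets if site_offsets is not None else DEFAULT_SITE_OFFSETS)
    if len(set(offsets)) != len(offsets):
        raise ValueError("duplicate site ids")
    for site, off in offsets.items():
        if not np.isfinite(off):
            raise ValueError(f"site {site}: non-finite depth offset")

    # loop Cα trace: planted offsets where the resid is a panel site, a smooth
    # default elsewhere; x spreads the residues out, y=0
    loop_ca: dict[int, np.ndarray] = {}
    for j, resid in enumerate(LOOP_RESIDS):
        off = offsets.get(resid, -4.0 + 0.5 * np.cos(j))
        loop_ca[resid] = np.array([1.5 * (resid - 340), 0.0, p_layer_z + off])

    atoms: list[Atom] = []
    serial = 1

    def add(name: str, resid: int, coord: np.ndarray, resname: str = "GLY") -> None:
        nonlocal serial
        element = name[0]
        atoms.append(Atom(serial, name, resname, "A", resid, element, coord))
        serial += 1

    # rigid core block, far on the water side of the membrane
    lo, hi = CORE_RESIDS
    for j, resid in enumerate(range(lo, hi + 1)):
        angle = 2 * np.pi * j / (hi - lo + 1)
        base = np.array([8 * np.cos(angle), 8 * np.sin(angle), p_layer_z - 40.0 + (j % 3)])
        for name, off in (("N", [-0.7, 0.4, 0.2]), ("CA", [0, 0, 0]),
                          ("C", [0.7, 0.4, -0.2]), ("O", [1.0, 1.5, -0.3])):
            add(name, resid, base + np.asarray(off, float))

    # anchor loop, basal conformer in the working model
    basal = _loop_backbone("basal", loop_ca)
    preactive = _loop_backbone("preactive", loop_ca)
    for resid in LOOP_RESIDS:
        for name in ("N", "CA", "C", "O"):
            add(name, resid, basal[(resid, name)].copy(), resname="LEU")

    # lone Cα markers for panel sites outside the loop
    for k, site in enumerate(sorted(offsets)):
        if site in LOOP_RESIDS:
            continue
        add("CA", site, np.array([3.0 * k, 6.0, p_layer_z + offsets[site]]), resname="CYS")

    model = StructureModel(atoms, metadata={"generator": "make_toy_cdomain"})

    def loop_model(template: dict[tuple[int, str], np.ndarray]) -> StructureModel:
        latoms = []
        s = 1
        for resid in LOOP_RESIDS:
            for name in ("N", "CA", "C", "O"):
                latoms.append(Atom(s, name, "LEU", "A", resid, name[0],
                                   template[(resid, name)].copy()))
                s += 1
        return StructureModel(latoms, metadata={"template": "loop"})

    cv_z = np.mean([loop_ca[r][2] for r in range(338, 343)])
    return ToyCDomain(
        model=model,
        basal_loop=loop_model(basal),
        preactive_loop=loop_model(preactive),
        site_offsets=offsets,
        p_layer_z=p_layer_z,
        loop_com_offset=float(cv_z - p_layer_z),
    )


# --------------------------------------------------------------------------
# Scripted trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryScript:
    """A scripted loop-COM z-path (piecewise linear) with conformer flips.

    ``path_knots`` are (time ns, CV offset Å vs the proximal P layer,
    positive = inserted beyond P). ``flip_frames`` toggle the loop conformer
    (starting from basal).
    """

    n_frames: int = 101
    dt_ns: float = 1.0
    path_knots: tuple[tuple[float, float], ...] = ((0.0, -5.0), (100.0, -5.0))
    flip_frames: tuple[int, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.path_knots]
        if sorted(ts) != ts:
            raise ValueError("path knots must be time-ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise must be non-negative")

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    def offsets(self) -> np.ndarray:
        ts, zs = np.array(self.path_knots).T
        return np.interp(self.times(), ts, zs)


@dataclass
class TrajectoryGroundTruth:
    offsets: np.ndarray                 # planted CV offset per frame (Å vs P)
    events: list[InsertionEvent]        # runs with offset > 0
    conformer_labels: list[str]         # per-frame basal|preactive


def _planted_events(times: np.ndarray, offsets: np.ndarray) -> list[InsertionEvent]:
    events = []
    inside = offsets > 0
    padded = np.concatenate(([False], inside, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2] - 1):
        events.append(
            InsertionEvent("344-loop", float(times[start]), float(times[stop]),
                           float(offsets[start : stop + 1].max()))
        )
    return events


def make_trajectory(
    script: TrajectoryScript,
    cdomain: ToyCDomain,
    membrane_frame: StructureModel,
) -> tuple[TrajectorySeries, TrajectoryGroundTruth]:
    """Frames realizing the scripted CV path over a static membrane.

    The protein is rigidly translated along z so its loop COM follows the
    script; conformer flips swap the loop backbone template; isotropic
    Gaussian noise is added to protein atoms. Membrane atoms are carried
    unchanged in every frame.
    """
    rng = np.random.default_rng(script.seed)
    protein = cdomain.model
    n_prot = len(protein.atoms)

    # merged topology with re-assigned serials
    atoms = []
    serial = 1
    for a in list(protein.atoms) + list(membrane_frame.atoms):
        atoms.append(Atom(serial, a.name, a.resname, a.chain, a.resid, a.element,
                          a.coord.copy(), mass=a.mass))
        serial += 1
    topology = StructureModel(atoms, metadata={"generator": "make_trajectory",
                                               "seed": script.seed,
                                               "noise_model":
                                               f"isotropic Gaussian, sigma={script.noise_sigma} A"})

    base_prot = protein.coords
    mem_coords = membrane_frame.coords

    # swap in the pre-active loop template where scripted
    loop_key_to_row: dict[tuple[int, str], int] = {}
    for i, a in enumerate(protein.atoms):
        if a.resid in LOOP_RESIDS and a.name in ("N", "CA", "C", "O"):
            loop_key_to_row[(a.resid, a.name)] = i
    pre_coords = {(a.resid, a.name): a.coord for a in cdomain.preactive_loop.atoms}

    offsets = script.offsets()
    times = script.times()
    labels = []
    current = "basal"
    frames = np.empty((script.n_frames, len(atoms), 3))
    for f in range(script.n_frames):
        if f in script.flip_frames:
            current = "preactive" if current == "basal" else "basal"
        labels.append(current)
        prot = base_prot.copy()
        if current == "preactive":
            for (resid, name), row in loop_key_to_row.items():
                prot[row] = pre_coords[(resid, name)]
        prot[:, 2] += offsets[f] - cdomain.loop_com_offset
        if script.noise_sigma > 0:
            prot = prot + rng.normal(0.0, script.noise_sigma, size=prot.shape)
        frames[f, :n_prot] = prot
        frames[f, n_prot:] = mem_coords

    truth = TrajectoryGroundTruth(offsets, _planted_events(times, offsets), labels)
    return TrajectorySeries(topology, frames, times), truth


# --------------------------------------------------------------------------
# Spectrum sets with planted quenching and shifts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumSpec:
    site: int = 342
    lambda_max_unbound: float = 470.0   # nm
    band_sigma: float = 28.0            # nm
    amplitude: float = 1000.0           # a.u.
    bound_scale: float = 0.9            # bound-state amplitude vs unbound
    baseline: float = 30.0              # deterministic instrument offset
    noise: float = 0.01                 # multiplicative Gaussian σ
    grid: tuple[float, float, float] = (420.0, 600.0, 2.0)
    planted_q: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("dark", "tempoyl"): 11.0, ("dark", "doxyl"): 30.0,
            ("light", "tempoyl"): 31.0, ("light", "doxyl"): 22.0,
        }
    )
    planted_shift: Mapping[str, float] = field(
        default_factory=lambda: {"dark": 13.0, "light": 13.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_sigma <= 0:
            raise ValueError("band sigma must be positive")
        for q in self.planted_q.values():
            if not -100 < q < 100:
                raise ValueError("planted Q must lie in (-100, 100)")

    def wavelengths(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + step / 2, step)


@dataclass
class SpectrumGroundTruth:
    planted_q: dict[tuple[str, str], float]
    planted_shift: dict[str, float]
    lambda_max_unbound: float


#: quencher → its unlabeled control lipid (generation-side mirror of the
#: analysis pairing)
_QUENCHER_CONTROL = {"tempoyl": "methyl_palmitate", "doxyl": "stearate"}


def make_spectrum_set(
    spec: SpectrumSpec,
) -> tuple[dict[tuple[str, str], EmissionSpectrum], EmissionSpectrum, SpectrumGroundTruth]:
    """Gaussian-band spectra over the (state × lipid) condition grid.

    Spin-labeled conditions are scaled by (1 − Q/100) relative to their
    paired unlabeled control; bound states are blue-shifted by the planted
    shift. Returns (spectra, background, ground truth); the background is
    the deterministic baseline alone.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths()
    spectra: dict[tuple[str, str], EmissionSpectrum] = {}

    def band(center: float, amp: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((wl - center) / spec.band_sigma) ** 2)

    for state in ("unbound", "dark", "light"):
        if state == "unbound":
            center, amp = spec.lambda_max_unbound, spec.amplitude
        else:
            center = spec.lambda_max_unbound - spec.planted_shift.get(state, 0.0)
            amp = spec.amplitude * spec.bound_scale
        for lipid in ("none", "methyl_palmitate", "tempoyl", "stearate", "doxyl"):
            scale = 1.0
            if state != "unbound" and lipid in ("tempoyl", "doxyl"):
                scale = 1.0 - spec.planted_q.get((state, lipid), 0.0) / 100.0
            signal = band(center, amp * scale)
            if spec.noise > 0:
                signal = signal * (1.0 + rng.normal(0.0, spec.noise, size=wl.shape))
            spectra[(state, lipid)] = EmissionSpectrum(
                wl, signal + spec.baseline, site=spec.site, state=state, lipid=lipid
            )
    background = EmissionSpectrum(wl, np.full_like(wl, spec.baseline),
                                  site=spec.site, state="unbound", lipid="none")
    truth = SpectrumGroundTruth(dict(spec.planted_q), dict(spec.planted_shift),
                                spec.lambda_max_unbound)
    return spectra, background, truth
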