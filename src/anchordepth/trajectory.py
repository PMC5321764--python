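"""Per-frame analytics over coordinate series.

Loop COM z-series, membrane insertion-event detection, basal/pre-active
conformer classification, domain-stability RMSD, and best-fit frame selection
against a reference complex plus a reference carbonyl plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coords import (
    SelectionSpec,
    StructureModel,
    rmsd,
    selection_indices,
    superpose,
)

#: default loop selection for conformer classification (344-loop region,
#: backbone atoms)
DEFAULT_LOOP_SPEC = SelectionSpec.make(resids=[(335, 345)], names=("N", "CA", "C", "O"))


@dataclass
class TrajectorySeries:
    """Time-stamped frames sharing one atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``times`` in ns,
    strictly increasing.
    """

    topology: StructureModel
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology.atoms):
            raise ValueError("frame atom count differs from topology")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])

    @classmethod
    def from_models(
        cls, models: Sequence[StructureModel], times: Sequence[float] | None = None
    ) -> "TrajectorySeries":
        if not models:
            raise ValueError("need at least one model")
        coords = np.stack([m.coords for m in models])
        if times is None:
            times = np.arange(len(models), dtype=float)
        return cls(models[0], coords, np.asarray(times, dtype=float))

    def save_npz(self, path: str | Path) -> None:
        """Runtime binary cache of the coordinate/time arrays (not a fixture format)."""
        np.savez_compressed(path, coords=self.coords, times=self.times)

    def load_npz(self, path: str | Path) -> "TrajectorySeries":
        data = np.load(path)
        return TrajectorySeries(self.topology, data["coords"], data["times"])


@dataclass(frozen=True)
class InsertionEvent:
    """A maximal dwell of the tracked loop beyond the phosphate layer."""

    label: str
    start_ns: float
    end_ns: float
    max_penetration: float

    def __post_init__(self) -> None:
        if self.end_ns < self.start_ns:
            raise ValueError("event end before start")
        if self.max_penetration <= 0:
            raise ValueError("max penetration must be positive")


@dataclass(frozen=True)
class ConformerAssignment:
    frame: int
    rmsd_to_basal: float
    rmsd_to_preactive: float
    label: str  # "basal" | "preactive" | "ambiguous"


@dataclass(frozen=True)
class FrameFitScore:
    frame: int
    rmsd_domain: float
    plane_offset: float
    combined: float


def loop_com_z(traj: TrajectorySeries, spec: SelectionSpec) -> np.ndarray:
    """Per-frame mass-weighted COM z (Å) of the selected atoms."""
    idx = selection_indices(traj.topology, spec)
    if len(idx) == 0:
        raise ValueError("empty selection for loop COM")
    masses = traj.topology.masses[idx]
    z = traj.coords[:, idx, 2]
    return (z * masses).sum(axis=1) / masses.sum()


def detect_insertions(
    com_z: np.ndarray,
    p_layer_z: np.ndarray | float,
    times: np.ndarray,
    min_depth: float,
    min_dwell: float,
    core_sign: float = 1.0,
    label: str = "344-loop",
) -> list[InsertionEvent]:
    """Maximal runs where the CV sits ≥ ``min_depth`` beyond the P layer on
    the membrane-core side, lasting ≥ ``min_dwell`` ns.

    Runs separated by gaps shorter than ``min_dwell``/2 are merged before the
    dwell filter. ``core_sign`` is +1 when the membrane core lies at larger z
    than the layer (protein approaching from below).
    """
    com_z = np.asarray(com_z, dtype=float)
    times = np.asarray(times, dtype=float)
    p = np.broadcast_to(np.asarray(p_layer_z, dtype=float), com_z.shape)
    if com_z.shape != times.shape:
        raise ValueError("com_z and times length mismatch")
    if min_depth <= 0:
        raise ValueError("min_depth must be positive")
    if min_dwell < 0:
        raise ValueError("min_dwell must be non-negative")

    penetration = core_sign * (com_z - p)
    inside = penetration >= min_depth
    if not inside.any():
        return []

    # index runs of consecutive True
    padded = np.concatenate(([False], inside, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = list(zip(edges[::2], edges[1::2] - 1))  # inclusive frame index pairs

    merged: list[list[int]] = [list(runs[0])]
    for start, end in runs[1:]:
        gap = times[start] - times[merged[-1][1]]
        if gap < min_dwell / 2.0:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    events = []
    for start, end in merged:
        duration = times[end] - times[start]
        if duration >= min_dwell:
            events.append(
                InsertionEvent(
                    label=label,
                    start_ns=float(times[start]),
                    end_ns=float(times[end]),
                    max_penetration=float(penetration[start : end + 1].max()),
                )
            )
    return events


def classify_conformers(
    traj: TrajectorySeries,
    basal_ref: StructureModel,
    preactive_ref: StructureModel,
    loop_spec: SelectionSpec = DEFAULT_LOOP_SPEC,
    margin: float = 0.5,
    window_frac: float = 0.3,
) -> tuple[list[ConformerAssignment], dict]:
    """Per-frame fit-RMSD to each reference conformer and the nearer label.

    A frame is labeled by the nearer reference when the two RMSDs differ by
    at least ``margin`` Å, else "ambiguous". The summary reports the average
    RMSD to each reference over the trailing ``window_frac`` of frames.
    """
    assignments: list[ConformerAssignment] = []
    for i in range(traj.n_frames):
        frame = traj.frame_model(i)
        r_b = rmsd(frame, basal_ref, loop_spec, fit=True)
        r_p = rmsd(frame, preactive_ref, loop_spec, fit=True)
        if abs(r_b - r_p) >= margin:
            label = "basal" if r_b < r_p else "preactive"
        else:
            label = "ambiguous"
        assignments.append(ConformerAssignment(i, r_b, r_p, label))

    n_tail = max(1, int(round(window_frac * traj.n_frames)))
    tail = assignments[-n_tail:]
    summary = {
        "window_frames": n_tail,
        "mean_rmsd_to_basal": float(np.mean([a.rmsd_to_basal for a in tail])),
        "mean_rmsd_to_preactive": float(np.mean([a.rmsd_to_preactive for a in tail])),
    }
    return assignments, summary


def stability_rmsd(
    traj: TrajectorySeries,
    reference: StructureModel,
    core_spec: SelectionSpec,
    excluded_loops: Sequence[tuple[int, int]] = (),
    fit: bool = True,
) -> tuple[np.ndarray, dict]:
    """Per-frame RMSD to a reference over a core selection with loops removed.

    Returns the per-frame series (Å) and a summary with its mean and max.
    """
    def keep(i: int, model: StructureModel) -> bool:
        resid = model.atoms[i].resid
        return not any(lo <= resid <= hi for lo, hi in excluded_loops)

    t_idx = [i for i in selection_indices(traj.topology, core_spec) if keep(i, traj.topology)]
    r_idx = [i for i in selection_indices(reference, core_spec) if keep(i, reference)]
    if len(t_idx) != len(r_idx):
        raise ValueError("core selection count mismatch between trajectory and reference")
    if len(t_idx) < 3:
        raise ValueError("core selection (after loop exclusion) has fewer than 3 atoms")

    sub_top = _submodel(traj.topology, t_idx)
    sub_ref = _submodel(reference, r_idx)
    series = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        sub_frame = sub_top.with_coords(traj.coords[i][t_idx])
        series[i] = rmsd(sub_frame, sub_ref, None, fit=fit)
    summary = {"mean": float(series.mean()), "max": float(series.max())}
    return series, summary


def _submodel(model: StructureModel, indices: Sequence[int]) -> StructureModel:
    out = object.__new__(StructureModel)
    out.atoms = [model.atoms[i] for i in indices]
    out.model_id = model.model_id
    out.metadata = dict(model.metadata)
    return out


def select_best_frame(
    traj: TrajectorySeries,
    reference_complex: StructureModel,
    reference_co_plane_z: float,
    domain_spec: SelectionSpec,
    co_spec: SelectionSpec | None = None,
    weights: tuple[float, float] | None = None,
) -> tuple[list[FrameFitScore], int]:
    """Two-step frame selection against a reference complex.

    Each frame is first superposed onto the reference over ``domain_spec``
    (backbone of the C-domain); the fitted transform is then applied to the
    frame's carbonyl lipid atoms and the plane offset is the |Δz| between
    their mean z and the reference carbonyl plane. The chosen frame minimizes
    the plane offset, ties broken by lower domain RMSD, then lower index.

    ``co_spec`` selects the carbonyl lipid atoms (default: atom name "CO";
    narrow it to one leaflet's chain when the reference plane is one-sided).
    ``weights=(w_offset, w_rmsd)`` switches to a weighted-sum combined score.
    """
    if co_spec is None:
        co_spec = SelectionSpec.make(names=("CO",))
    co_idx = list(selection_indices(traj.topology, co_spec))
    if not co_idx:
        raise ValueError("trajectory frames contain no carbonyl (CO) lipid atoms")

    scores: list[FrameFitScore] = []
    for i in range(traj.n_frames):
        frame = traj.frame_model(i)
        transform, r_dom = superpose(frame, reference_complex, domain_spec)
        co_z = transform.apply(traj.coords[i][co_idx])[:, 2].mean()
        offset = abs(float(co_z) - reference_co_plane_z)
        if weights is None:
            combined = offset
        else:
            combined = weights[0] * offset + weights[1] * r_dom
        scores.append(FrameFitScore(i, r_dom, offset, combined))

    if weights is None:
        chosen = min(scores, key=lambda s: (s.plane_offset, s.rmsd_domain, s.frame)).frame
    else:
        chosen = min(scores, key=lambda s: (s.combined, s.frame)).frame
    return scores, chosen
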