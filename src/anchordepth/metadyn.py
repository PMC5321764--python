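"""One-dimensional well-tempered metadynamics on analytic toy potentials.

Langevin (BAOAB) dynamics on a single collective variable s (Å), Gaussian
hill deposition with well-tempered height decay, one-sided harmonic walls,
free-energy reconstruction F̂(s) = −(γ/(γ−1))·V_b(s), and well localization.

Units: energies kcal/mol, lengths Å, times ps, temperatures K, masses amu.
The engine is desk-scale by design: hill sums go over the full ledger and
the CV is propagated exactly, which keeps every quantity auditable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872
#: (kcal/mol/Å) per amu → Å/ps² (force-to-acceleration conversion)
ACCEL = 418.4


# --------------------------------------------------------------------------
# Toy potentials
# --------------------------------------------------------------------------

@dataclass
class ToyPotential:
    """An analytic 1D potential with energy (kcal/mol) and gradient."""

    kind: str
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    @classmethod
    def harmonic(cls, k: float = 2.0, s0: float = 0.0) -> "ToyPotential":
        """U(s) = ½k(s−s0)²; k in kcal/mol/Å²."""
        return cls(
            kind="harmonic",
            energy=lambda s: 0.5 * k * (np.asarray(s, float) - s0) ** 2,
            gradient=lambda s: k * (np.asarray(s, float) - s0),
            params={"k": k, "s0": s0},
        )

    @classmethod
    def double_well(cls, barrier: float = 3.0, minimum: float = 1.0) -> "ToyPotential":
        """U(s) = B((s/m)² − 1)²: minima at ±m (Å), barrier B (kcal/mol) at 0."""
        b, m = float(barrier), float(minimum)
        return cls(
            kind="double_well",
            energy=lambda s: b * ((np.asarray(s, float) / m) ** 2 - 1.0) ** 2,
            gradient=lambda s: 4.0 * b * np.asarray(s, float)
            * ((np.asarray(s, float) / m) ** 2 - 1.0) / m**2,
            params={"barrier": b, "minimum": m},
        )

    @classmethod
    def tabulated(cls, s: np.ndarray, u: np.ndarray) -> "ToyPotential":
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(np.asarray(s, float), np.asarray(u, float))
        return cls(
            kind="tabulated",
            energy=lambda x: spline(x),
            gradient=lambda x: spline(x, 1),
            params={"n_knots": len(s)},
        )


# --------------------------------------------------------------------------
# Bias: hills, walls, state
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Hill:
    center: float       # Å
    height: float       # kcal/mol
    sigma: float        # Å
    time: float         # ps of deposition

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if self.sigma <= 0:
            raise ValueError("hill sigma must be positive")


@dataclass(frozen=True)
class WallSpec:
    """One-sided harmonic wall: V = κ·Δ² beyond the limit (no ½ by default,
    matching the plugin convention the printed κ refers to)."""

    side: str           # "upper" | "lower"
    limit: float        # Å
    kappa: float        # kcal/mol/Å²
    half_factor: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("upper", "lower"):
            raise ValueError("wall side must be upper|lower")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


#: walls mirroring the printed restraint: κ=100, limits at 14 Å (deep
#: insertion side) and 20 Å (water side) in the CV's units
DEFAULT_WALLS = (
    WallSpec("upper", 14.0, 100.0),
    WallSpec("lower", -20.0, 100.0),
)


@dataclass
class BiasState:
    """The metadynamics bias: hill ledger plus deposition parameters."""

    bias_factor: float = 15.0       # γ, dimensionless
    temperature: float = 300.0      # K
    pace: float = 2.0               # ps between depositions
    hill_height: float = 2.0        # w₀, kcal/mol
    hill_sigma: float = 0.2         # Å
    hills: list[Hill] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bias_factor > 1:
            raise ValueError("well-tempered bias factor must exceed 1")
        if self.pace <= 0:
            raise ValueError("pace must be positive")
        self._sync_arrays()

    def _sync_arrays(self) -> None:
        self._centers = np.array([h.center for h in self.hills])
        self._heights = np.array([h.height for h in self.hills])
        self._sigmas = np.array([h.sigma for h in self.hills])

    def append(self, hill: Hill) -> None:
        self.hills.append(hill)
        self._centers = np.append(self._centers, hill.center)
        self._heights = np.append(self._heights, hill.height)
        self._sigmas = np.append(self._sigmas, hill.sigma)

    @property
    def delta_t(self) -> float:
        """ΔT = (γ−1)·T of the well-tempered tempering rule."""
        return (self.bias_factor - 1.0) * self.temperature


def bias_energy(state: BiasState, s: float | np.ndarray) -> float | np.ndarray:
    """V_b(s) = Σ_k w_k exp(−(s−s₀ₖ)²/(2σₖ²)); 0 with no hills."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if len(state.hills) == 0:
        v = np.zeros_like(s_arr)
    else:
        d = s_arr[:, None] - state._centers[None, :]
        v = (state._heights * np.exp(-0.5 * (d / state._sigmas) ** 2)).sum(axis=1)
    return float(v[0]) if np.isscalar(s) or np.asarray(s).ndim == 0 else v


def bias_force(state: BiasState, s: float) -> float:
    """−dV_b/ds at a scalar s."""
    if len(state.hills) == 0:
        return 0.0
    d = s - state._centers
    g = state._heights * np.exp(-0.5 * (d / state._sigmas) ** 2)
    return float((g * d / state._sigmas**2).sum())


def deposit_hill(state: BiasState, s_now: float, time: float = 0.0) -> Hill | None:
    """Append a well-tempered hill at s_now: w = w₀·exp(−V_b(s)/(k_B·ΔT)).

    In the γ→∞ limit heights stay at w₀ (standard metadynamics). Hills
    tempered below 1e-12 kcal/mol are dropped (returns None).
    """
    if math.isinf(state.bias_factor):
        w = state.hill_height
    else:
        w = state.hill_height * math.exp(-bias_energy(state, s_now) / (KB * state.delta_t))
    if w < 1e-12:
        return None
    hill = Hill(center=float(s_now), height=w, sigma=state.hill_sigma, time=time)
    state.append(hill)
    return hill


def wall_energy(walls: Sequence[WallSpec], s: float) -> float:
    """Sum of one-sided harmonic wall energies at s."""
    v = 0.0
    for w in walls:
        if w.side == "upper" and s > w.limit:
            d = s - w.limit
        elif w.side == "lower" and s < w.limit:
            d = w.limit - s
        else:
            continue
        v += (0.5 if w.half_factor else 1.0) * w.kappa * d * d
    return v


def wall_force(walls: Sequence[WallSpec], s: float) -> float:
    """−d/ds of the wall energy at s."""
    f = 0.0
    for w in walls:
        factor = (1.0 if w.half_factor else 2.0) * w.kappa
        if w.side == "upper" and s > w.limit:
            f -= factor * (s - w.limit)
        elif w.side == "lower" and s < w.limit:
            f += factor * (w.limit - s)
    return f


# --------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinParams:
    friction: float = 1.0       # ps⁻¹
    dt: float = 0.002           # ps
    temperature: float = 300.0  # K
    seed: int = 0
    mass: float = 50.0          # amu (loop-scale effective mass)


def run_biased(
    potential: ToyPotential,
    state: BiasState | None,
    walls: Sequence[WallSpec],
    langevin: LangevinParams,
    steps: int,
    s0: float = 0.0,
    sample_stride: int = 10,
) -> tuple[np.ndarray, np.ndarray, BiasState | None]:
    """BAOAB-discretized Langevin trajectory on U + V_b + walls.

    Hills are deposited every ``state.pace`` ps (skipped when state is None,
    i.e. an unbiased run). Returns (sample times ps, CV samples Å, state).
    Bit-reproducible for a fixed seed. Aborts on non-finite coordinates.
    """
    m = langevin.mass
    dt = langevin.dt
    # stability guard: dt·ω < 0.1 for the stiffest curvature near the start
    probe = np.linspace(s0 - 1, s0 + 1, 9)
    g = potential.gradient(probe)
    k_est = float(np.max(np.abs(np.gradient(g, probe))))
    if k_est > 0:
        omega = math.sqrt(k_est * ACCEL / m)
        if dt * omega >= 0.1:
            raise ValueError(
                f"dt={dt} ps too large for potential stiffness (dt·ω={dt*omega:.2f} ≥ 0.1)"
            )

    rng = np.random.default_rng(langevin.seed)
    kbt = KB * langevin.temperature
    c1 = math.exp(-langevin.friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kbt * ACCEL / m)

    pace_steps = max(1, int(round((state.pace if state else 1.0) / dt)))
    s = float(s0)
    v = 0.0 if langevin.temperature == 0 else rng.normal(0.0, math.sqrt(kbt * ACCEL / m))

    def force(x: float) -> float:
        f = -float(potential.gradient(x)) + wall_force(walls, x)
        if state is not None:
            f += bias_force(state, x)
        return f

    n_samples = steps // sample_stride
    samples = np.empty(n_samples)
    sample_times = np.empty(n_samples)
    f = force(s)
    j = 0
    for step in range(1, steps + 1):
        # B
        v += 0.5 * dt * f * ACCEL / m
        # A
        s += 0.5 * dt * v
        # O
        if langevin.temperature > 0:
            v = c1 * v + c2 * rng.standard_normal()
        else:
            v = c1 * v
        # A
        s += 0.5 * dt * v
        if not math.isfinite(s) or abs(s) > 1e6:
            raise RuntimeError(f"trajectory diverged at step {step} (s={s})")
        if state is not None and step % pace_steps == 0:
            deposit_hill(state, s, time=step * dt)
        # B (force after any deposition so the new hill acts immediately)
        f = force(s)
        v += 0.5 * dt * f * ACCEL / m
        if step % sample_stride == 0:
            samples[j] = s
            sample_times[j] = step * dt
            j += 1
    return sample_times, samples, state


# --------------------------------------------------------------------------
# Free-energy reconstruction and well localization
# --------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """F(s) on a strictly increasing grid, gauge-fixed to min F = 0."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be matching 1D arrays")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        self.values = self.values - self.values.min()


@dataclass(frozen=True)
class Well:
    location: float     # Å
    half_width: float   # Å (half-width of the basin at F_min + 1 k_BT)
    depth: float        # kcal/mol (prominence of the minimum)


def reconstruct_fes(state: BiasState, grid: np.ndarray) -> FreeEnergyProfile:
    """Well-tempered estimator F̂(s) = −(γ/(γ−1))·V_b(s), min-shifted to 0."""
    if len(state.hills) == 0:
        raise ValueError("cannot reconstruct a free energy from an empty hill ledger")
    grid = np.asarray(grid, dtype=float)
    gamma = state.bias_factor
    scale = 1.0 if math.isinf(gamma) else gamma / (gamma - 1.0)
    f = -scale * np.asarray(bias_energy(state, grid), dtype=float)
    return FreeEnergyProfile(grid, f)


def locate_well(
    profile: FreeEnergyProfile,
    prominence: float = 0.5,
    temperature: float = 300.0,
) -> list[Well]:
    """Local minima with prominence ≥ ``prominence`` kcal/mol.

    Location is refined by a 3-point parabola through the discrete minimum;
    the width is the half-width of the basin at 1 k_BT above the minimum.
    """
    f = profile.values
    s = profile.grid
    idx, props = find_peaks(-f, prominence=prominence)
    kbt = KB * temperature
    wells: list[Well] = []
    for i, prom in zip(idx, props["prominences"]):
        # parabolic refinement of the minimum location
        if 0 < i < len(s) - 1:
            denom = f[i - 1] - 2 * f[i] + f[i + 1]
            offset = 0.5 * (f[i - 1] - f[i + 1]) / denom if denom > 0 else 0.0
            loc = s[i] + offset * (s[i + 1] - s[i])
        else:
            loc = s[i]
        threshold = f[i] + kbt
        left = i
        while left > 0 and f[left - 1] <= threshold:
            left -= 1
        right = i
        while right < len(s) - 1 and f[right + 1] <= threshold:
            right += 1
        half_width = 0.5 * (s[right] - s[left])
        wells.append(Well(float(loc), float(half_width), float(prom)))
    return wells


def two_well_barrier(
    profile: FreeEnergyProfile, prominence: float = 1.0, temperature: float = 300.0
) -> tuple[float | None, list[Well]]:
    """Barrier between the two deepest wells of a profile.

    The barrier is the maximum of F between the two well minima minus the
    mean of F at the minima. Returns (barrier or None, the two wells sorted
    by location).
    """
    wells = sorted(locate_well(profile, prominence, temperature), key=lambda w: -w.depth)[:2]
    wells = sorted(wells, key=lambda w: w.location)
    if len(wells) < 2:
        return None, wells
    i0 = int(np.searchsorted(profile.grid, wells[0].location))
    i1 = int(np.searchsorted(profile.grid, wells[1].location))
    barrier = float(
        profile.values[i0 : i1 + 1].max() - 0.5 * (profile.values[i0] + profile.values[i1])
    )
    return barrier, wells


# --------------------------------------------------------------------------
# Hills ledger file I/O (whitespace-delimited: time center sigma height)
# --------------------------------------------------------------------------

def write_hills(path: str | Path, state: BiasState) -> None:
    with Path(path).open("w") as fh:
        fh.write("#! FIELDS time center sigma height\n")
        for h in state.hills:
            fh.write(f"{h.time:.6f} {h.center:.9f} {h.sigma:.9f} {h.height:.9f}\n")


def read_hills(
    path: str | Path,
    bias_factor: float = 15.0,
    temperature: float = 300.0,
    pace: float = 2.0,
) -> BiasState:
    data = np.loadtxt(path, comments="#", ndmin=2)
    state = BiasState(bias_factor=bias_factor, temperature=temperature, pace=pace)
    for t, c, sig, w in data:
        state.append(Hill(center=float(c), height=float(w), sigma=float(sig), time=float(t)))
    return state
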