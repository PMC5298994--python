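"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its spec and seed, and each has a
closed-loop identity with its consuming stage: the noiseless output, fed to
that stage, returns the generating parameters exactly.  The generators
emulate:

* two-class descriptor matrices with a few class-separating columns among
  many noise columns (the structure of the published descriptor table);
* two-state Markov single-channel current traces with set unitary
  conductance, open probability and noise;
* phase-structured dye-uptake traces (e.g. control -> trigger -> blocker);
* cylindrical pseudo-atom pore geometries with known constrictions, for
  which the pore-radius profile has a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import ChannelTrace, UptakeTrace
from .io import DescriptorMatrix, NON_PERMEANT, PERMEANT
from .pore import AtomSet

__all__ = [
    "PlantedSpec",
    "PoreSpec",
    "Ring",
    "gen_descriptor_dataset",
    "gen_channel_trace",
    "gen_uptake_trace",
    "gen_pore_geometry",
    "write_pdb",
]


# ---------------------------------------------------------------------------
# Descriptor matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSpec:
    """Two-class descriptor matrix with planted informative columns.

    Informative columns are Normal(+effect_size/2, 1) for permeant and
    Normal(-effect_size/2, 1) for non-permeant molecules; noise columns are
    Normal(0, 1) regardless of class.  ``missing_fraction`` scatters missing
    cells uniformly; ``n_missing_heavy`` plants columns missing for two
    molecules and ``n_degenerate_zero`` plants all-but-one-zero columns,
    both of which the non-informative filter should drop.
    """

    n_permeant: int = 6
    n_nonpermeant: int = 3
    n_informative: int = 5
    n_noise: int = 495
    effect_size: float = 3.0
    missing_fraction: float = 0.0
    n_missing_heavy: int = 0
    n_degenerate_zero: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permeant <= 0 or self.n_nonpermeant <= 0:
            raise ValueError("both classes must be non-empty")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one descriptor")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


def gen_descriptor_dataset(
    spec: PlantedSpec,
) -> tuple[DescriptorMatrix, tuple[str, ...]]:
    """Generate a labelled descriptor matrix; returns (matrix, informative names)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_permeant + spec.n_nonpermeant
    labels = [PERMEANT] * spec.n_permeant + [NON_PERMEANT] * spec.n_nonpermeant
    molecules = [f"P{i + 1}" for i in range(spec.n_permeant)] + [
        f"N{i + 1}" for i in range(spec.n_nonpermeant)
    ]
    class_sign = np.array([1.0] * spec.n_permeant + [-1.0] * spec.n_nonpermeant)

    cols: dict[str, np.ndarray] = {}
    informative = tuple(f"INF{i + 1}" for i in range(spec.n_informative))
    for name in informative:
        cols[name] = rng.normal(class_sign * spec.effect_size / 2.0, 1.0)
    for j in range(spec.n_noise):
        cols[f"NS{j + 1}"] = rng.normal(0.0, 1.0, size=n)
    for j in range(spec.n_missing_heavy):
        col = rng.normal(0.0, 1.0, size=n)
        col[rng.choice(n, size=2, replace=False)] = np.nan
        cols[f"MISS{j + 1}"] = col
    for j in range(spec.n_degenerate_zero):
        col = np.zeros(n)
        col[rng.integers(0, n)] = rng.normal(5.0, 1.0)
        cols[f"ZERO{j + 1}"] = col

    frame = pd.DataFrame(cols, index=molecules)
    if spec.missing_fraction > 0:
        mask = rng.random(frame.shape) < spec.missing_fraction
        frame = frame.mask(mask)
    return DescriptorMatrix(frame, labels), informative


# ---------------------------------------------------------------------------
# Single-channel traces
# ---------------------------------------------------------------------------

def gen_channel_trace(
    g: float = 75.0,
    P_o: float = 0.3,
    V: float = 60.0,
    noise_sd: float = 0.5,
    mean_dwell_open_ms: float = 50.0,
    mean_dwell_closed_ms: float | None = None,
    duration: float = 40.0,
    rate: float = 5000.0,
    seed: int = 0,
) -> ChannelTrace:
    """Two-state Markov single-channel trace.

    Open current is g*V/1000 pA (75 pS at +60 mV gives 4.5 pA), closed
    current is 0, both plus Gaussian noise.  Dwell times are exponential;
    the mean closed dwell is derived from P_o and the mean open dwell as
    tau_c = tau_o * (1 - P_o) / P_o, so the specification cannot be
    over-determined.  Passing ``mean_dwell_closed_ms`` explicitly must agree
    with that relation (1% tolerance) or a ValueError is raised.
    """
    if not 0.0 <= P_o <= 1.0:
        raise ValueError("P_o must be in [0, 1]")
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    open_current = g * V / 1000.0

    if P_o in (0.0, 1.0):
        if mean_dwell_closed_ms is not None:
            raise ValueError("mean_dwell_closed_ms is meaningless at P_o of 0 or 1")
        states = np.full(n, P_o == 1.0, dtype=bool)
    else:
        tau_o = mean_dwell_open_ms / 1000.0
        tau_c_derived = tau_o * (1.0 - P_o) / P_o
        if mean_dwell_closed_ms is not None:
            tau_c = mean_dwell_closed_ms / 1000.0
            if abs(tau_c - tau_c_derived) > 0.01 * tau_c_derived:
                raise ValueError(
                    "mean_dwell_closed_ms inconsistent with P_o and mean_dwell_open_ms"
                )
        tau_c = tau_c_derived
        states = np.empty(n, dtype=bool)
        state = bool(rng.random() < P_o)
        i = 0
        while i < n:
            tau = tau_o if state else tau_c
            dwell = rng.exponential(tau)
            j = min(n, i + max(int(round(dwell * rate)), 1))
            states[i:j] = state
            state = not state
            i = j

    samples = np.where(states, open_current, 0.0)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    return ChannelTrace(
        samples=samples,
        sampling_rate=rate,
        holding_voltage=V,
        protocol=f"step {V:+g} mV for {duration:g} s",
    )


# ---------------------------------------------------------------------------
# Dye-uptake traces
# ---------------------------------------------------------------------------

def gen_uptake_trace(
    phase_slopes: Sequence[tuple[str, float, float]],
    noise_sd: float = 0.0,
    sample_interval: float = 0.5,
    f0: float = 10.0,
    seed: int = 0,
) -> UptakeTrace:
    """Piecewise-linear fluorescence trace with labelled phases.

    ``phase_slopes`` is a list of (label, slope AU/min, duration min); the
    mean trace is continuous at phase boundaries and starts at ``f0``.
    Samples are taken every ``sample_interval`` minutes (default 0.5 min,
    i.e. every 30 s).
    """
    if not phase_slopes:
        raise ValueError("at least one phase is required")
    if any(duration <= 0 for _, _, duration in phase_slopes):
        raise ValueError("phase durations must be positive")
    rng = np.random.default_rng(seed)
    total = sum(d for _, _, d in phase_slopes)
    t = np.arange(0.0, total + sample_interval / 2, sample_interval)

    phases = []
    t0 = 0.0
    for label, _, duration in phase_slopes:
        phases.append((label, t0, t0 + duration))
        t0 += duration

    f = np.empty_like(t)
    level = f0
    start = 0.0
    for (label, slope, duration), (_, p0, p1) in zip(phase_slopes, phases):
        last = p1 >= total
        mask = (t >= p0) & (t <= p1 if last else t < p1)
        f[mask] = level + slope * (t[mask] - start)
        level = level + slope * duration
        start = p1
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=len(f))
    return UptakeTrace(time=t, fluorescence=f, phases=tuple(phases))


# ---------------------------------------------------------------------------
# Pore geometries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ring:
    """A ring of pseudo-atoms in the plane z = const."""

    z: float
    ring_radius: float
    n_atoms: int = 12
    vdw: float = 1.7

    def __post_init__(self) -> None:
        if self.ring_radius <= self.vdw:
            raise ValueError("ring_radius must exceed the atom vdw radius")
        if self.vdw < 0:
            raise ValueError("vdw must be >= 0")
        if self.n_atoms < 3:
            raise ValueError("a ring needs at least 3 atoms")


@dataclass(frozen=True)
class PoreSpec:
    """Stack of atom rings plus optional coordinate jitter."""

    rings: tuple[Ring, ...]
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rings:
            raise ValueError("at least one ring is required")


def gen_pore_geometry(spec: PoreSpec) -> tuple[AtomSet, tuple[tuple[float, float], ...]]:
    """Place atoms on each ring, centered on the z axis.

    Returns the atom set and the closed-form oracle: for jitter 0, the pore
    radius at each ring plane equals ring_radius - vdw (the axis-to-atom
    distance in-plane minus the atom's van der Waals radius).
    """
    rng = np.random.default_rng(spec.seed)
    positions, vdw = [], []
    for ring in spec.rings:
        angles = 2.0 * np.pi * np.arange(ring.n_atoms) / ring.n_atoms
        xyz = np.column_stack([
            ring.ring_radius * np.cos(angles),
            ring.ring_radius * np.sin(angles),
            np.full(ring.n_atoms, ring.z),
        ])
        if spec.jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sd, size=xyz.shape)
        positions.append(xyz)
        vdw.append(np.full(ring.n_atoms, ring.vdw))
    positions = np.vstack(positions)
    vdw = np.concatenate(vdw)
    atoms = AtomSet(
        elements=np.asarray(["C"] * len(vdw), dtype=object),
        positions=positions,
        vdw_radii=vdw,
    )
    oracle = tuple((ring.z, ring.ring_radius - ring.vdw) for ring in spec.rings)
    return atoms, oracle


def write_pdb(atoms: AtomSet, path: str | Path, radii_sidecar: str | Path | None = None) -> Path:
    """Write pseudo-atoms as generic carbon ATOM records.

    Crystal-style PDB records carry no radii, so the exact per-atom radii
    can be saved to a JSON sidecar and fed back to the profiler, bypassing
    the element radii table in oracle comparisons.
    """
    path = Path(path)
    lines = []
    for i, pos in enumerate(atoms.positions, start=1):
        lines.append(
            f"ATOM  {i:5d}  C   RNG A{((i - 1) % 9999) + 1:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if radii_sidecar is not None:
        import json

        Path(radii_sidecar).write_text(
            json.dumps({"vdw_radii": [float(r) for r in atoms.vdw_radii]})
        )
    return path
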