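"""Sweep/protocol data model, unit conventions, tabular I/O and junction correction.

Canonical units throughout the package: voltage mV, current pA, time ms,
resistance MΩ, capacitance pF, frequency Hz.  With these units,

    Rin [MΩ] = ΔV [mV] / (ΔI [pA] / 1000)
    Cin [pF] = 1000 · τm [ms] / Rin [MΩ]

Sweeps are stored with an explicit uniformly-spaced time axis starting at 0.
The current step window is half-open, ``[onset_ms, offset_ms)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Liquid junction potential of the potassium-gluconate internal solution, mV.
JUNCTION_POTENTIAL_MV = 14.0

SWEEP_COLUMNS = [
    "cell_id", "animal_id", "group_label", "sweep_index",
    "step_pA", "onset_ms", "offset_ms", "holding_pA", "sample_khz",
    "t_ms", "v_mV",
]


class TraceError(ValueError):
    """Invalid sweep or protocol data."""


class JunctionStateError(TraceError):
    """Junction-potential correction applied to an already corrected sweep."""


@dataclass(frozen=True)
class CurrentStep:
    """Rectangular current injection: amplitude in pA over [onset, offset) ms."""

    amplitude_pA: float
    onset_ms: float
    offset_ms: float


@dataclass(frozen=True)
class Sweep:
    """One uniformly sampled current-clamp voltage trace.

    Parameters
    ----------
    t : ndarray
        Time base in ms, 0-based, uniformly spaced.
    v : ndarray
        Membrane voltage in mV, one sample per time point.
    step : CurrentStep
        Injected current step description.
    holding_pA : float
        Constant holding current applied throughout the sweep.
    sample_khz : float
        Sampling rate in kHz (any value ≥ 5; acquisition hardware used 20/50).
    junction_corrected : bool
        Whether the liquid-junction-potential offset has been removed.
    """

    t: np.ndarray
    v: np.ndarray
    step: CurrentStep
    holding_pA: float = 0.0
    sample_khz: float = 50.0
    junction_corrected: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or t.size < 2:
            raise TraceError("time axis must be 1-D with at least two samples")
        if v.shape != t.shape:
            raise TraceError(
                f"voltage length {v.size} does not match time length {t.size}"
            )
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise TraceError("time axis must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise TraceError("time axis must be uniformly spaced (rtol 1e-9)")
        if abs(t[0]) > 1e-12:
            raise TraceError("time axis must start at 0")
        if self.sample_khz < 5.0:
            raise TraceError(f"sample rate {self.sample_khz} kHz below 5 kHz minimum")
        if not (0.0 <= self.step.onset_ms < self.step.offset_ms <= t[-1] + 1e-9):
            raise TraceError(
                "step window must satisfy 0 <= onset < offset <= last time point"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def index_at(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        return int(math.ceil(round(t_ms / self.dt_ms, 9)))

    def window(self, t0_ms: float, t1_ms: float) -> slice:
        """Half-open sample slice covering [t0, t1) ms."""
        return slice(max(self.index_at(t0_ms), 0),
                     min(self.index_at(t1_ms), self.n_samples))

    def step_slice(self) -> slice:
        return self.window(self.step.onset_ms, self.step.offset_ms)

    def baseline_slice(self) -> slice:
        return self.window(0.0, self.step.onset_ms)


@dataclass
class StepProtocol:
    """Ordered family of sweeps from one cell (a current-step series).

    Sweeps are sorted by step amplitude (ascending) and must share the sample
    rate and the step window.
    """

    cell_id: str
    animal_id: str
    group_label: str
    sweeps: list[Sweep] = field(default_factory=list)
    holding_potential_mV: float = -79.0

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise TraceError(f"protocol {self.cell_id!r} has no sweeps")
        self.sweeps = sorted(self.sweeps, key=lambda s: s.step.amplitude_pA)
        amps = [s.step.amplitude_pA for s in self.sweeps]
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise TraceError(
                f"protocol {self.cell_id!r}: step amplitudes must be strictly "
                f"increasing, got {amps}"
            )
        first = self.sweeps[0]
        for s in self.sweeps:
            if not math.isclose(s.sample_khz, first.sample_khz, rel_tol=1e-9):
                raise TraceError(
                    f"protocol {self.cell_id!r}: mixed sample rates "
                    f"({s.sample_khz} vs {first.sample_khz} kHz)"
                )
            if not (math.isclose(s.step.onset_ms, first.step.onset_ms, abs_tol=1e-9)
                    and math.isclose(s.step.offset_ms, first.step.offset_ms,
                                     abs_tol=1e-9)):
                raise TraceError(
                    f"protocol {self.cell_id!r}: sweeps must share the step window"
                )

    @property
    def dt_ms(self) -> float:
        return self.sweeps[0].dt_ms

    @property
    def onset_ms(self) -> float:
        return self.sweeps[0].step.onset_ms

    @property
    def offset_ms(self) -> float:
        return self.sweeps[0].step.offset_ms

    def sweep_at(self, amplitude_pA: float) -> Sweep:
        for s in self.sweeps:
            if math.isclose(s.step.amplitude_pA, amplitude_pA, abs_tol=1e-9):
                return s
        raise TraceError(
            f"protocol {self.cell_id!r}: no sweep with step {amplitude_pA} pA"
        )

    def zero_sweep(self) -> Sweep | None:
        for s in self.sweeps:
            if abs(s.step.amplitude_pA) < 1e-9:
                return s
        return None


# -- unit conventions -------------------------------------------------------

def input_resistance_mohm(delta_v_mV: float, delta_i_pA: float) -> float:
    """Ohm's law in canonical units: MΩ from mV and pA."""
    if delta_i_pA == 0:
        raise ZeroDivisionError("ΔI must be nonzero")
    return delta_v_mV / (delta_i_pA / 1000.0)


def capacitance_pf(tau_m_ms: float, rin_mohm: float) -> float:
    """Membrane capacitance in pF from τm (ms) and Rin (MΩ)."""
    if tau_m_ms <= 0 or rin_mohm <= 0:
        raise ValueError("τm and Rin must be positive")
    return 1000.0 * tau_m_ms / rin_mohm


# -- junction potential -----------------------------------------------------

def correct_junction_potential(sweep: Sweep,
                               jp_mV: float = JUNCTION_POTENTIAL_MV) -> Sweep:
    """Subtract the liquid junction potential from every voltage sample.

    The correction is a pure shift (all inter-sample differences are
    preserved exactly) and may be applied only once per sweep.
    """
    if sweep.junction_corrected:
        raise JunctionStateError(
            "sweep is already junction-corrected; refusing to correct twice"
        )
    return replace(sweep, v=sweep.v - jp_mV, junction_corrected=True)


# -- tabular sweep I/O ------------------------------------------------------

def write_sweeps(protocols: Sequence[StepProtocol], path: str | Path) -> Path:
    """Write protocols to the long-format TSV sweep dialect.

    One row per sample; deterministic column order and shortest-repr float
    formatting (which round-trips float64 exactly), so repeated writes of
    equal protocols are byte-identical.  A sidecar JSON file
    (``<path>.meta.json``) carries per-cell holding potential and the
    junction-correction state.
    """
    path = Path(path)
    meta: dict[str, dict] = {}
    frames = []
    for prot in protocols:
        meta[prot.cell_id] = {
            "animal_id": prot.animal_id,
            "group_label": prot.group_label,
            "holding_potential_mV": float(prot.holding_potential_mV),
            "junction_corrected": all(s.junction_corrected for s in prot.sweeps),
        }
        for idx, s in enumerate(prot.sweeps):
            frames.append(pd.DataFrame({
                "cell_id": prot.cell_id, "animal_id": prot.animal_id,
                "group_label": prot.group_label, "sweep_index": idx,
                "step_pA": float(s.step.amplitude_pA),
                "onset_ms": float(s.step.onset_ms),
                "offset_ms": float(s.step.offset_ms),
                "holding_pA": float(s.holding_pA),
                "sample_khz": float(s.sample_khz),
                "t_ms": s.t, "v_mV": s.v,
            }))
    if frames:
        df = pd.concat(frames, ignore_index=True)[SWEEP_COLUMNS]
        df.to_csv(path, sep="\t", index=False)
    else:
        path.write_text("\t".join(SWEEP_COLUMNS) + "\n")
    meta_path = path.with_name(path.name + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def read_sweeps(path: str | Path, *, junction_potential_mV: float | None = None,
                ) -> list[StepProtocol]:
    """Read protocols from the long-format TSV sweep dialect.

    Returns one :class:`StepProtocol` per ``cell_id`` with sweeps sorted by
    step amplitude.  If ``junction_potential_mV`` is given, sweeps whose
    sidecar metadata marks them as uncorrected are junction-corrected at load
    (the package default convention is post-hoc correction at load time).
    Malformed files raise :class:`TraceError` with row-numbered diagnostics.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={"cell_id": str, "animal_id": str,
                                "group_label": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TraceError(f"{path}: cannot parse sweep file: {exc}") from exc
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"{path}: missing required columns {missing}")
    bad = df[SWEEP_COLUMNS[3:]].isna()
    if bad.to_numpy().any():
        rows = (np.nonzero(bad.to_numpy().any(axis=1))[0] + 2)[:5]
        raise TraceError(f"{path}: malformed numeric fields at rows {rows.tolist()}")

    meta_path = path.with_name(path.name + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    protocols: list[StepProtocol] = []
    for cell_id, cdf in df.groupby("cell_id", sort=True):
        rates = cdf["sample_khz"].unique()
        if len(rates) > 1:
            raise TraceError(
                f"{path}: cell {cell_id!r} mixes sample rates {sorted(rates)}"
            )
        cmeta = meta.get(str(cell_id), {})
        corrected = bool(cmeta.get("junction_corrected", True))
        sweeps = []
        for sweep_index, sdf in cdf.groupby("sweep_index", sort=True):
            t = sdf["t_ms"].to_numpy()
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                first_bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
                raise TraceError(
                    f"{path}: cell {cell_id!r} sweep {sweep_index}: "
                    f"non-monotonic time column near sample {first_bad}"
                )
            row = sdf.iloc[0]
            sweep = Sweep(
                t=t,
                v=sdf["v_mV"].to_numpy(),
                step=CurrentStep(float(row["step_pA"]), float(row["onset_ms"]),
                                 float(row["offset_ms"])),
                holding_pA=float(row["holding_pA"]),
                sample_khz=float(row["sample_khz"]),
                junction_corrected=corrected,
            )
            if not corrected and junction_potential_mV is not None:
                sweep = correct_junction_potential(sweep, junction_potential_mV)
            sweeps.append(sweep)
        protocols.append(StepProtocol(
            cell_id=str(cell_id),
            animal_id=str(cmeta.get("animal_id", cdf["animal_id"].iloc[0])),
            group_label=str(cmeta.get("group_label", cdf["group_label"].iloc[0])),
            sweeps=sweeps,
            holding_potential_mV=float(cmeta.get("holding_potential_mV", -79.0)),
        ))
    return protocols


def protocols_equal(a: StepProtocol, b: StepProtocol) -> bool:
    """Field-level equality of two protocols (exact float comparison)."""
    if (a.cell_id, a.animal_id, a.group_label) != (b.cell_id, b.animal_id,
                                                   b.group_label):
        return False
    if not math.isclose(a.holding_potential_mV, b.holding_potential_mV,
                        rel_tol=0, abs_tol=0.0):
        if a.holding_potential_mV != b.holding_potential_mV:
            return False
    if len(a.sweeps) != len(b.sweeps):
        return False
    for sa, sb in zip(a.sweeps, b.sweeps):
        if sa.step != sb.step:
            return False
        if (sa.holding_pA, sa.sample_khz, sa.junction_corrected) != (
                sb.holding_pA, sb.sample_khz, sb.junction_corrected):
            return False
        if not (np.array_equal(sa.t, sb.t) and np.array_equal(sa.v, sb.v)):
            return False
    return True
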