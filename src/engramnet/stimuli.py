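"""External drive waveforms: constant and half-rectified sinusoidal inputs.

Drives are deterministic current waveforms (mV/ms) injected uniformly into
every neuron of a target population.  A drive routed through a di-synaptic
pathway is injected into the pathway's relay population instead; the
relay's projection onto the target provides the delayed second hop.  The
oscillatory drive is a half-rectified sinusoid — the simplest non-negative
periodic current with a single spectral peak at its nominal frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import SimulationConfig

__all__ = [
    "PathwaySpec",
    "DriveSpec",
    "make_oscillatory_drive",
    "make_constant_drive",
    "render_drive",
]

MONO = "mono_synaptic"
DI = "di_synaptic"


@dataclass(frozen=True)
class PathwaySpec:
    """How a signal reaches its target: directly or through a relay.

    For a di-synaptic pathway the drive current enters the ``relay``
    population and reaches the target through the relay's synapse, so its
    total latency (relay integration + synaptic delay) strictly exceeds the
    mono-synaptic latency onto the same target.
    """

    kind: str = MONO
    relay: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (MONO, DI):
            raise ValueError(f"pathway kind must be {MONO!r} or {DI!r}")
        if self.kind == DI and not self.relay:
            raise ValueError("di-synaptic pathway requires a relay population")
        if self.kind == MONO and self.relay:
            raise ValueError("mono-synaptic pathway must not name a relay")


@dataclass(frozen=True)
class DriveSpec:
    """One external input: target, pathway, waveform kind and window.

    ``amplitude`` is in mV/ms (current that moves an isolated membrane by
    ``amplitude * tau_m`` mV at steady state).  The waveform is exactly zero
    outside ``[onset, offset)``.
    """

    target: str
    kind: str
    amplitude: float
    frequency: float = 0.0
    phase: float = 0.0
    onset: float = 0.0
    offset: float = float("inf")
    pathway: PathwaySpec = field(default_factory=PathwaySpec)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid"):
            raise ValueError("drive kind must be 'constant' or 'sinusoid'")
        if self.amplitude < 0:
            raise ValueError("drive amplitude must be >= 0")
        if self.onset < 0:
            raise ValueError("drive onset must be >= 0")
        if not self.offset > self.onset:
            raise ValueError("drive offset must exceed onset")
        if self.kind == "sinusoid" and self.frequency <= 0:
            raise ValueError("sinusoidal drive requires frequency > 0")

    def effective_target(self) -> str:
        """Population receiving the injected current (relay for di-synaptic)."""
        if self.pathway.kind == DI:
            return self.pathway.relay  # type: ignore[return-value]
        return self.target


def make_oscillatory_drive(
    frequency: float,
    amplitude: float,
    onset: float = 0.0,
    offset: float = float("inf"),
    pathway: PathwaySpec | None = None,
    target: str = "oscillator_I",
    phase: float = 0.0,
) -> DriveSpec:
    """Half-rectified sinusoidal drive at ``frequency`` Hz within the window."""
    return DriveSpec(
        target=target,
        kind="sinusoid",
        amplitude=amplitude,
        frequency=frequency,
        phase=phase,
        onset=onset,
        offset=offset,
        pathway=pathway or PathwaySpec(),
    )


def make_constant_drive(
    amplitude: float,
    onset: float = 0.0,
    offset: float = float("inf"),
    pathway: PathwaySpec | None = None,
    target: str = "oscillator_I",
) -> DriveSpec:
    """Flat drive of the given amplitude within the window."""
    return DriveSpec(
        target=target,
        kind="constant",
        amplitude=amplitude,
        onset=onset,
        offset=offset,
        pathway=pathway or PathwaySpec(),
    )


def render_drive(drive: DriveSpec, config: SimulationConfig) -> np.ndarray:
    """Sample a drive on the simulation grid.

    Returns one current value per step, sampled at the step start; windows
    beyond ``duration`` are truncated silently.  Rendering involves no
    randomness: for a fixed config the waveform is identical on every call.
    """
    n = config.n_steps
    t = np.arange(n) * config.dt
    window = (t >= drive.onset) & (t < drive.offset)
    if drive.kind == "constant":
        wave = np.full(n, drive.amplitude)
    else:
        arg = 2.0 * np.pi * drive.frequency * (t - drive.onset) / 1000.0
        wave = drive.amplitude * np.maximum(np.sin(arg + drive.phase), 0.0)
    return np.where(window, wave, 0.0)
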