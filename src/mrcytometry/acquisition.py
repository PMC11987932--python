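"""Diffusion-weighting acquisitions and gradient waveforms.

Represents single-direction diffusion encodings — pulsed gradient spin echo
(PGSE), cosine-modulated oscillating gradient spin echo (OGSE) and
stimulated-echo (STEAM) sequences — and converts between protocol timing,
explicit gradient waveforms, b-values and effective diffusion times.

The effective diffusion time is the time scale over which molecular
displacement is probed: ``Delta - delta/3`` for pulsed gradients and
``1/(4f)`` for cosine oscillating gradients of frequency ``f``.  Together the
shipped protocol set spans roughly 5–70 ms, the range needed to sense cells
of 5–25 µm.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .constants import GAMMA

__all__ = [
    "DiffusionProtocol",
    "GradientWaveform",
    "make_waveform",
    "b_value",
    "max_b",
    "effective_diffusion_time",
    "default_b_grid",
    "load_protocols",
    "save_protocols",
    "ex_vivo_protocols",
    "ProtocolError",
    "InfeasibleBValueError",
]

SEQUENCE_KINDS = ("PGSE", "OGSE_cosine", "STEAM")

#: Default waveform sampling interval, ms.
DEFAULT_TIME_STEP = 0.01


class ProtocolError(ValueError):
    """Invalid acquisition protocol definition."""


class InfeasibleBValueError(ValueError):
    """Requested b-value exceeds what the gradient hardware limit allows."""


@dataclass(frozen=True)
class DiffusionProtocol:
    """One diffusion acquisition.

    Parameters
    ----------
    kind:
        ``"PGSE"``, ``"OGSE_cosine"`` or ``"STEAM"``.
    delta:
        Gradient lobe duration δ, ms.
    Delta:
        Lobe separation Δ (leading edge to leading edge), ms.
    frequency:
        Oscillation frequency for OGSE, Hz.  ``None`` otherwise.
    b_values:
        Requested b-values, ms/µm², ascending, starting at 0.
    g_max:
        Maximum gradient amplitude, mT/m.
    TE:
        Echo time, ms (must accommodate the waveform).
    protocol_id:
        Short label used to index signal tables.
    """

    kind: str
    delta: float
    Delta: float
    frequency: float | None = None
    b_values: tuple[float, ...] = ()
    g_max: float = 360.0
    TE: float = 55.0
    protocol_id: str = ""

    def __post_init__(self):
        if self.kind not in SEQUENCE_KINDS:
            raise ProtocolError(f"unknown sequence kind {self.kind!r}")
        if not self.delta > 0:
            raise ProtocolError("delta must be positive")
        if self.kind in ("PGSE", "STEAM"):
            if self.Delta < self.delta:
                raise ProtocolError("Delta must be >= delta for pulsed gradients")
            if self.frequency is not None:
                raise ProtocolError("frequency only applies to OGSE")
        else:  # OGSE_cosine
            if self.frequency is None or self.frequency <= 0:
                raise ProtocolError("OGSE requires a positive frequency")
            periods = self.delta * self.frequency * 1e-3  # f in Hz, delta in ms
            if abs(periods - round(periods)) > 1e-9 or round(periods) < 1:
                raise ProtocolError(
                    f"OGSE lobe must contain a whole number of periods; "
                    f"delta*f = {periods:g}"
                )
            if self.Delta < self.delta:
                raise ProtocolError("Delta must be >= delta")
        # STEAM stores magnetization longitudinally between lobes (mixing
        # time), so Delta is not bounded by TE for it.
        if self.kind != "STEAM" and self.Delta + self.delta > self.TE:
            raise ProtocolError("waveform does not fit within TE")
        bvals = tuple(float(b) for b in self.b_values)
        if bvals:
            if any(b < 0 for b in bvals):
                raise ProtocolError("b-values must be non-negative")
            if list(bvals) != sorted(bvals):
                raise ProtocolError("b-values must be ascending")
            if bvals[0] != 0.0:
                raise ProtocolError("first b-value must be 0")
            bmax = max_b(self)
            if bvals[-1] > bmax * (1 + 1e-9):
                raise InfeasibleBValueError(
                    f"b = {bvals[-1]:g} ms/µm² exceeds max_b = {bmax:g} "
                    f"at g_max = {self.g_max:g} mT/m"
                )
        object.__setattr__(self, "b_values", bvals)
        if not self.protocol_id:
            object.__setattr__(self, "protocol_id", self._default_id())

    def _default_id(self) -> str:
        if self.kind == "OGSE_cosine":
            return f"ogse{self.frequency:g}Hz_{self.delta:g}_{self.Delta:g}"
        stem = "pgse" if self.kind == "PGSE" else "steam"
        return f"{stem}_{self.delta:g}_{self.Delta:g}"

    @property
    def n_periods(self) -> int | None:
        """Whole cosine periods per lobe (OGSE only)."""
        if self.kind != "OGSE_cosine":
            return None
        return round(self.delta * self.frequency * 1e-3)

    def with_b_values(self, b_values) -> "DiffusionProtocol":
        return replace(self, b_values=tuple(float(b) for b in b_values))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "delta_ms": self.delta,
            "Delta_ms": self.Delta,
            "frequency_hz": self.frequency,
            "b_values_ms_per_um2": list(self.b_values),
            "g_max_mT_per_m": self.g_max,
            "TE_ms": self.TE,
            "protocol_id": self.protocol_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionProtocol":
        return cls(
            kind=d["kind"],
            delta=float(d["delta_ms"]),
            Delta=float(d["Delta_ms"]),
            frequency=(None if d.get("frequency_hz") in (None, "")
                       else float(d["frequency_hz"])),
            b_values=tuple(d.get("b_values_ms_per_um2", ())),
            g_max=float(d.get("g_max_mT_per_m", 360.0)),
            TE=float(d.get("TE_ms", 55.0)),
            protocol_id=d.get("protocol_id", ""),
        )


@dataclass(frozen=True)
class GradientWaveform:
    """Sampled effective (refocused) gradient waveform, one spatial direction.

    ``samples[n]`` is the average gradient amplitude (mT/m) over
    ``[n*time_step, (n+1)*time_step)``; the refocusing-pulse sign convention
    is already applied so the samples integrate to zero.
    """

    time_step: float
    samples: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, float))
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) * self.time_step

    @property
    def amplitude(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0

    def q(self) -> np.ndarray:
        """Cumulative gradient moment γ∫g dt at sample boundaries (rad/µm)."""
        return GAMMA * np.concatenate(
            ([0.0], np.cumsum(self.samples) * self.time_step)
        )


def _segment_average(shape, t0: float, t1: float, n: int, dt: float) -> np.ndarray:
    """Average an analytic lobe shape over each sampling interval.

    ``shape(a, b)`` must return the exact integral of the lobe over [a, b]
    clipped to the lobe's support [t0, t1].
    """
    edges = np.arange(n + 1) * dt
    lo = np.clip(edges[:-1], t0, t1)
    hi = np.clip(edges[1:], t0, t1)
    return shape(lo, hi) / dt


def _unit_waveform(protocol: DiffusionProtocol, time_step: float) -> np.ndarray:
    """Unit-amplitude effective waveform samples for the protocol."""
    T = protocol.Delta + protocol.delta
    n = int(math.ceil(T / time_step - 1e-12))
    d, D = protocol.delta, protocol.Delta
    if protocol.kind in ("PGSE", "STEAM"):
        lobe1 = _segment_average(lambda lo, hi: hi - lo, 0.0, d, n, time_step)
        lobe2 = _segment_average(lambda lo, hi: hi - lo, D, D + d, n, time_step)
    else:
        w = 2 * math.pi * protocol.frequency * 1e-3  # rad/ms

        def cos_int(t0):
            def integ(lo, hi):
                return (np.sin(w * (hi - t0)) - np.sin(w * (lo - t0))) / w
            return integ

        lobe1 = _segment_average(cos_int(0.0), 0.0, d, n, time_step)
        lobe2 = _segment_average(cos_int(D), D, D + d, n, time_step)
    return lobe1 - lobe2


def b_value(waveform: GradientWaveform) -> float:
    """Diffusion weighting b = γ²∫₀ᵀ q(t)² dt of a refocused waveform, ms/µm².

    Exact for the piecewise-constant sample representation (q is piecewise
    linear).  For a rectangular PGSE this equals the closed form
    γ²g²δ²(Δ−δ/3).  Raises if the waveform is not refocused.
    """
    g = waveform.samples
    if len(g) == 0:
        return 0.0
    dt = waveform.time_step
    net = abs(np.sum(g)) * dt
    scale = max(np.max(np.abs(g)) * waveform.duration, 1e-300)
    if net > 1e-9 * scale:
        raise ValueError("waveform is not refocused (nonzero zeroth moment)")
    q = GAMMA * np.concatenate(([0.0], np.cumsum(g)[:-1] * dt))  # at left edges
    s = GAMMA * g
    # ∫ (q + s·t)² dt over each interval of length dt
    return float(np.sum(q * q * dt + q * s * dt * dt + s * s * dt ** 3 / 3.0))


def make_waveform(
    protocol: DiffusionProtocol, b: float, time_step: float = DEFAULT_TIME_STEP
) -> GradientWaveform:
    """Build the gradient waveform realizing b-value ``b`` for a protocol.

    The amplitude is solved from the request so that the numerically
    integrated b of the sampled waveform equals ``b`` to machine precision.
    Raises :class:`InfeasibleBValueError` if the required amplitude exceeds
    ``protocol.g_max``.
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    unit = _unit_waveform(protocol, time_step)
    if b == 0:
        return GradientWaveform(time_step, np.zeros_like(unit))
    b_unit = b_value(GradientWaveform(time_step, unit))
    amp = math.sqrt(b / b_unit)
    # tolerate sub-0.1% overshoot from re-deriving max_b at a coarser sampling
    if amp > protocol.g_max * (1 + 1e-3):
        raise InfeasibleBValueError(
            f"b = {b:g} ms/µm² needs {amp:.1f} mT/m > g_max = {protocol.g_max:g}"
        )
    return GradientWaveform(time_step, unit * amp)


def max_b(protocol: DiffusionProtocol, g_max: float | None = None,
          time_step: float = DEFAULT_TIME_STEP) -> float:
    """Largest achievable b-value (ms/µm²) at the hardware amplitude limit."""
    g = protocol.g_max if g_max is None else g_max
    if g < 0:
        raise ValueError("g_max must be non-negative")
    unit = _unit_waveform(protocol, time_step)
    return g * g * b_value(GradientWaveform(time_step, unit))


def effective_diffusion_time(protocol: DiffusionProtocol) -> float:
    """Effective diffusion time t_diff, ms.

    ``1/(4f)`` for cosine OGSE of frequency f; ``Δ − δ/3`` for PGSE and
    STEAM (the standard pulsed-gradient convention).
    """
    if protocol.kind == "OGSE_cosine":
        return 1.0 / (4.0 * protocol.frequency * 1e-3)
    return protocol.Delta - protocol.delta / 3.0


def default_b_grid(
    protocol: DiffusionProtocol | None = None,
    b_max: float = 1.0,
    n: int = 5,
    decades: float = 1.0,
) -> tuple[float, ...]:
    """b = 0 plus ``n−1`` log-spaced values ending at ``b_max``, ms/µm².

    Since a logarithmic ladder cannot contain 0, "equally log-spaced from 0"
    is realized as {0} ∪ {log-spaced values spanning ``decades`` decades up
    to ``b_max``}.  When a protocol is given, ``b_max`` is capped at its
    achievable maximum.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    if protocol is not None:
        b_max = min(b_max, max_b(protocol))
    if n == 2:
        return (0.0, b_max)
    nonzero = np.geomspace(b_max * 10.0 ** (-decades), b_max, n - 1)
    nonzero[-1] = b_max
    return (0.0, *[float(b) for b in nonzero])


# ---------------------------------------------------------------------------
# protocol file I/O


def load_protocols(path: str | Path) -> list[DiffusionProtocol]:
    """Read protocols from a YAML or JSON file (list of mappings)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = data["protocols"]
    return [DiffusionProtocol.from_dict(d) for d in data]


def save_protocols(protocols, path: str | Path) -> None:
    path = Path(path)
    data = {"protocols": [p.to_dict() for p in protocols]}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def ex_vivo_protocols(b_max: float = 1.0, n_b: int = 5) -> list[DiffusionProtocol]:
    """The packaged four-protocol ex-vivo set.

    PGSE δ/Δ = 3/11 and 3/31 ms, cosine OGSE 50 Hz δ/Δ = 20/25 ms and STEAM
    δ/Δ = 3/71 ms at g_max = 360 mT/m, each with five b-values spaced at
    equal logarithmic intervals from 0 up to 1 ms/µm² (1000 s/mm²) or the
    hardware maximum, whichever is lower.
    """
    ref = importlib.resources.files("mrcytometry.data") / "ex_vivo_protocols.yaml"
    with importlib.resources.as_file(ref) as path:
        protocols = load_protocols(path)
    out = []
    for p in protocols:
        if not p.b_values:
            p = p.with_b_values(default_b_grid(p, b_max=b_max, n=n_b))
        out.append(p)
    return out
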