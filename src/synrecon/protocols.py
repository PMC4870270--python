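"""Stimulation protocols: jittered low- and high-frequency spike trains and
global event timelines (LFS blocks, HFS, protein-synthesis inhibition,
dopamine) for the reconsolidation paradigms.

Times are seconds throughout.  Low-frequency stimulation (LFS) is a jittered
periodic train: each presynaptic neuron receives one spike per period, shifted
by a Gaussian delay (SD 3 ms by default).  High-frequency stimulation (HFS)
is the same construction at 100 Hz for 60 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimBlock",
    "Protocol",
    "SpikeTrainSet",
    "InvalidProtocolError",
    "HFS_RATE",
    "HFS_DURATION",
    "DEFAULT_JITTER_SD",
    "generate_lfs",
    "generate_hfs",
    "build_paradigm",
    "scale_protocol",
    "PARADIGM_NAMES",
]

HFS_RATE = 100.0  # Hz
HFS_DURATION = 60.0  # s
DEFAULT_JITTER_SD = 3e-3  # s


class InvalidProtocolError(ValueError):
    """Raised for malformed stimulation blocks or timelines."""


@dataclass(frozen=True)
class StimBlock:
    """A block of periodic, jittered presynaptic stimulation."""

    t_start: float
    t_end: float
    rate: float
    jitter_sd: float = DEFAULT_JITTER_SD

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidProtocolError(
                f"block end {self.t_end} must exceed start {self.t_start}"
            )
        if not self.rate > 0:
            raise InvalidProtocolError(f"rate must be positive, got {self.rate}")
        if self.jitter_sd < 0:
            raise InvalidProtocolError("jitter_sd must be non-negative")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def nominal_pulse_times(self) -> np.ndarray:
        """Nominal (unjittered) pulse times: one pulse per period 1/rate."""
        n = int(np.floor(self.duration * self.rate + 1e-9))
        return self.t_start + np.arange(n) / self.rate


@dataclass(frozen=True)
class Protocol:
    """Global event timeline for one experiment.

    ``psi_window`` and ``dopamine_window`` are (t_start, t_end) pairs or None.
    The dopamine pulse models the reward/novelty signal that accompanies LTP
    induction and must co-occur with an HFS event.
    """

    duration: float
    lfs_blocks: tuple[StimBlock, ...] = ()
    hfs_events: tuple[float, ...] = ()
    psi_window: Optional[tuple[float, float]] = None
    dopamine_window: Optional[tuple[float, float]] = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "lfs_blocks", tuple(self.lfs_blocks))
        object.__setattr__(self, "hfs_events", tuple(self.hfs_events))
        if self.duration <= 0:
            raise InvalidProtocolError("protocol duration must be positive")
        for blk in self.lfs_blocks:
            if blk.t_start < 0 or blk.t_end > self.duration + 1e-9:
                raise InvalidProtocolError(
                    f"LFS block [{blk.t_start}, {blk.t_end}] outside protocol"
                )
        for t in self.hfs_events:
            if not (0 <= t and t + HFS_DURATION <= self.duration + 1e-9):
                raise InvalidProtocolError(f"HFS at {t} s does not fit protocol")
        for label, win in (("psi", self.psi_window), ("dopamine", self.dopamine_window)):
            if win is not None:
                a, b = win
                if not (0 <= a < b <= self.duration + 1e-9):
                    raise InvalidProtocolError(
                        f"{label} window {win} is degenerate or outside protocol"
                    )
        if self.dopamine_window is not None:
            a, b = self.dopamine_window
            if not any(a <= t <= b or t <= a <= t + HFS_DURATION for t in self.hfs_events):
                raise InvalidProtocolError(
                    "dopamine window must co-occur with an HFS event"
                )

    # --- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "duration": self.duration,
            "lfs_blocks": [asdict(b) for b in self.lfs_blocks],
            "hfs_events": list(self.hfs_events),
            "psi_window": list(self.psi_window) if self.psi_window else None,
            "dopamine_window": (
                list(self.dopamine_window) if self.dopamine_window else None
            ),
            "name": self.name,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        doc = json.loads(text)
        return cls(
            duration=doc["duration"],
            lfs_blocks=tuple(StimBlock(**b) for b in doc["lfs_blocks"]),
            hfs_events=tuple(doc["hfs_events"]),
            psi_window=tuple(doc["psi_window"]) if doc.get("psi_window") else None,
            dopamine_window=(
                tuple(doc["dopamine_window"]) if doc.get("dopamine_window") else None
            ),
            name=doc.get("name", ""),
        )

    def lfs_pulse_times(self) -> np.ndarray:
        """All nominal LFS pulse times, sorted (used by the reduced model)."""
        if not self.lfs_blocks:
            return np.empty(0)
        return np.sort(np.concatenate([b.nominal_pulse_times() for b in self.lfs_blocks]))


@dataclass
class SpikeTrainSet:
    """Per-neuron presynaptic spike times (sorted, seconds)."""

    n_neurons: int
    spikes: list  # list of np.ndarray

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes flattened and time-sorted; returns (times, neuron_ids)."""
        if self.n_neurons == 0:
            return np.empty(0), np.empty(0, dtype=np.int32)
        times = np.concatenate(self.spikes)
        ids = np.concatenate(
            [np.full(len(s), i, dtype=np.int32) for i, s in enumerate(self.spikes)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], ids[order]

    def extend(self, other: "SpikeTrainSet") -> None:
        if other.n_neurons != self.n_neurons:
            raise ValueError("neuron count mismatch")
        self.spikes = [
            np.sort(np.concatenate([a, b])) for a, b in zip(self.spikes, other.spikes)
        ]

    def to_tsv(self, path) -> None:
        times, ids = self.merged()
        np.savetxt(path, np.column_stack([ids, times]), fmt=("%d", "%.6f"),
                   delimiter="\t", header="neuron_id\ttime_s", comments="")


def _jittered(block: StimBlock, n_neurons: int, rng: np.random.Generator) -> list:
    nominal = block.nominal_pulse_times()
    out = []
    for _ in range(n_neurons):
        t = nominal + rng.normal(0.0, block.jitter_sd, size=nominal.size)
        # jitter may push a spike across the block boundary; clip and re-sort
        np.clip(t, block.t_start, np.nextafter(block.t_end, -np.inf), out=t)
        out.append(np.sort(t))
    return out


def generate_lfs(block: StimBlock, n_neurons: int, seed: int) -> SpikeTrainSet:
    """One jittered spike per period per neuron, independent across neurons."""
    if n_neurons < 1:
        raise InvalidProtocolError("n_neurons must be >= 1")
    rng = np.random.default_rng(seed)
    return SpikeTrainSet(n_neurons, _jittered(block, n_neurons, rng))


def generate_hfs(t_start: float, n_neurons: int, seed: int,
                 jitter_sd: float = DEFAULT_JITTER_SD) -> SpikeTrainSet:
    """100 Hz for 60 s with the same Gaussian jitter as LFS."""
    if t_start < 0:
        raise InvalidProtocolError("HFS start must be non-negative")
    block = StimBlock(t_start, t_start + HFS_DURATION, HFS_RATE, jitter_sd)
    rng = np.random.default_rng(seed)
    return SpikeTrainSet(n_neurons, _jittered(block, n_neurons, rng))


# --------------------------------------------------------------------------
# Paradigm presets (full scale, seconds).  The induction phase is common to
# all paradigms: background 0.1 Hz stimulation with one HFS at minute 20.
# PSI windows reproduce the qualitative classification (paradigms 1, 3, 4
# persist; paradigm 2 degrades); see docs/methods.md for the reservoir budget
# arithmetic behind the choices.

_MIN = 60.0
_HR = 3600.0

PARADIGM_NAMES = ("p1", "p2", "p3", "p4", "fig3", "fig3_grid", "fig5")


def _paradigm_defaults(name: str) -> dict:
    lfs = lambda a, b, rate=0.1: StimBlock(a, b, rate)
    hfs_t = 20 * _MIN
    dopa = (hfs_t, hfs_t + HFS_DURATION)
    if name == "p1":
        return dict(
            duration=10 * _HR,
            lfs_blocks=(lfs(0, 40 * _MIN), lfs(8 * _HR, 10 * _HR)),
            hfs_events=(hfs_t,),
            psi_window=(100 * _MIN, 200 * _MIN),
            dopamine_window=dopa,
        )
    if name in ("p2", "fig5"):
        return dict(
            duration=10 * _HR,
            lfs_blocks=(lfs(0, 40 * _MIN), lfs(150 * _MIN, 170 * _MIN),
                        lfs(8 * _HR, 10 * _HR)),
            hfs_events=(hfs_t,),
            psi_window=(100 * _MIN, 200 * _MIN),
            dopamine_window=dopa,
        )
    if name == "p3":
        return dict(
            duration=10 * _HR,
            lfs_blocks=(lfs(0, 100 * _MIN), lfs(150 * _MIN, 170 * _MIN),
                        lfs(8 * _HR, 10 * _HR)),
            hfs_events=(hfs_t,),
            psi_window=(100 * _MIN, 200 * _MIN),
            dopamine_window=dopa,
        )
    if name == "p4":
        return dict(
            duration=10 * _HR,
            lfs_blocks=(lfs(0, 10 * _HR),),
            hfs_events=(hfs_t,),
            psi_window=(100 * _MIN, 140 * _MIN),
            dopamine_window=dopa,
        )
    if name in ("fig3", "fig3_grid"):
        # 40 min initiation (HFS at 20 min), then a stimulation window and a
        # PSI window both centered at minute 150; readout at minute 280.
        return dict(
            duration=280 * _MIN,
            stim_duration=20 * _MIN,
            psi_duration=2 * _HR,
            center=150 * _MIN,
        )
    raise KeyError(name)


def build_paradigm(name: str, overrides: Optional[dict] = None) -> Protocol:
    """Build the full timeline for a named paradigm; all fields overridable.

    ``fig3``/``fig3_grid`` accept ``stim_duration``, ``psi_duration`` and
    ``center`` overrides and build the corresponding boundary-condition cell
    (stimulation and PSI windows centered on the same time).
    """
    if name not in PARADIGM_NAMES:
        raise InvalidProtocolError(
            f"unknown paradigm {name!r}; valid names: {', '.join(PARADIGM_NAMES)}"
        )
    spec = _paradigm_defaults(name)
    if overrides:
        unknown = set(overrides) - set(spec)
        if unknown:
            raise InvalidProtocolError(
                f"unknown override(s) {sorted(unknown)} for paradigm {name!r}"
            )
        spec.update(overrides)

    if name in ("fig3", "fig3_grid"):
        duration = spec["duration"]
        s, d, c = spec["stim_duration"], spec["psi_duration"], spec["center"]
        hfs_t = 20 * _MIN
        blocks = [StimBlock(0, 40 * _MIN, 0.1)]
        if s > 0:
            blocks.append(StimBlock(max(c - s / 2, 40 * _MIN + 1e-6),
                                    min(c + s / 2, duration), 0.1))
        psi = (c - d / 2, c + d / 2) if d > 0 else None
        return Protocol(
            duration=duration,
            lfs_blocks=tuple(blocks),
            hfs_events=(hfs_t,),
            psi_window=psi,
            dopamine_window=(hfs_t, hfs_t + HFS_DURATION),
            name=name,
        )
    return Protocol(name=name, **spec)


def scale_protocol(protocol: Protocol, time_factor: float,
                   rate_factor: Optional[float] = None) -> Protocol:
    """Compress a timeline by ``time_factor`` (e.g. 10 for the fast preset).

    LFS rates are multiplied by ``rate_factor`` (defaults to ``time_factor``)
    so each block delivers the same number of pulses.  HFS events keep their
    native 100 Hz / 60 s shape: the induction cascade (gate, dopamine,
    consolidation) is driven by the absolute number of induction pairings and
    must not be thinned.
    """
    if rate_factor is None:
        rate_factor = time_factor
    f = 1.0 / time_factor
    blocks = tuple(
        StimBlock(b.t_start * f, b.t_end * f, b.rate * rate_factor, b.jitter_sd)
        for b in protocol.lfs_blocks
    )
    hfs = tuple(t * f for t in protocol.hfs_events)
    psi = tuple(t * f for t in protocol.psi_window) if protocol.psi_window else None
    dopa = (
        (protocol.dopamine_window[0] * f,
         protocol.dopamine_window[0] * f + HFS_DURATION)
        if protocol.dopamine_window else None
    )
    return Protocol(
        duration=protocol.duration * f,
        lfs_blocks=blocks,
        hfs_events=hfs,
        psi_window=psi,
        dopamine_window=dopa,
        name=protocol.name + f"/x{time_factor:g}",
    )
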