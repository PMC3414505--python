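"""Block-design timing: boxcar regressors and FSL-style three-column events.

The default parameters encode the functional reference battery run layout:
twelve alternating 28-s off/on blocks of seven volumes at TR 4 s, preceded
by three magnetisation-stabilisation volumes that are discarded before
analysis.  All retained-volume time axes start at t = 0 at the first
retained volume; the stabilisation volumes exist only in the total-duration
bookkeeping and timing export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DesignSpec", "make_boxcar", "design_events", "boxcar_from_events"]


@dataclass(frozen=True)
class DesignSpec:
    """Timing of one block-design run.

    Parameters
    ----------
    n_blocks
        Total number of blocks (off + on).  Must be even so that off and on
        blocks alternate in equal numbers.
    vols_per_block
        Volumes acquired per block.
    tr
        Repetition time in seconds.
    n_stabilization
        Leading volumes discarded before analysis.
    first_block_state
        State of the first retained block, ``"off"`` or ``"on"``.
    """

    n_blocks: int = 12
    vols_per_block: int = 7
    tr: float = 4.0
    n_stabilization: int = 3
    first_block_state: str = "off"

    def __post_init__(self) -> None:
        if self.n_blocks < 0 or self.n_blocks % 2 != 0:
            raise ValueError(
                f"n_blocks must be even and non-negative, got {self.n_blocks}"
            )
        if self.vols_per_block <= 0:
            raise ValueError("vols_per_block must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_stabilization < 0:
            raise ValueError("n_stabilization must be non-negative")
        if self.first_block_state not in ("off", "on"):
            raise ValueError("first_block_state must be 'off' or 'on'")

    @property
    def n_volumes(self) -> int:
        """Retained volumes (stabilisation volumes excluded)."""
        return self.n_blocks * self.vols_per_block

    @property
    def block_duration(self) -> float:
        """Duration of one block in seconds."""
        return self.vols_per_block * self.tr

    @property
    def total_duration(self) -> float:
        """Run duration in seconds, including stabilisation volumes."""
        return (self.n_stabilization + self.n_volumes) * self.tr


def make_boxcar(design: DesignSpec) -> np.ndarray:
    """Return the per-volume 0/1 stimulation time-course.

    The output has ``design.n_volumes`` entries, alternating runs of zeros
    ('off') and ones ('on') starting with ``design.first_block_state``.
    """
    first_on = 1 if design.first_block_state == "on" else 0
    states = np.fromiter(
        ((b + first_on) % 2 for b in range(design.n_blocks)), dtype=np.int64,
        count=design.n_blocks,
    )
    return np.repeat(states, design.vols_per_block)


def design_events(design: DesignSpec) -> np.ndarray:
    """Three-column event rows (onset s, duration s, value) for 'on' blocks.

    Onsets are relative to the first retained volume, matching the timeline
    on which the boxcar and all analyses are defined.
    """
    first_on = 1 if design.first_block_state == "on" else 0
    onsets = [
        b * design.block_duration
        for b in range(design.n_blocks)
        if (b + first_on) % 2 == 1
    ]
    if not onsets:
        return np.empty((0, 3), dtype=float)
    rows = np.column_stack(
        [onsets, np.full(len(onsets), design.block_duration), np.ones(len(onsets))]
    )
    return rows


def boxcar_from_events(
    events: np.ndarray, n_volumes: int, tr: float
) -> np.ndarray:
    """Sample a three-column event table onto the retained-volume grid.

    Volume ``i`` is sampled at time ``i * tr``; a volume takes the event's
    value when ``onset <= t < onset + duration``.  Events extending past the
    retained timeline raise ``ValueError``.
    """
    events = np.asarray(events, dtype=float)
    if events.ndim != 2 or events.shape[1] != 3:
        raise ValueError("events must be an (n, 3) array of onset/duration/value")
    if events.shape[0] == 0:
        raise ValueError("event table is empty")
    t_end = n_volumes * tr
    if np.any(events[:, 0] < 0) or np.any(events[:, 0] + events[:, 1] > t_end):
        raise ValueError("events extend outside the retained-volume timeline")
    t = np.arange(n_volumes) * tr
    out = np.zeros(n_volumes)
    for onset, duration, value in events:
        out[(t >= onset) & (t < onset + duration)] += value
    return out
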