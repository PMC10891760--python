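"""Cardiac-dimension partitioning of a 5D series across devices.

The cardiac axis (Nc phases) is split into consecutive, disjoint ranges, one
per device, covering phases 1..Nc.  The temporal-TV gradient couples each
frame to its phase neighbours, so a device additionally holds read-only
"ghost" copies of the boundary cardiac phase of each neighbouring device:
one ghost phase for the end devices, two for interior devices.  Each cardiac
phase carries all Nr respiratory phases, so a device with ``e`` assigned
phases and ``g`` ghost phases is resident for ``(e + g) * Nr`` 3D frames.

Phase indices are 0-based internally; serialized plans and messages report
them 1-based (device 1 starts at cardiac phase 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "DevicePartition",
    "PartitionPlan",
    "partition_cardiac",
    "resident_frame_count",
    "dependency_pairs",
]


@dataclass(frozen=True)
class DevicePartition:
    """One device's consecutive cardiac-phase range plus ghost requirements.

    ``start``/``stop`` delimit the assigned range as a 0-based half-open
    interval.  ``ghost_left``/``ghost_right`` say whether the device needs
    the cardiac phase just before/after its range from a neighbour (false
    exactly for the first/last device respectively).
    """

    device_index: int  # 0-based
    start: int
    stop: int
    ghost_left: bool
    ghost_right: bool

    @property
    def n_phases(self) -> int:
        return self.stop - self.start

    @property
    def n_ghosts(self) -> int:
        return int(self.ghost_left) + int(self.ghost_right)

    def to_dict(self) -> dict:
        # 1-based inclusive range for human-readable reports
        return {
            "device": self.device_index + 1,
            "cardiac_range": [self.start + 1, self.stop],
            "ghost_left": self.ghost_left,
            "ghost_right": self.ghost_right,
        }


@dataclass(frozen=True)
class PartitionPlan:
    """Ordered device partitions covering cardiac phases 1..Nc exactly."""

    partitions: tuple[DevicePartition, ...]
    nc: int
    nr: int

    @property
    def n_devices(self) -> int:
        return len(self.partitions)

    def __post_init__(self) -> None:
        d = self.n_devices
        if d < 1 or d > self.nc:
            raise ValueError(f"need 1 <= d <= Nc, got d={d}, Nc={self.nc}")
        cursor = 0
        for q, p in enumerate(self.partitions):
            if p.device_index != q:
                raise ValueError("partitions must be ordered by device index")
            if p.start != cursor or p.stop <= p.start:
                raise ValueError(
                    f"device {q + 1} range [{p.start + 1}, {p.stop}] breaks coverage "
                    f"of 1..{self.nc}"
                )
            if p.ghost_left != (q > 0) or p.ghost_right != (q < d - 1):
                raise ValueError(f"device {q + 1} has inconsistent ghost flags")
            cursor = p.stop
        if cursor != self.nc:
            raise ValueError(f"ranges cover 1..{cursor}, expected 1..{self.nc}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "nc": self.nc,
                "nr": self.nr,
                "n_devices": self.n_devices,
                "partitions": [p.to_dict() for p in self.partitions],
            },
            indent=2,
        )


def _share_sizes(nc: int, capacities: Sequence[float]) -> list[int]:
    """Phase counts per device: proportional shares, largest-remainder rounding.

    Equal capacities reduce to floor(Nc/d) each with the remainder handed to
    the lowest-indexed devices.  Every device ends with at least one phase.
    """
    d = len(capacities)
    total = float(sum(capacities))
    quotas = [nc * c / total for c in capacities]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    # hand leftover phases to the largest remainders, ties to the lowest index
    order = sorted(range(d), key=lambda i: (-remainders[i], i))
    for i in range(nc - sum(sizes)):
        sizes[order[i % d]] += 1
    # no device may be empty: take from the largest
    for i in range(d):
        while sizes[i] == 0:
            donor = max(range(d), key=lambda q: (sizes[q], -q))
            sizes[donor] -= 1
            sizes[i] += 1
    return sizes


def partition_cardiac(
    nc: int,
    nr: int,
    capacities: Sequence[float] | None = None,
    n_devices: int | None = None,
    split: Sequence[int] | None = None,
) -> PartitionPlan:
    """Partition Nc cardiac phases across devices, in device order.

    ``capacities`` are abstract positive weights (e.g. relative memory); equal
    weights give balanced ranges with the remainder on the lowest-indexed
    devices.  ``split`` is an explicit per-device phase-count override for
    capacity-to-phase policies the proportional rule cannot express.
    """
    if nc < 2 or nr < 1:
        raise ValueError(f"need Nc >= 2 and Nr >= 1, got Nc={nc}, Nr={nr}")
    if split is not None:
        sizes = [int(s) for s in split]
        if capacities is not None and len(capacities) != len(sizes):
            raise ValueError("split and capacities disagree on device count")
        if any(s < 1 for s in sizes):
            raise ValueError(f"split entries must be >= 1, got {sizes}")
        if sum(sizes) != nc:
            raise ValueError(f"split {sizes} must sum to Nc={nc}")
    else:
        if capacities is None:
            capacities = [1.0] * (n_devices if n_devices is not None else 1)
        capacities = [float(c) for c in capacities]
        d = len(capacities)
        if d < 1 or d > nc:
            raise ValueError(f"need 1 <= d <= Nc devices, got d={d}, Nc={nc}")
        if any(c <= 0 for c in capacities):
            raise ValueError(f"capacities must be positive, got {capacities}")
        sizes = _share_sizes(nc, capacities)
    d = len(sizes)
    if d > nc:
        raise ValueError(f"need d <= Nc, got d={d}, Nc={nc}")
    parts = []
    cursor = 0
    for q, size in enumerate(sizes):
        parts.append(
            DevicePartition(
                device_index=q,
                start=cursor,
                stop=cursor + size,
                ghost_left=q > 0,
                ghost_right=q < d - 1,
            )
        )
        cursor += size
    return PartitionPlan(partitions=tuple(parts), nc=nc, nr=nr)


def resident_frame_count(p: DevicePartition, nr: int) -> int:
    """3D frames resident on a device: assigned phases plus ghosts, times Nr."""
    return (p.n_phases + p.n_ghosts) * nr


def dependency_pairs(plan: PartitionPlan) -> list[tuple[int, int, int]]:
    """Directed (producer, consumer, cardiac phase) triples, 1-based.

    Each interior boundary between devices q and q+1 yields two dependencies:
    q produces its last assigned phase for q+1, and q+1 produces its first
    assigned phase for q — 2(d-1) in total.
    """
    pairs = []
    for left, right in zip(plan.partitions, plan.partitions[1:]):
        q, r = left.device_index + 1, right.device_index + 1
        pairs.append((q, r, left.stop))  # left.stop == last phase of q, 1-based
        pairs.append((r, q, right.start + 1))
    return pairs
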