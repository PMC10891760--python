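"""Partitioned reconstruction: one NESTA solver per simulated device.

The cardiac axis is split across devices (see :mod:`cine5d.partition`); each
device runs the staged NESTA iteration on its assigned frames, evaluating the
data-fidelity term frame-locally and the temporal-TV term on its assigned
frames extended by read-only ghost copies of the neighbouring boundary
cardiac phases.  Because the regularization gradient at a frame depends only
on the immediately adjacent phases, exchanging those boundary frames once
per iteration reproduces the unpartitioned gradient exactly.

Synchronization points (per stage):

  S.0  before the stage loop, devices share computed constants (the maxima
       that fix the continuation schedule), so all devices run the same mu
       and Lipschitz values as the unpartitioned solver;
  S.1  a stage barrier: no device starts stage s+1 until all finished s, and
       payloads never cross stages;
  S.2  just before the gradient computation, devices publish their boundary
       frames into per-dependency channels (one channel per dependency,
       exclusive replace, last writer wins);
  S.3  devices retrieve their ghost frames from the channels, reusing the
       latest payload when the producer published nothing new;
  S.4  a device that converges early publishes its final stage solution;
  S.5  and notifies its dependents, which keep iterating on that payload.

Execution modes: ``lockstep`` advances all devices round-robin in device
order (deterministic, bit-reproducible); ``concurrent`` runs one thread per
device with the same per-iteration exchange discipline; ``single`` is the
degenerate one-device case.  With ``local_stopping`` each device halts on
the progress quotient of its own local objective (assigned-frame fidelity
plus every temporal difference touching its frames); with it disabled the
stopping statistic is the global objective of the assembled iterate, forcing
all devices through identical iteration counts.
"""

from __future__ import annotations

import json
import threading
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from cine5d.data_model import (
    CoilSet,
    ImageSeries5D,
    KSpace5D,
    ObjectiveHistory,
    ReconConfig,
)
from cine5d.nesta import (
    DivergenceError,
    SolverState,
    _schedule_from_constants,
)
from cine5d.operators import (
    HuberParams,
    apply_encoding_adjoint,
    objective,
    objective_and_gradient,
    ttv_forward,
)
from cine5d.partition import DevicePartition, PartitionPlan, dependency_pairs, partition_cardiac

__all__ = [
    "DependencyChannel",
    "DeviceRun",
    "TraceLog",
    "share_constants",
    "run_partitioned",
]


class TraceLog:
    """Thread-safe, line-oriented structured log of orchestration events."""

    def __init__(self) -> None:
        self.events: list[dict] = []
        self._lock = threading.Lock()

    def add(
        self,
        device: int,
        stage: int,
        iteration: int,
        event: str,
        stamp: tuple[int, int] | None = None,
        phase: int | None = None,
    ) -> None:
        entry = {"device": device + 1, "stage": stage, "iteration": iteration, "event": event}
        if stamp is not None:
            entry["stamp"] = [stamp[0], stamp[1]]
        if phase is not None:
            entry["phase"] = phase + 1
        with self._lock:
            self.events.append(entry)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e) for e in self.events)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_jsonl() + "\n")


class DependencyChannel:
    """One buffered communication channel for a single frame dependency.

    Exactly one producer and one consumer.  ``publish`` replaces the payload
    under the channel mutex (no torn reads); ``retrieve`` never blocks on an
    absent update — it simply returns the latest stamped payload.
    """

    def __init__(self, producer: int, consumer: int, phase: int):
        self.producer = producer  # 0-based device index
        self.consumer = consumer
        self.phase = phase  # 0-based global cardiac phase
        self._payload: np.ndarray | None = None
        self._stamp: tuple[int, int] | None = None
        self._lock = threading.Lock()

    def publish(self, frames: np.ndarray, stamp: tuple[int, int]) -> None:
        payload = np.array(frames)  # snapshot before swapping in
        with self._lock:
            self._payload = payload
            self._stamp = stamp

    def retrieve(self) -> tuple[np.ndarray, tuple[int, int]]:
        with self._lock:
            if self._payload is None:
                raise RuntimeError(
                    f"channel {self.producer + 1}->{self.consumer + 1} "
                    f"(phase {self.phase + 1}) retrieved before any publish"
                )
            return self._payload, self._stamp


def share_constants(local_values: Sequence[float]) -> float:
    """S.0 reduction: the global maximum of per-device constants.

    Every device receives the same value, so local continuation schedules
    coincide with the unpartitioned ones.  Reduction runs in ascending device
    order (irrelevant for max, fixed for reproducibility).
    """
    result = None
    for q, v in enumerate(local_values):
        v = float(v)
        if not np.isfinite(v):
            raise ValueError(f"device {q + 1} shared a non-finite constant: {v}")
        result = v if result is None or v > result else result
    if result is None:
        raise ValueError("share_constants needs at least one value")
    return result


class DeviceRun:
    """Per-device solver state: local k-space, extended iterate, channels.

    The extended iterate ``x_ext`` holds the assigned cardiac phases plus the
    ghost phases; ghost columns of the local k-space are zero-masked so the
    fidelity term covers assigned frames only, while the temporal-TV term of
    the local objective covers every difference touching the device's frames.
    """

    def __init__(
        self, part: DevicePartition, y: KSpace5D, coils: CoilSet, config: ReconConfig
    ):
        self.part = part
        self.q = part.device_index
        self.coils = coils
        self.config = config
        gl, gr = int(part.ghost_left), int(part.ghost_right)
        self.e0 = part.start - gl
        e1 = part.stop + gr
        data = np.array(y.data[:, self.e0:e1])
        masks = np.array(y.masks[:, self.e0:e1])
        if gl:
            data[:, 0] = 0
            masks[:, 0] = 0
        if gr:
            data[:, -1] = 0
            masks[:, -1] = 0
        self.y_ext = KSpace5D._unchecked(data, masks)
        self.sl = slice(gl, gl + part.n_phases)
        self.x_ext = np.zeros_like(data[:, :, 0])  # (Nr, n_ext, X, Y, Z)
        self.in_channels: list[tuple[DependencyChannel, int]] = []
        self.out_channels: list[tuple[DependencyChannel, int]] = []
        self.state: SolverState | None = None
        self.stage_result: np.ndarray | None = None
        self.histories: list[ObjectiveHistory] = []
        self.last_gradient: np.ndarray | None = None
        self.finished = False

    # -- initialization ----------------------------------------------------

    def init_zero_filled(self) -> None:
        """Assigned frames of m0 = E^H y (ghost frames are filled by S.0 exchange)."""
        m0 = apply_encoding_adjoint(self.y_ext, self.coils)
        self.x_ext = m0.data.copy()
        self.stage_result = self.x_ext[:, self.sl].copy()

    def local_constants(self) -> tuple[float, float]:
        """(max |Phi m0| over local diffs, max |m0| over assigned frames)."""
        phi_max = ttv_forward(
            ImageSeries5D._unchecked(self.x_ext), self.config.ttv_weights
        ).max_abs()
        m0_max = float(np.abs(self.x_ext[:, self.sl]).max())
        return phi_max, m0_max

    # -- per-stage machinery -----------------------------------------------

    def begin_stage(self, stage: int, trace: TraceLog) -> None:
        self.state = SolverState(x=self.stage_result, stage_index=stage)
        self.x_ext[:, self.sl] = self.state.x
        self.finished = False
        trace.add(self.q, stage, -1, "stage_start")
        # channels are (re)initialized with the stage-initial boundary frames
        self.publish_dependencies(stage, -1, trace)

    def publish_dependencies(self, stage: int, iteration: int, trace: TraceLog) -> None:
        """S.2: push current boundary frames into every outgoing channel."""
        for ch, idx in self.out_channels:
            ch.publish(self.x_ext[:, idx], (stage, iteration))
            trace.add(self.q, stage, iteration, "publish", stamp=(stage, iteration), phase=ch.phase)

    def retrieve_dependencies(self, stage: int, iteration: int, trace: TraceLog) -> None:
        """S.3: refresh ghost frames from the latest channel payloads."""
        for ch, idx in self.in_channels:
            payload, stamp = ch.retrieve()
            self.x_ext[:, idx] = payload
            trace.add(self.q, stage, iteration, "retrieve", stamp=stamp, phase=ch.phase)

    def compute_step(
        self, params: HuberParams, lam: float, lipschitz: float, f_override: float | None
    ) -> None:
        """One local objective/gradient evaluation and NESTA update."""
        self.x_ext[:, self.sl] = self.state.x
        f, g = objective_and_gradient(
            ImageSeries5D._unchecked(self.x_ext),
            self.y_ext,
            self.coils,
            lam,
            params,
            self.config.ttv_weights,
        )
        g_local = g.data[:, self.sl]
        self.last_iterate = self.state.x  # the iterate this gradient was taken at
        self.last_gradient = g_local
        try:
            self.state.step(f if f_override is None else f_override, g_local, lipschitz)
        except ValueError as exc:
            raise DivergenceError(
                self.state.stage_index, self.state.k + 1, device=self.q + 1
            ) from exc

    def finish_stage(self, stage: int, iteration: int, trace: TraceLog) -> None:
        """S.4/S.5: final publish of the stage solution and notification."""
        self.stage_result = self.state.y_last.copy()
        self.x_ext[:, self.sl] = self.stage_result
        self.publish_dependencies(stage, iteration, trace)
        trace.add(self.q, stage, iteration, "converged")
        self.histories.append(self.state.history)
        self.finished = True


def _build_devices(
    plan: PartitionPlan, y: KSpace5D, coils: CoilSet, config: ReconConfig
) -> list[DeviceRun]:
    devices = [DeviceRun(p, y, coils, config) for p in plan.partitions]
    for producer, consumer, phase1 in dependency_pairs(plan):
        p, c, phase = producer - 1, consumer - 1, phase1 - 1
        ch = DependencyChannel(p, c, phase)
        devices[p].out_channels.append((ch, phase - devices[p].e0))
        devices[c].in_channels.append((ch, phase - devices[c].e0))
    return devices


def _assemble(devices: list[DeviceRun], current: bool = False) -> np.ndarray:
    """Concatenate assigned frames in ascending device order."""
    parts = [
        (dev.state.x if current else dev.stage_result) for dev in devices
    ]
    return np.concatenate(parts, axis=1)


def _stage_lockstep(
    devices: list[DeviceRun],
    stage: int,
    mu: float,
    lipschitz: float,
    lam: float,
    y: KSpace5D,
    coils: CoilSet,
    config: ReconConfig,
    trace: TraceLog,
    on_iteration: Callable | None,
) -> None:
    params = HuberParams(mu=mu)
    for dev in devices:
        dev.begin_stage(stage, trace)
    for dev in devices:
        dev.retrieve_dependencies(stage, -1, trace)
    active = list(devices)
    k = 0
    while active:
        for dev in active:
            dev.x_ext[:, dev.sl] = dev.state.x
            dev.publish_dependencies(stage, k, trace)
        for dev in active:
            dev.retrieve_dependencies(stage, k, trace)
        f_override = None
        if not config.local_stopping:
            full = ImageSeries5D._unchecked(_assemble(devices, current=True))
            f_override = objective(full, y, coils, lam, params, config.ttv_weights)
        for dev in active:
            dev.compute_step(params, lam, lipschitz, f_override)
        if on_iteration is not None:
            on_iteration(stage, k, devices)
        still_active = []
        for dev in active:
            if dev.state.should_stop(config.tau, config.tol) or k + 1 >= config.max_iter_per_stage:
                dev.finish_stage(stage, k, trace)
            else:
                still_active.append(dev)
        active = still_active
        k += 1
    for dev in devices:
        trace.add(dev.q, stage, -1, "barrier")


class _DynamicBarrier:
    """A cyclic barrier whose party count shrinks as devices finish a stage."""

    def __init__(self, parties: int, timeout: float):
        self._parties = parties
        self._count = 0
        self._generation = 0
        self._timeout = timeout
        self._cond = threading.Condition()
        self.broken = False

    def wait(self) -> None:
        with self._cond:
            if self.broken:
                raise RuntimeError("barrier broken by a failed device")
            gen = self._generation
            self._count += 1
            if self._count >= self._parties:
                self._release()
                return
            ok = self._cond.wait_for(
                lambda: self._generation != gen or self.broken, timeout=self._timeout
            )
            if self.broken:
                raise RuntimeError("barrier broken by a failed device")
            if not ok:
                raise TimeoutError("device synchronization timed out")

    def _release(self) -> None:
        self._count = 0
        self._generation += 1
        self._cond.notify_all()

    def deregister(self) -> None:
        with self._cond:
            self._parties -= 1
            if self._parties > 0 and self._count >= self._parties:
                self._release()

    def abort(self) -> None:
        with self._cond:
            self.broken = True
            self._cond.notify_all()


def _stage_concurrent(
    devices: list[DeviceRun],
    stage: int,
    mu: float,
    lipschitz: float,
    lam: float,
    y: KSpace5D,
    coils: CoilSet,
    config: ReconConfig,
    trace: TraceLog,
) -> None:
    params = HuberParams(mu=mu)
    d = len(devices)
    iter_barrier = _DynamicBarrier(d, config.barrier_timeout_s)
    stage_done: set[int] = set()
    done_lock = threading.Lock()
    errors: list[BaseException] = []
    full_buf = {"f": None}
    nc_total = sum(dev.part.n_phases for dev in devices)
    full_x = np.zeros(
        (devices[0].y_ext.nr, nc_total, *devices[0].y_ext.grid), dtype=np.complex128
    )

    def worker(dev: DeviceRun) -> None:
        try:
            dev.begin_stage(stage, trace)
            iter_barrier.wait()
            dev.retrieve_dependencies(stage, -1, trace)
            k = 0
            while True:
                dev.x_ext[:, dev.sl] = dev.state.x
                dev.publish_dependencies(stage, k, trace)
                iter_barrier.wait()  # all active devices published iteration k
                dev.retrieve_dependencies(stage, k, trace)
                iter_barrier.wait()  # nobody publishes k+1 until all retrieved k
                f_override = None
                if not config.local_stopping:
                    full_x[:, dev.part.start:dev.part.stop] = dev.state.x
                    iter_barrier.wait()
                    if dev.q == 0:
                        full_buf["f"] = objective(
                            ImageSeries5D._unchecked(full_x), y, coils, lam, params,
                            config.ttv_weights,
                        )
                    iter_barrier.wait()
                    f_override = full_buf["f"]
                dev.compute_step(params, lam, lipschitz, f_override)
                if (
                    dev.state.should_stop(config.tau, config.tol)
                    or k + 1 >= config.max_iter_per_stage
                ):
                    dev.finish_stage(stage, k, trace)
                    iter_barrier.deregister()
                    break
                k += 1
            with done_lock:
                stage_done.add(dev.q)
            trace.add(dev.q, stage, -1, "barrier")
        except BaseException as exc:  # noqa: BLE001 - propagated to the caller
            errors.append(exc)
            iter_barrier.abort()

    threads = [threading.Thread(target=worker, args=(dev,), daemon=True) for dev in devices]
    for t in threads:
        t.start()
    for t in threads:
        t.join(timeout=config.barrier_timeout_s + 5.0)
    if errors:
        raise errors[0]
    unfinished = [dev.q + 1 for dev in devices if dev.q not in stage_done]
    if unfinished:
        raise TimeoutError(
            f"stage {stage} barrier timed out; unfinished devices: {unfinished}"
        )


def run_partitioned(
    y: KSpace5D,
    coils: CoilSet,
    config: ReconConfig | None = None,
    on_iteration: Callable | None = None,
) -> tuple[ImageSeries5D, list[list[ObjectiveHistory]], TraceLog]:
    """Partitioned staged reconstruction over simulated devices.

    Returns the assembled 5D image, the per-device lists of per-stage
    objective histories, and the orchestration trace.  ``on_iteration``
    (lockstep only) is invoked as ``on_iteration(stage, k, devices)`` after
    every synchronized iteration, mainly for auditing gradients.
    """
    config = config or ReconConfig()
    if config.exec_mode == "single" and config.n_devices != 1:
        raise ValueError("exec_mode 'single' requires n_devices == 1")
    if config.n_devices > y.nc:
        raise ValueError(f"need n_devices <= Nc, got d={config.n_devices}, Nc={y.nc}")
    plan = partition_cardiac(
        y.nc,
        y.nr,
        capacities=config.device_capacities,
        n_devices=config.n_devices,
        split=config.manual_split,
    )
    trace = TraceLog()
    devices = _build_devices(plan, y, coils, config)

    # S.0 — zero-filled init, ghost exchange, and shared schedule constants
    for dev in devices:
        dev.init_zero_filled()
        dev.publish_dependencies(0, -1, trace)
    for dev in devices:
        dev.retrieve_dependencies(0, -1, trace)
    phi_maxima, m0_maxima = zip(*(dev.local_constants() for dev in devices))
    mu0 = 0.9 * share_constants(phi_maxima)
    if mu0 <= 0:
        mu0 = 1.0
    lam = (
        config.lambda_reg
        if config.lambda_reg is not None
        else 0.01 * share_constants(m0_maxima)
    )
    schedule = _schedule_from_constants(mu0, lam, config)

    for s, (mu, lips) in enumerate(schedule, start=1):
        if config.exec_mode == "concurrent":
            _stage_concurrent(devices, s, mu, lips, lam, y, coils, config, trace)
        else:
            _stage_lockstep(
                devices, s, mu, lips, lam, y, coils, config, trace, on_iteration
            )

    final = ImageSeries5D(data=_assemble(devices))
    histories = [dev.histories for dev in devices]
    return final, histories, trace
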