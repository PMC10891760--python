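"""Multi-device orchestration: channels, equivalence with the global solver."""

import numpy as np
import pytest

from cine5d.data_model import ImageSeries5D, ReconConfig
from cine5d.nesta import resolve_schedule, run_reconstruction, zero_filled
from cine5d.operators import HuberParams, gradient
from cine5d.orchestrator import (
    DependencyChannel,
    run_partitioned,
    share_constants,
)
from cine5d.synthetic import MaskSpec, PhantomSpec, generate_dataset


# ---------------------------------------------------------------------------
# S.0 constants and channels
# ---------------------------------------------------------------------------


def test_share_constants_identity_and_max():
    assert share_constants([0.7]) == 0.7
    assert share_constants([0.2, 0.9, 0.5]) == 0.9


def test_share_constants_rejects_non_finite():
    with pytest.raises(ValueError, match="device 2"):
        share_constants([0.1, float("nan")])


def test_shared_maximum_matches_unpartitioned(tiny_problem):
    from cine5d.operators import ttv_forward

    y, coils, _ = tiny_problem
    m0 = zero_filled(y, coils)
    global_max = ttv_forward(m0).max_abs()
    # emulate the per-device computation over extended (ghost-padded) ranges
    locals_ = []
    for lo, hi, e0, e1 in [(0, 3, 0, 4), (3, 6, 2, 6)]:
        ext = ImageSeries5D(data=m0.data[:, e0:e1])
        locals_.append(ttv_forward(ext).max_abs())
    assert share_constants(locals_) == global_max


def test_channel_round_trip_and_last_writer_wins(rng):
    ch = DependencyChannel(producer=0, consumer=1, phase=4)
    first = rng.standard_normal((2, 4, 4, 4)) + 1j * rng.standard_normal((2, 4, 4, 4))
    second = first + 1.0
    ch.publish(first, (1, 0))
    payload, stamp = ch.retrieve()
    assert stamp == (1, 0)
    np.testing.assert_array_equal(payload, first)
    ch.publish(second, (1, 1))
    payload, stamp = ch.retrieve()
    assert stamp == (1, 1)
    np.testing.assert_array_equal(payload, second)
    # retrieval without a new publish reuses the latest payload
    payload2, stamp2 = ch.retrieve()
    assert stamp2 == (1, 1)
    np.testing.assert_array_equal(payload2, second)


def test_channel_retrieve_before_publish_is_error():
    ch = DependencyChannel(0, 1, 0)
    with pytest.raises(RuntimeError, match="before any publish"):
        ch.retrieve()


# ---------------------------------------------------------------------------
# equivalence with the unpartitioned solver
# ---------------------------------------------------------------------------


def test_single_device_matches_global_bitwise(tiny_problem):
    y, coils, _ = tiny_problem
    config = ReconConfig(max_iter_per_stage=20)
    ref, ref_hists = run_reconstruction(y, coils, config)
    cfg = ReconConfig(max_iter_per_stage=20, n_devices=1, exec_mode="lockstep")
    img, hists, trace = run_partitioned(y, coils, cfg)
    assert img.data.tobytes() == ref.data.tobytes()
    assert [h.values for h in hists[0]] == [h.values for h in ref_hists]


def test_lockstep_global_stopping_matches_single_device(tiny_problem):
    y, coils, _ = tiny_problem
    ref, _ = run_reconstruction(y, coils, ReconConfig(max_iter_per_stage=20))
    cfg = ReconConfig(
        max_iter_per_stage=20, n_devices=2, exec_mode="lockstep", local_stopping=False
    )
    img, hists, _ = run_partitioned(y, coils, cfg)
    rel = np.abs(img.data - ref.data).max() / np.abs(ref.data).max()
    assert rel < 1e-9
    # disabled local stopping forces identical per-stage iteration counts
    counts = [[len(h) for h in hs] for hs in hists]
    assert counts[0] == counts[1]


@pytest.mark.parametrize("d", [2, 3])
def test_partitioned_gradients_equal_global_gradient(tiny_problem, d):
    y, coils, _ = tiny_problem
    config = ReconConfig(
        n_stages=1, tau=5, max_iter_per_stage=6, n_devices=d, exec_mode="lockstep",
        local_stopping=False,
    )
    m0 = zero_filled(y, coils)
    schedule, lam = resolve_schedule(m0, config)
    mu = schedule.mus[0]
    checked = []

    def audit(stage, k, devices):
        x_full = np.concatenate([dev.last_iterate for dev in devices], axis=1)
        g_ref = gradient(
            ImageSeries5D(data=x_full), y, coils, lam, HuberParams(mu=mu)
        ).data
        g_dev = np.concatenate([dev.last_gradient for dev in devices], axis=1)
        rel = np.abs(g_dev - g_ref).max() / np.abs(g_ref).max()
        checked.append(rel)

    run_partitioned(y, coils, config, on_iteration=audit)
    assert len(checked) >= 5
    assert max(checked) < 1e-10


def test_lockstep_is_deterministic(tiny_problem):
    y, coils, _ = tiny_problem
    cfg = ReconConfig(max_iter_per_stage=15, n_devices=3, exec_mode="lockstep")
    img1, _, tr1 = run_partitioned(y, coils, cfg)
    img2, _, tr2 = run_partitioned(y, coils, cfg)
    assert img1.data.tobytes() == img2.data.tobytes()
    assert tr1.to_jsonl() == tr2.to_jsonl()


def test_concurrent_matches_lockstep(tiny_problem):
    y, coils, _ = tiny_problem
    base = dict(max_iter_per_stage=25, n_devices=3, tol=1e-3)
    img_l, h_l, _ = run_partitioned(y, coils, ReconConfig(exec_mode="lockstep", **base))
    img_c, h_c, _ = run_partitioned(y, coils, ReconConfig(exec_mode="concurrent", **base))
    counts = lambda hs: [[len(h) for h in dev] for dev in hs]  # noqa: E731
    assert counts(h_l) == counts(h_c)
    np.testing.assert_array_equal(img_l.data, img_c.data)


def test_concurrent_equal_iteration_counts_without_local_stopping(tiny_problem):
    y, coils, _ = tiny_problem
    base = dict(max_iter_per_stage=12, n_devices=2, local_stopping=False)
    _, h_l, _ = run_partitioned(y, coils, ReconConfig(exec_mode="lockstep", **base))
    _, h_c, _ = run_partitioned(y, coils, ReconConfig(exec_mode="concurrent", **base))
    assert [[len(h) for h in dev] for dev in h_l] == [[len(h) for h in dev] for dev in h_c]


# ---------------------------------------------------------------------------
# trace audits of the synchronization protocol
# ---------------------------------------------------------------------------


def _uneven_run(tiny_problem):
    y, coils, _ = tiny_problem
    cfg = ReconConfig(n_devices=3, exec_mode="lockstep", tol=1e-3)
    return run_partitioned(y, coils, cfg)


def test_no_stage_mixing_in_consumed_payloads(tiny_problem):
    _, _, trace = _uneven_run(tiny_problem)
    retrieves = [e for e in trace.events if e["event"] == "retrieve"]
    assert retrieves
    for e in retrieves:
        assert e["stamp"][0] == e["stage"]


def test_stage_boundaries_are_barriers(tiny_problem):
    _, _, trace = _uneven_run(tiny_problem)
    last_barrier = {}
    first_start = {}
    for pos, e in enumerate(trace.events):
        if e["event"] == "barrier":
            last_barrier[e["stage"]] = pos
        if e["event"] == "stage_start" and e["stage"] not in first_start:
            first_start[e["stage"]] = pos
    for s in range(1, 4):
        assert last_barrier[s] < first_start[s + 1]


def test_lockstep_retrievals_are_current_iteration(tiny_problem):
    y, coils, _ = tiny_problem
    cfg = ReconConfig(
        n_devices=2, exec_mode="lockstep", local_stopping=False, max_iter_per_stage=10
    )
    _, _, trace = run_partitioned(y, coils, cfg)
    for e in trace.events:
        if e["event"] == "retrieve" and e["iteration"] >= 0:
            assert e["stamp"] == [e["stage"], e["iteration"]]


def test_finished_producer_payload_reused(tiny_problem):
    _, hists, trace = _uneven_run(tiny_problem)
    counts = [[len(h) for h in dev] for dev in hists]
    assert any(c1 != c2 for c1, c2 in zip(counts, counts[1:]))  # uneven stopping
    stale = [
        e
        for e in trace.events
        if e["event"] == "retrieve" and e["iteration"] >= 0
        and e["stamp"][1] < e["iteration"]
    ]
    # after a producer converges, consumers keep using its final payload
    assert stale


# ---------------------------------------------------------------------------
# configuration errors
# ---------------------------------------------------------------------------


def test_single_mode_rejects_multiple_devices(tiny_problem):
    y, coils, _ = tiny_problem
    with pytest.raises(ValueError, match="single"):
        run_partitioned(y, coils, ReconConfig(n_devices=2, exec_mode="single"))


def test_more_devices_than_cardiac_phases_rejected():
    spec = PhantomSpec(grid=(4, 4, 4), nc=2, nr=1, ncoils=1, seed=0)
    y, coils, _ = generate_dataset(spec, MaskSpec(af=1.0))
    with pytest.raises(ValueError, match="Nc"):
        run_partitioned(y, coils, ReconConfig(n_devices=3, exec_mode="lockstep"))
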