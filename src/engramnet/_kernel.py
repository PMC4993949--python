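"""Time-stepped LIF integration kernels.

Two interchangeable implementations of the same update rule: a vectorized
numpy loop (reference) and a numba-jitted scalar loop (fast path, used when
numba is importable).  Both consume pre-generated background-noise counts
and identical dense synapse-class matrices, and perform the floating-point
operations in the same order, so they produce identical rasters; a test
holds them to that.

Synapses are grouped into classes by (delay in steps, tau_syn); each class
keeps one exponentially decaying current state per neuron and one ring
buffer of pending deliveries.
"""

from __future__ import annotations

import numpy as np

try:  # optional fast path
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in dev environment
    _HAVE_NUMBA = False

STATUS_OK = 0
STATUS_SPIKE_OVERFLOW = 1
STATUS_NONFINITE = 2


def _simulate_numpy(
    n_steps,
    dt,
    tau_m,
    v_rest,
    v_thresh,
    v_reset,
    ref_steps,
    w,
    delays,
    decays,
    bg_counts,
    bg_weight,
    drive_traces,
    drive_lo,
    drive_hi,
    n_drives,
    record_voltages,
):
    n = len(tau_m)
    n_classes = len(delays)
    buf_len = int(delays.max()) + 1 if n_classes else 1
    s = np.zeros((n_classes, n), dtype=np.float64)
    inbuf = np.zeros((n_classes, buf_len, n), dtype=np.float64)
    v = v_rest.copy()
    ref = np.zeros(n, dtype=np.int64)
    volts = (
        np.zeros((n_steps, n), dtype=np.float64)
        if record_voltages
        else np.zeros((0, 0))
    )
    spk_steps: list[np.ndarray] = []
    spk_ids: list[np.ndarray] = []

    for t in range(n_steps):
        current = np.zeros(n, dtype=np.float64)
        for c in range(n_classes):
            slot = t % buf_len
            s[c] *= decays[c]
            s[c] += inbuf[c, slot]
            inbuf[c, slot] = 0.0
            current += s[c]
        for d in range(n_drives):
            current[drive_lo[d] : drive_hi[d]] += drive_traces[d, t]

        active = ref == 0
        v_new = v + dt * ((v_rest - v) / tau_m + current) + bg_counts[t] * bg_weight
        v = np.where(active, v_new, v_reset)
        ref = np.where(active, 0, ref - 1)
        if not np.all(np.isfinite(v)):
            return (
                np.concatenate(spk_steps) if spk_steps else np.empty(0, np.int64),
                np.concatenate(spk_ids) if spk_ids else np.empty(0, np.int64),
                volts,
                STATUS_NONFINITE,
            )
        spk = np.flatnonzero(active & (v >= v_thresh))
        if spk.size:
            v[spk] = v_reset[spk]
            ref[spk] = ref_steps[spk]
            for c in range(n_classes):
                col = w[c][:, spk]
                if col.any():
                    inbuf[c, (t + delays[c]) % buf_len] += col.sum(axis=1)
            spk_steps.append(np.full(spk.size, t, dtype=np.int64))
            spk_ids.append(spk.astype(np.int64))
        if record_voltages:
            volts[t] = v

    steps_out = np.concatenate(spk_steps) if spk_steps else np.empty(0, np.int64)
    ids_out = np.concatenate(spk_ids) if spk_ids else np.empty(0, np.int64)
    return steps_out, ids_out, volts, STATUS_OK


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _simulate_loop(
        n_steps,
        dt,
        tau_m,
        v_rest,
        v_thresh,
        v_reset,
        ref_steps,
        w,
        delays,
        decays,
        bg_counts,
        bg_weight,
        drive_traces,
        drive_lo,
        drive_hi,
        n_drives,
        spk_steps,
        spk_ids,
    ):  # pragma: no cover - exercised via equivalence test
        n = tau_m.shape[0]
        n_classes = delays.shape[0]
        buf_len = 1
        for c in range(n_classes):
            if delays[c] + 1 > buf_len:
                buf_len = delays[c] + 1
        s = np.zeros((n_classes, n))
        inbuf = np.zeros((n_classes, buf_len, n))
        v = v_rest.copy()
        ref = np.zeros(n, dtype=np.int64)
        has_out = np.zeros((n_classes, n), dtype=np.uint8)
        for c in range(n_classes):
            for j in range(n):
                for i in range(n):
                    if w[c, i, j] != 0.0:
                        has_out[c, j] = 1
                        break
        cap = spk_steps.shape[0]
        n_spk = 0
        current = np.zeros(n)

        for t in range(n_steps):
            slot = t % buf_len
            for i in range(n):
                acc = 0.0
                for c in range(n_classes):
                    sv = s[c, i] * decays[c] + inbuf[c, slot, i]
                    s[c, i] = sv
                    inbuf[c, slot, i] = 0.0
                    acc += sv
                current[i] = acc
            for d in range(n_drives):
                amp = drive_traces[d, t]
                if amp != 0.0:
                    for i in range(drive_lo[d], drive_hi[d]):
                        current[i] += amp

            spk_start = n_spk
            for i in range(n):
                if ref[i] > 0:
                    ref[i] -= 1
                    v[i] = v_reset[i]
                    continue
                vi = (
                    v[i]
                    + dt * ((v_rest[i] - v[i]) / tau_m[i] + current[i])
                    + bg_counts[t, i] * bg_weight[i]
                )
                if not np.isfinite(vi):
                    return n_spk, STATUS_NONFINITE
                if vi >= v_thresh[i]:
                    if n_spk >= cap:
                        return n_spk, STATUS_SPIKE_OVERFLOW
                    spk_steps[n_spk] = t
                    spk_ids[n_spk] = i
                    n_spk += 1
                    v[i] = v_reset[i]
                    ref[i] = ref_steps[i]
                else:
                    v[i] = vi
            for k in range(spk_start, n_spk):
                j = spk_ids[k]
                for c in range(n_classes):
                    if has_out[c, j]:
                        dslot = (t + delays[c]) % buf_len
                        for i in range(n):
                            inbuf[c, dslot, i] += w[c, i, j]
        return n_spk, STATUS_OK


def simulate(
    *,
    n_steps,
    dt,
    tau_m,
    v_rest,
    v_thresh,
    v_reset,
    ref_steps,
    w,
    delays,
    decays,
    bg_counts,
    bg_weight,
    drive_traces,
    drive_lo,
    drive_hi,
    n_drives,
    record_voltages=False,
    force_numpy=False,
):
    """Run the LIF loop; dispatches to numba when available.

    Returns ``(spike_steps, spike_neuron_ids, voltages, status)``; spikes in
    (step, neuron-index) order, which makes simultaneous spikes deterministic
    (population-concatenation index order).
    """
    use_numpy = force_numpy or record_voltages or not _HAVE_NUMBA
    if use_numpy:
        return _simulate_numpy(
            n_steps,
            dt,
            tau_m,
            v_rest,
            v_thresh,
            v_reset,
            ref_steps,
            w,
            delays,
            decays,
            bg_counts,
            bg_weight,
            drive_traces,
            drive_lo,
            drive_hi,
            n_drives,
            record_voltages,
        )
    # refractory periods bound the spike count per neuron
    cap = int(np.sum(n_steps // (ref_steps + 1) + 1))
    spk_steps = np.zeros(cap, dtype=np.int64)
    spk_ids = np.zeros(cap, dtype=np.int64)
    n_spk, status = _simulate_loop(
        n_steps,
        dt,
        tau_m,
        v_rest,
        v_thresh,
        v_reset,
        ref_steps.astype(np.int64),
        w,
        delays.astype(np.int64),
        decays,
        bg_counts,
        bg_weight,
        drive_traces,
        drive_lo.astype(np.int64),
        drive_hi.astype(np.int64),
        n_drives,
        spk_steps,
        spk_ids,
    )
    return spk_steps[:n_spk], spk_ids[:n_spk], np.zeros((0, 0)), status
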