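"""Deterministic synthetic traces with ground-truth manifests.

These generators produce the waveforms the analysis routines are specified
against — voltage traces with known DADs/triggered APs, per-disc flux
traces with injected spark pulses, and α-function Ca²⁺ transients — without
running the simulator.  Each generator returns ``(trace arrays, manifest)``
where the manifest lists the injected ground truth, so detector output can
be checked by round-trip.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "voltage_with_events",
    "flux_with_sparks",
    "alpha_transient",
    "generate_fixture",
]


def voltage_with_events(
    duration: float = 5000.0,
    dt: float = 0.1,
    baseline: float = -80.0,
    dad_times: tuple = (1000.0, 2500.0),
    dad_amplitude: float = 5.0,
    dad_width: float = 80.0,
    ap_times: tuple = (4000.0,),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Voltage trace with Gaussian DAD humps and stylized AP upstrokes.

    APs rise 120 mV in 1 ms (dV/dt ≈ 120 mV/ms), hold 10 ms and decay back
    over 50 ms — well above any upstroke-detection threshold.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    v = np.full_like(t, baseline)
    for t0 in dad_times:
        v += dad_amplitude * np.exp(-0.5 * ((t - t0) / (dad_width / 2.355)) ** 2)
    for t0 in ap_times:
        rise = (t >= t0) & (t < t0 + 1.0)
        v[rise] = baseline + 120.0 * (t[rise] - t0)
        hold = (t >= t0 + 1.0) & (t < t0 + 11.0)
        v[hold] = baseline + 120.0
        fall = (t >= t0 + 11.0) & (t < t0 + 61.0)
        v[fall] = baseline + 120.0 * (1.0 - (t[fall] - (t0 + 11.0)) / 50.0)
    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, size=v.shape)
    manifest = {
        "dads": [(float(x), float(dad_amplitude)) for x in dad_times],
        "triggered_aps": [float(x) for x in ap_times],
    }
    return t, v, manifest


def flux_with_sparks(
    duration: float = 2000.0,
    dt: float = 0.1,
    n_discs: int = 10,
    events: Optional[list] = None,
    amplitude: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-disc flux traces with injected rectangular spark pulses.

    ``events`` is a list of ``(disc, t_start, duration_ms)``; by default
    three 2-ms pulses on different discs.  Returns ``(t, flux, manifest)``
    with ``flux`` of shape (n_samples, n_discs).
    """
    rng = np.random.default_rng(seed)
    if events is None:
        events = [(0, 300.0, 2.0), (3, 800.0, 2.0), (7, 1500.0, 2.0)]
    t = np.arange(0.0, duration, dt)
    flux = np.zeros((len(t), n_discs))
    if noise_sd > 0:
        flux += rng.normal(0.0, noise_sd, size=flux.shape)
    for disc, t0, width in events:
        sel = (t >= t0) & (t < t0 + width)
        flux[sel, disc] += amplitude
    manifest = {"sparks": [(int(d), float(t0), float(w)) for d, t0, w in events]}
    return t, flux, manifest


def alpha_transient(
    duration: float = 1000.0,
    dt: float = 0.1,
    t0: float = 50.0,
    baseline: float = 0.1,
    amplitude: float = 1.0,
    tau: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """α-function Ca²⁺ transient ``A·(s/τ)·exp(1 − s/τ)`` with peak at ``t0 + τ``.

    The analytic peak amplitude is exactly ``A`` and the time to peak is
    exactly ``τ``, which makes the transient-metric recovery test closed-form.
    """
    t = np.arange(0.0, duration, dt)
    s = np.clip(t - t0, 0.0, None)
    ca = baseline + amplitude * (s / tau) * np.exp(1.0 - s / tau)
    manifest = {"peak_amplitude": amplitude, "time_to_peak": tau, "baseline": baseline}
    return t, ca, manifest


def generate_fixture(kind: str, spec: Optional[dict] = None, seed: int = 0):
    """Dispatch by fixture kind: ``voltage_dads``, ``flux_sparks`` or ``ca_transient``."""
    spec = dict(spec or {})
    if kind == "voltage_dads":
        return voltage_with_events(seed=seed, **spec)
    if kind == "flux_sparks":
        return flux_with_sparks(seed=seed, **spec)
    if kind == "ca_transient":
        return alpha_transient(**spec)
    raise ValueError(f"unknown fixture kind: {kind}")
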