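"""Fiber-photometry signal processing.

Implements the processing chain for dual-wavelength (470-nm functional /
405-nm isosbestic) recordings of a fluorescent dopamine sensor:

1. demultiplex the interleaved excitation phases and re-bin to the
   multiplexing cycle rate (100 Hz for 2-kHz recordings alternated at 100 Hz);
2. subtract non-sensor background as a fraction ``f`` of the sliding
   8th-percentile / 20-s baseline, per channel;
3. normalize by a freshly computed sliding baseline and convert to %dF/F
   against the whole-trace 8th percentile of the normalized trace;
4. extract stimulation-triggered segments and integrate the light-on window
   per stimulation ("evoked release integral"), with an optional affine
   normalization of the integrals to the display range [-0.25, 1].

The isosbestic channel is processed identically and reported as a movement
control; no regression-based motion correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from axsite.synthetic_data import PhotometryRecording

__all__ = [
    "DemuxedTrace",
    "TriggeredResponseSet",
    "demultiplex_and_rebin",
    "sliding_percentile_baseline",
    "estimate_background_fraction",
    "subtract_background",
    "compute_dff",
    "triggered_average",
    "evoked_integral_table",
    "normalized_integral_column",
    "process_session",
]

BASELINE_WINDOW_S = 20.0
BASELINE_PERCENTILE = 8.0
SETTLE_SAMPLES = 2
NORM_RANGE = (-0.25, 1.0)


@dataclass
class DemuxedTrace:
    """Single-wavelength fluorescence re-binned at the mux cycle rate."""

    channel: int  # 470 or 405
    rate_hz: float
    values: np.ndarray


@dataclass
class TriggeredResponseSet:
    """Per-stimulation segments aligned at light onset."""

    time_s: np.ndarray  # offsets relative to onset
    segments: np.ndarray  # (n_stim, n_time)
    mean: np.ndarray
    sem: np.ndarray
    onset_indices: np.ndarray
    rate_hz: float
    n_dropped: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.segments.shape[0]


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def demultiplex_and_rebin(
    rec: PhotometryRecording, settle_samples: int = SETTLE_SAMPLES
) -> tuple[DemuxedTrace, DemuxedTrace, np.ndarray]:
    """Split the interleaved 470/405 phases and average each phase per cycle.

    The mux signal must be a two-level alternation with constant phase length.
    The first ``settle_samples`` samples of every phase are discarded
    (LED/detector settling) and the remainder averaged into one bin per cycle;
    the output rate equals the mux cycle rate.  The trigger is down-sampled by
    an any-high rule within each cycle.  The higher mux level is taken as the
    470-nm phase.
    """
    mux = np.asarray(rec.mux)
    levels = np.unique(mux)
    if levels.size != 2:
        raise ValueError(
            f"mux signal must take exactly two levels, found {levels.size}: {levels[:5]}"
        )
    high = mux == levels[1]
    changes = np.flatnonzero(np.diff(high.astype(np.int8))) + 1
    if changes.size < 2:
        raise ValueError("mux signal contains fewer than one full alternation cycle")
    run_lengths = np.diff(changes)
    spp = int(run_lengths[0])
    # interior runs must all be complete phases; leading/trailing may be partial
    if np.any(run_lengths != spp) or changes[0] > spp:
        raise ValueError("mux signal is not a regular two-level alternation")
    if settle_samples >= spp:
        raise ValueError("settle_samples must be smaller than the phase length")

    cycle_len = 2 * spp
    # start at the first complete high (470) phase
    if high[0] and changes[0] == spp:
        start = 0
    else:
        high_starts = [int(c) for c in changes if high[c]]
        if not high_starts:
            raise ValueError("mux signal contains no complete 470 phase")
        start = high_starts[0]
    n_cycles = (len(mux) - start) // cycle_len
    if n_cycles < 1:
        raise ValueError("record shorter than one full mux cycle")
    sl = slice(start, start + n_cycles * cycle_len)
    fluor = np.asarray(rec.fluor)[sl].reshape(n_cycles, cycle_len)
    trig = np.asarray(rec.trig)[sl].reshape(n_cycles, cycle_len)

    v470 = fluor[:, settle_samples:spp].mean(axis=1)
    v405 = fluor[:, spp + settle_samples :].mean(axis=1)
    trig_binned = (trig > 0).any(axis=1).astype(float)

    rate = rec.sample_rate_hz / cycle_len
    return (
        DemuxedTrace(channel=470, rate_hz=rate, values=v470),
        DemuxedTrace(channel=405, rate_hz=rate, values=v405),
        trig_binned,
    )


# ---------------------------------------------------------------------------
# sliding-percentile baseline
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sliding_percentile_core(x: np.ndarray, half: int, q: float) -> np.ndarray:  # pragma: no cover
    n = x.shape[0]
    out = np.empty(n)
    cap = min(2 * half + 2, n + 1)
    buf = np.empty(cap)
    m = min(n, half + 1)
    buf[:m] = np.sort(x[:m])
    for t in range(n):
        if t > 0:
            j = t + half
            if j < n:
                v = x[j]
                lo, hi = 0, m
                while lo < hi:
                    mid = (lo + hi) // 2
                    if buf[mid] < v:
                        lo = mid + 1
                    else:
                        hi = mid
                for k in range(m, lo, -1):
                    buf[k] = buf[k - 1]
                buf[lo] = v
                m += 1
            i = t - half - 1
            if i >= 0:
                v = x[i]
                lo, hi = 0, m
                while lo < hi:
                    mid = (lo + hi) // 2
                    if buf[mid] < v:
                        lo = mid + 1
                    else:
                        hi = mid
                for k in range(lo, m - 1):
                    buf[k] = buf[k + 1]
                m -= 1
        pos = q / 100.0 * (m - 1)
        i0 = int(np.floor(pos))
        frac = pos - i0
        if i0 + 1 < m:
            out[t] = buf[i0] + frac * (buf[i0 + 1] - buf[i0])
        else:
            out[t] = buf[m - 1]
    return out


def sliding_percentile_baseline(
    values: np.ndarray,
    rate_hz: float,
    window_s: float = BASELINE_WINDOW_S,
    q: float = BASELINE_PERCENTILE,
) -> np.ndarray:
    """Sliding q-th percentile baseline B(t), centered windows truncated at edges.

    B(t) is the linearly interpolated q-th percentile of the samples in the
    window of ``window_s`` seconds centered at t; windows are truncated at the
    record edges rather than padded.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    if not 0 < q < 100:
        raise ValueError("percentile q must be in (0, 100)")
    if window_s < 2.0 / rate_hz:
        raise ValueError("window must span at least two samples")
    half = int(round(window_s * rate_hz / 2.0))
    return _sliding_percentile_core(x, half, float(q))


# ---------------------------------------------------------------------------
# background subtraction and dF/F
# ---------------------------------------------------------------------------


def estimate_background_fraction(
    control_values: np.ndarray,
    signal_values: np.ndarray,
    rate_hz: float,
    window_s: float = BASELINE_WINDOW_S,
    q: float = BASELINE_PERCENTILE,
) -> float:
    """Background fraction f from a no-sensor control recording.

    The control region carries only non-sensor fluorescence; f is its median
    expressed as a fraction of the median sliding baseline of the signal
    recording, clipped to [0, 1).
    """
    b = sliding_percentile_baseline(np.asarray(signal_values, float), rate_hz, window_s, q)
    f = float(np.median(control_values) / np.median(b))
    return min(max(f, 0.0), 1.0 - 1e-12)


def subtract_background(
    values: np.ndarray,
    rate_hz: float,
    f: float,
    window_s: float = BASELINE_WINDOW_S,
    q: float = BASELINE_PERCENTILE,
) -> np.ndarray:
    """Remove a fraction ``f`` of the sliding-percentile baseline: out = F - f*B."""
    if not 0 <= f < 1:
        raise ValueError("background fraction f must be in [0, 1)")
    if f == 0:
        return np.asarray(values, dtype=np.float64).copy()
    b = sliding_percentile_baseline(values, rate_hz, window_s, q)
    return np.asarray(values, dtype=np.float64) - f * b


def compute_dff(
    values: np.ndarray,
    rate_hz: float,
    window_s: float = BASELINE_WINDOW_S,
    q: float = BASELINE_PERCENTILE,
) -> np.ndarray:
    """%dF/F from a background-subtracted trace.

    Step 1 divides by the sliding-percentile baseline (drift removal);
    step 2 subtracts and divides by the whole-trace q-th percentile of the
    normalized trace and scales to percent.  The result is invariant to
    rescaling the raw fluorescence by any positive constant.
    """
    b = sliding_percentile_baseline(values, rate_hz, window_s, q)
    bad = np.flatnonzero(b <= 0)
    if bad.size:
        raise ValueError(f"nonpositive sliding baseline at sample {bad[0]}")
    n = np.asarray(values, dtype=np.float64) / b
    b0 = float(np.percentile(n, q))
    if b0 <= 0:
        raise ValueError("nonpositive whole-trace baseline")
    return 100.0 * (n - b0) / b0


# ---------------------------------------------------------------------------
# triggered responses and evoked integrals
# ---------------------------------------------------------------------------


def triggered_average(
    dff: np.ndarray,
    trig: np.ndarray,
    rate_hz: float,
    pre_s: float = 5.0,
    post_s: float = 10.0,
) -> TriggeredResponseSet:
    """Segments of ``dff`` aligned at trigger rising edges, with mean and SEM.

    Segments whose pre/post window would run past the record edges are
    dropped and counted in ``n_dropped``.
    """
    dff = np.asarray(dff, dtype=np.float64)
    trig = np.asarray(trig)
    high = trig > 0
    onsets = np.flatnonzero(high & ~np.concatenate([[False], high[:-1]]))
    npre = int(round(pre_s * rate_hz))
    npost = int(round(post_s * rate_hz))
    tvec = np.arange(-npre, npost + 1) / rate_hz

    segs = []
    kept = []
    dropped = 0
    for on in onsets:
        if on - npre < 0 or on + npost >= dff.size:
            dropped += 1
            continue
        segs.append(dff[on - npre : on + npost + 1])
        kept.append(on)
    if segs:
        m = np.vstack(segs)
        mean = m.mean(axis=0)
        sem = (
            m.std(axis=0, ddof=1) / np.sqrt(m.shape[0])
            if m.shape[0] > 1
            else np.zeros_like(mean)
        )
    else:
        m = np.zeros((0, tvec.size))
        mean = np.zeros(tvec.size)
        sem = np.zeros(tvec.size)
    return TriggeredResponseSet(
        time_s=tvec,
        segments=m,
        mean=mean,
        sem=sem,
        onset_indices=np.asarray(kept, dtype=int),
        rate_hz=rate_hz,
        n_dropped=dropped,
    )


def evoked_integral_table(
    resp: TriggeredResponseSet,
    stim_duration_s: float,
    subject: str = "",
    genotype: str = "",
    power_mw: float = float("nan"),
) -> pd.DataFrame:
    """Per-stimulation trapezoidal integral of dF/F over the light-on window (% * s)."""
    npre = int(round(-resp.time_s[0] * resp.rate_hz))
    nwin = int(round(stim_duration_s * resp.rate_hz))
    if npre + nwin >= resp.time_s.size:
        raise ValueError("stim_duration_s exceeds the post-onset window")
    t = resp.time_s[npre : npre + nwin + 1]
    rows = []
    for k in range(resp.n):
        seg = resp.segments[k, npre : npre + nwin + 1]
        rows.append(
            {
                "subject": subject,
                "genotype": genotype,
                "stim_index": k,
                "power_mw": power_mw,
                "integral": float(np.trapezoid(seg, t)),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "genotype", "stim_index", "power_mw", "integral"])


def normalized_integral_column(table: pd.DataFrame, column: str = "integral") -> pd.DataFrame:
    """Affine map of integrals across the whole comparison set: min -> -0.25, max -> 1.

    Display-only convention for plotting evoked-release responses from pooled
    groups on one axis; statistics always run on the raw integrals.  With
    fewer than two distinct values the normalized column is left as NaN.
    """
    out = table.copy()
    vals = out[column].to_numpy(dtype=float)
    lo_t, hi_t = NORM_RANGE
    if vals.size < 2 or np.ptp(vals) == 0:
        out[column + "_norm"] = np.nan
        return out
    out[column + "_norm"] = lo_t + (vals - vals.min()) / np.ptp(vals) * (hi_t - lo_t)
    return out


def process_session(
    rec: PhotometryRecording,
    background_fraction: float = 0.0,
    window_s: float = BASELINE_WINDOW_S,
    q: float = BASELINE_PERCENTILE,
    settle_samples: int = SETTLE_SAMPLES,
    process_isosbestic: bool = True,
) -> dict:
    """Full chain: demux -> background subtraction -> %dF/F for both channels.

    Returns a dict with keys ``rate_hz``, ``trig``, ``dff470`` and (optionally)
    ``dff405``.
    """
    tr470, tr405, trig = demultiplex_and_rebin(rec, settle_samples=settle_samples)
    rate = tr470.rate_hz
    out = {"rate_hz": rate, "trig": trig}
    sub = subtract_background(tr470.values, rate, background_fraction, window_s, q)
    out["dff470"] = compute_dff(sub, rate, window_s, q)
    if process_isosbestic:
        sub405 = subtract_background(tr405.values, rate, background_fraction, window_s, q)
        out["dff405"] = compute_dff(sub405, rate, window_s, q)
    return out
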