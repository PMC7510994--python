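"""Activity and oscillation metrics computed from spike rasters.

Five summary measures characterize a measurement window: population mean
firing rate, mean coefficient of variation of the inter-spike interval
(CoV ISI), oscillation frequency, oscillation peak magnitude, and oscillation
full width at half maximum (FWHM).  Oscillations are transient population
events detected as prominence-qualified peaks of a 10-ms sliding-window spike
count.  Also provided: within-oscillation phase occupancy (decile/quintile
firing likelihoods) and the structural neuron-connectivity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import MetricsConfig
from .dynamics import SpikeRaster
from .netgen import NetworkTopology


@dataclass(frozen=True)
class OscillationEvent:
    """One detected population oscillation."""

    t_peak_ms: float
    magnitude: float          # peak spike count in the sliding window
    magnitude_frac: float     # as a fraction of surviving network size
    fwhm_ms: float
    interval: tuple[float, float]  # t_peak +- 0.7 * fwhm


@dataclass(frozen=True)
class MetricsSummary:
    """The five activity metrics for one measurement window.

    Oscillation fields are NaN when no oscillation was detected in the window
    (recorded as missing, not as zero).
    """

    firing_rate_hz: float
    cov_isi: float
    osc_freq_hz: float
    osc_magnitude: float       # mean peak count
    osc_magnitude_frac: float  # mean peak fraction of network size
    osc_fwhm_ms: float
    window_ms: float
    n_neurons: int
    n_oscillations: int

    def to_dict(self) -> dict:
        return {
            "firing_rate_hz": self.firing_rate_hz,
            "cov_isi": self.cov_isi,
            "osc_freq_hz": self.osc_freq_hz,
            "osc_magnitude": self.osc_magnitude,
            "osc_magnitude_frac": self.osc_magnitude_frac,
            "osc_fwhm_ms": self.osc_fwhm_ms,
            "window_ms": self.window_ms,
            "n_neurons": self.n_neurons,
            "n_oscillations": self.n_oscillations,
        }


def _window(raster: SpikeRaster, window) -> tuple[float, float]:
    if window is None:
        return 0.0, raster.duration_ms
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty measurement window")
    return float(t0), float(t1)


def firing_rate(raster: SpikeRaster, window=None):
    """Per-neuron firing rate (Hz) over the window and the population mean.

    Silent neurons count as 0 Hz; the mean runs over all surviving neurons.
    Returns ``(rates, mean)`` where ``rates`` is indexed like
    ``raster.neuron_ids``.
    """
    t0, t1 = _window(raster, window)
    sel = (raster.times_ms >= t0) & (raster.times_ms < t1)
    ids = raster.ids[sel]
    # map original ids -> position among survivors
    order = np.argsort(raster.neuron_ids, kind="stable")
    pos = order[np.searchsorted(raster.neuron_ids[order], ids)]
    counts = np.bincount(pos, minlength=raster.n_neurons)
    rates = counts / ((t1 - t0) / 1000.0)
    return rates, float(rates.mean())


def cov_isi(raster: SpikeRaster, window=None):
    """Coefficient of variation of inter-spike intervals, per neuron and mean.

    Only neurons with at least two spikes in the window qualify; the
    population mean runs over qualifying neurons.  Returns ``(cov, mean)``
    with NaN for non-qualifying neurons.
    """
    t0, t1 = _window(raster, window)
    sel = (raster.times_ms >= t0) & (raster.times_ms < t1)
    times = raster.times_ms[sel]
    ids = raster.ids[sel]
    out = np.full(raster.n_neurons, np.nan)
    if len(times):
        order = np.lexsort((times, ids))
        ids_s, times_s = ids[order], times[order]
        starts = np.flatnonzero(np.concatenate([[True], ids_s[1:] != ids_s[:-1]]))
        bounds = np.concatenate([starts, [len(ids_s)]])
        norder = np.argsort(raster.neuron_ids, kind="stable")
        sorted_nids = raster.neuron_ids[norder]
        for g in range(len(starts)):
            lo, hi = bounds[g], bounds[g + 1]
            if hi - lo < 2:
                continue
            isi = np.diff(times_s[lo:hi])
            mu = isi.mean()
            if mu > 0:
                k = norder[np.searchsorted(sorted_nids, ids_s[lo])]
                out[k] = isi.std() / mu
    valid = ~np.isnan(out)
    mean = float(out[valid].mean()) if valid.any() else float("nan")
    return out, mean


def windowed_counts(raster: SpikeRaster, window_ms: float = 10.0, stride_ms: float = 0.2,
                    time_range=None):
    """Sliding-window population spike counts.

    ``trace[i]`` is the number of spikes in ``[t0 + i*stride, t0 + i*stride +
    window)``; the trace covers windows fully inside the range.  Returns
    ``(trace, t_centers_ms)``.
    """
    if window_ms < stride_ms:
        raise ValueError("window must be >= stride")
    t0, t1 = _window(raster, time_range)
    n_bins = int(round((t1 - t0) / stride_ms))
    w = int(round(window_ms / stride_ms))
    if n_bins < w:
        return np.zeros(0), np.zeros(0)
    sel = (raster.times_ms >= t0) & (raster.times_ms < t1)
    bins = ((raster.times_ms[sel] - t0) / stride_ms).astype(np.int64)
    bins = np.minimum(bins, n_bins - 1)
    hist = np.bincount(bins, minlength=n_bins)
    cs = np.concatenate([[0], np.cumsum(hist)])
    trace = (cs[w:] - cs[:-w]).astype(np.float64)
    centers = t0 + (np.arange(len(trace)) + w / 2.0) * stride_ms
    return trace, centers


def detect_oscillations(trace: np.ndarray, stride_ms: float = 0.2,
                        n_surviving: int = 1,
                        cfg: MetricsConfig = MetricsConfig(),
                        t_centers: np.ndarray | None = None):
    """Find population oscillations as prominent peaks of the count trace.

    Peaks need topographic prominence above the acceptance threshold (by
    default ``cfg.prominence_frac * n_surviving`` spikes, so the criterion
    tracks network size; set ``cfg.prominence_mode="spikes"`` for an absolute
    count) and >= ``cfg.min_separation_ms`` spacing.  FWHM is measured at half
    the prominence-referenced height via linear interpolation; the event
    interval spans ``cfg.interval_factor * fwhm`` centered on the peak.

    Returns ``(events, osc_freq_hz)``; a flat trace yields an empty list.
    """
    if len(trace) == 0:
        return [], float("nan")
    if cfg.prominence_mode == "fraction":
        prominence = max(cfg.prominence_frac * n_surviving, 1.0)
    else:
        prominence = cfg.prominence_min
    distance = max(int(round(cfg.min_separation_ms / stride_ms)), 1)
    peaks, props = signal.find_peaks(trace, prominence=prominence, distance=distance)
    duration_s = len(trace) * stride_ms / 1000.0
    if len(peaks) == 0:
        return [], 0.0 if duration_s > 0 else float("nan")
    widths, _, _, _ = signal.peak_widths(
        trace, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    events = []
    for p, w in zip(peaks, widths):
        t_peak = float(t_centers[p]) if t_centers is not None else p * stride_ms
        fwhm = float(w * stride_ms)
        if fwhm <= 0:
            continue
        half = cfg.interval_factor * fwhm / 2.0
        events.append(OscillationEvent(
            t_peak_ms=t_peak,
            magnitude=float(trace[p]),
            magnitude_frac=float(trace[p]) / n_surviving,
            fwhm_ms=fwhm,
            interval=(t_peak - half, t_peak + half),
        ))
    return events, len(events) / duration_s


def summarize(raster: SpikeRaster, window=None, cfg: MetricsConfig = MetricsConfig()) -> MetricsSummary:
    """Compute the five-metric summary of a measurement window."""
    t0, t1 = _window(raster, window)
    _, rate = firing_rate(raster, (t0, t1))
    _, cov = cov_isi(raster, (t0, t1))
    trace, centers = windowed_counts(raster, cfg.count_window_ms, cfg.stride_ms, (t0, t1))
    events, freq = detect_oscillations(trace, cfg.stride_ms, raster.n_neurons, cfg, centers)
    if events:
        mag = float(np.mean([e.magnitude for e in events]))
        mag_frac = float(np.mean([e.magnitude_frac for e in events]))
        fwhm = float(np.mean([e.fwhm_ms for e in events]))
    else:
        mag = mag_frac = fwhm = float("nan")
        freq = float("nan") if len(trace) == 0 else 0.0
    return MetricsSummary(
        firing_rate_hz=rate, cov_isi=cov,
        osc_freq_hz=freq, osc_magnitude=mag, osc_magnitude_frac=mag_frac,
        osc_fwhm_ms=fwhm, window_ms=t1 - t0, n_neurons=raster.n_neurons,
        n_oscillations=len(events),
    )


def phase_occupancy(raster: SpikeRaster, events, n_bins: int = 10,
                    groups: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """Firing likelihood per phase bin inside detected oscillations.

    Each event's interval (1.4 x FWHM around the peak) is split into
    ``n_bins`` equal sub-intervals; spikes are aggregated per neuron group and
    normalized to the group's in-interval total.  ``groups`` maps a label to
    an array of original neuron ids (default: one group with every neuron).
    Zero-width events are skipped.
    """
    if not events:
        raise ValueError("phase occupancy requires at least one oscillation event")
    if n_bins not in (5, 10):
        raise ValueError("n_bins must be 5 (quintiles) or 10 (deciles)")
    if groups is None:
        groups = {"all": raster.neuron_ids}
    counts = {name: np.zeros(n_bins) for name in groups}
    member = {name: np.isin(raster.ids, ids) for name, ids in groups.items()}
    for ev in events:
        lo, hi = ev.interval
        if hi <= lo:
            continue
        inside = (raster.times_ms >= lo) & (raster.times_ms < hi)
        if not inside.any():
            continue
        b = ((raster.times_ms[inside] - lo) / (hi - lo) * n_bins).astype(np.int64)
        b = np.minimum(b, n_bins - 1)
        for name in groups:
            sel = member[name][inside]
            if sel.any():
                counts[name] += np.bincount(b[sel], minlength=n_bins)
    out = {}
    for name, cnt in counts.items():
        total = cnt.sum()
        out[name] = cnt / total if total > 0 else cnt
    return out


def connectivity_index(topology: NetworkTopology) -> np.ndarray:
    """Structural input/output balance per neuron, in [-1, 1].

    ``(sum |w_in| - sum |w_out|) / (sum |w_in| + sum |w_out|)`` using absolute
    synaptic strengths; +1 means pure receiver, -1 pure sender.  Isolated
    neurons get NaN (undefined).
    """
    n = topology.n_neurons
    w = np.abs(topology.weight)
    w_in = np.zeros(n)
    w_out = np.zeros(n)
    np.add.at(w_in, topology.post, w)
    np.add.at(w_out, topology.pre, w)
    total = w_in + w_out
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = (w_in - w_out) / total
    idx[total == 0] = np.nan
    return idx
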