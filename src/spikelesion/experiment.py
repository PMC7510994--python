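"""Protocol orchestration: settle -> measure -> injure -> measure -> recover,
across injury modes/levels, E/I compositions and replicates, with the
associated statistical comparisons (one-way ANOVA + Tukey-Kramer; Welch
t-tests with Bonferroni correction).

Seeding: one master seed spawns independent child streams per replicate and
per stage (build, settling drive, injury choice, ...), so every condition
within a replicate starts from the same settled network and the whole
protocol is bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ProtocolConfig
from .dynamics import SimState, SpikeRaster, init_state, run_simulation
from .injury import injure_by_rate, injure_focal, injure_random, subset_state
from .metrics import MetricsSummary, connectivity_index, firing_rate, summarize
from .netgen import NetworkTopology, build_network

log = logging.getLogger("spikelesion")

METRIC_COLS = ["firing_rate_hz", "cov_isi", "osc_freq_hz",
               "osc_magnitude", "osc_magnitude_frac", "osc_fwhm_ms"]


@dataclass
class SettleResult:
    raster: SpikeRaster          # final settle window
    elapsed_min: float
    converged: bool
    history: list[MetricsSummary] = field(default_factory=list)


def _rel_change(new: float, old: float) -> float:
    if np.isnan(new) and np.isnan(old):
        return 0.0  # metric missing in both blocks (e.g. no oscillations)
    if np.isnan(new) or np.isnan(old):
        return float("inf")
    if old == 0:
        return 0.0 if new == 0 else float("inf")
    return abs(new - old) / abs(old)


def pinned_metrics(cfg: ProtocolConfig, n_original: int):
    """Detection config with the peak-prominence threshold fixed in absolute
    spikes at ``prominence_frac * n_original``.

    Injured conditions are then measured with the *same* detector as their
    intact baseline, so oscillation frequency compares like with like instead
    of tracking the shrinking network into the Poisson noise floor.
    """
    from dataclasses import replace
    m = cfg.metrics
    if m.prominence_mode != "fraction":
        return m
    return replace(m, prominence_mode="spikes",
                   prominence_min=max(m.prominence_frac * n_original, 1.0))


def settle(topology: NetworkTopology, state: SimState, cfg: ProtocolConfig,
           rng, plasticity_on: bool = True, metrics_cfg=None) -> SettleResult:
    """Simulate in settle-window blocks until activity stabilizes.

    Stops when both the mean firing rate and the oscillation frequency change
    by less than ``cfg.settle_tol`` (relative) between consecutive blocks, or
    at the ``cfg.settle_max_min`` cap (a warning is recorded and the run
    proceeds).  STDP is active unless ``plasticity_on`` is False.
    """
    if metrics_cfg is None:
        metrics_cfg = cfg.metrics
    block_ms = cfg.settle_window_min * 60_000.0
    max_blocks = max(int(round(cfg.settle_max_min / cfg.settle_window_min)), 1)
    prev: MetricsSummary | None = None
    history: list[MetricsSummary] = []
    raster = None
    for blk in range(max_blocks):
        raster, state = run_simulation(
            topology, state, block_ms, cfg.stimulus, cfg.sim, cfg.stdp,
            plasticity_on=plasticity_on, record=True, seed=rng,
        )
        summ = summarize(raster, cfg=metrics_cfg)
        history.append(summ)
        log.info("settle block %d: rate=%.2f Hz, osc=%.2f /s",
                 blk + 1, summ.firing_rate_hz, summ.osc_freq_hz)
        if prev is not None:
            dr = _rel_change(summ.firing_rate_hz, prev.firing_rate_hz)
            do = _rel_change(summ.osc_freq_hz, prev.osc_freq_hz)
            if dr < cfg.settle_tol and do < cfg.settle_tol:
                return SettleResult(raster, (blk + 1) * cfg.settle_window_min, True, history)
        prev = summ
    warnings.warn("settling did not converge within the simulated-time cap; proceeding",
                  RuntimeWarning, stacklevel=2)
    return SettleResult(raster, max_blocks * cfg.settle_window_min, False, history)


def _injure(topology, mode, fraction, rate_by_id, rng):
    if mode == "random":
        return injure_random(topology, fraction, rng)
    if mode == "focal":
        return injure_focal(topology, fraction, rng)
    if mode in ("lfr", "hfr"):
        return injure_by_rate(topology, fraction, mode, rate_by_id, rng)
    raise ValueError(f"unknown injury mode {mode!r}")


def _row(replicate, mode, fraction, phase, summ: MetricsSummary) -> dict:
    row = {"replicate": replicate, "mode": mode, "fraction": fraction, "phase": phase}
    row.update({k: v for k, v in summ.to_dict().items() if k in METRIC_COLS})
    return row


def run_replicate(cfg: ProtocolConfig, seed_seq: np.random.SeedSequence,
                  replicate: int = 0) -> list[dict]:
    """Full protocol for one replicate; returns result-table rows."""
    s_build, s_settle, s_injury, s_measure, s_recover = (
        np.random.default_rng(c) for c in seed_seq.spawn(5))
    topo = build_network(cfg.network, s_build)
    state = init_state(topo, cfg.sim)
    mc = pinned_metrics(cfg, topo.n_neurons)
    settled = settle(topo, state, cfg, s_settle, metrics_cfg=mc)
    rows = [_row(replicate, "none", 0.0, "baseline", summarize(settled.raster, cfg=mc))]

    # per-neuron rates over the final pre-injury window, keyed by original id
    rates, _ = firing_rate(settled.raster)
    rate_by_id = np.zeros(int(topo.ids.max()) + 1)
    rate_by_id[settled.raster.neuron_ids] = rates

    measure_ms = cfg.measure_window_min * 60_000.0
    for mode in cfg.injury_modes:
        for frac in cfg.injury_fractions:
            inj_topo, deleted = _injure(topo, mode, frac, rate_by_id, s_injury)
            inj_state = subset_state(state, inj_topo.ids, topo.ids, inj_topo, cfg.sim)
            # immediate post-injury window with frozen weights
            raster, inj_state = run_simulation(
                inj_topo, inj_state, measure_ms, cfg.stimulus, cfg.sim,
                plasticity_on=False, record=True, seed=s_measure)
            rows.append(_row(replicate, mode, frac, "post-injury",
                             summarize(raster, cfg=mc)))
            # recovery with STDP, then a final measurement window
            rec_cfg = _recovery_cfg(cfg)
            rec = settle(inj_topo, inj_state, rec_cfg, s_recover, metrics_cfg=mc)
            rows.append(_row(replicate, mode, frac, "post-plasticity",
                             summarize(rec.raster, cfg=mc)))
            log.info("replicate %d %s@%.2f done (deleted %d)",
                     replicate, mode, frac, len(deleted))
    return rows


def _recovery_cfg(cfg: ProtocolConfig) -> ProtocolConfig:
    from dataclasses import replace
    return replace(cfg, settle_max_min=cfg.recovery_max_min)


def run_protocol(cfg: ProtocolConfig = ProtocolConfig(), seed=0) -> pd.DataFrame:
    """Run the full multi-replicate protocol; returns the tidy result table.

    One row per (replicate, condition, phase) holding the five metrics.
    """
    root = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for rep, child in enumerate(root.spawn(cfg.n_replicates)):
        rows.extend(run_replicate(cfg, child, rep))
    return pd.DataFrame(rows)


def group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- standard error of each metric per (mode, fraction, phase)."""
    g = table.groupby(["mode", "fraction", "phase"])[METRIC_COLS]
    mean = g.mean()
    se = g.sem()
    se.columns = [c + "_se" for c in se.columns]
    return pd.concat([mean, se], axis=1).reset_index()


# ---------------------------------------------------------------------------
# statistics


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA with Tukey-Kramer post-hoc pairwise comparisons.

    ``groups`` maps condition label to a 1-D sample array (unequal sizes
    allowed).  Returns ``(F, p, pairs)`` where ``pairs`` is a DataFrame with
    one row per unordered pair: adjusted p-value (studentized-range
    distribution) and the significance decision at ``alpha``.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    F, p = sps.f_oneway(*samples)
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p_adj": float(res.pvalue[i, j]),
                "significant": bool(res.pvalue[i, j] < alpha),
            })
    return float(F), float(p), pd.DataFrame(rows)


def ttest_bonferroni(pairs: list[tuple[np.ndarray, np.ndarray]], alpha: float = 0.05,
                     labels: list[str] | None = None) -> pd.DataFrame:
    """Welch two-sample t-tests with Bonferroni correction over ``pairs``.

    Each pair is tested at the corrected level ``alpha / len(pairs)``; the
    returned table reports raw and Bonferroni-adjusted p-values.
    """
    m = len(pairs)
    if m == 0:
        raise ValueError("no pairs to test")
    rows = []
    for k, (xa, xb) in enumerate(pairs):
        xa = np.asarray(xa, dtype=float)
        xb = np.asarray(xb, dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("each sample needs >= 2 observations")
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({
            "pair": labels[k] if labels else str(k),
            "t": float(t), "p": float(p),
            "p_adj": float(min(p * m, 1.0)),
            "significant": bool(p < alpha / m),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# E/I composition sweep


def ei_sweep(cfg: ProtocolConfig = ProtocolConfig(), seed=0,
             frac_exc_grid=None) -> pd.DataFrame:
    """Baseline-only protocol across excitatory fractions, normalized to 80 %.

    For each composition and replicate: build, settle with STDP, and measure
    the five metrics plus the index-rate correlation over the final window.
    Metric columns suffixed ``_norm`` are scaled by the 0.80-composition group
    mean.
    """
    from dataclasses import replace

    grid = tuple(frac_exc_grid) if frac_exc_grid is not None else cfg.frac_exc_grid
    root = np.random.SeedSequence(seed)
    rows = []
    for fe in grid:
        net_cfg = replace(cfg.network, frac_exc=fe)
        sub = replace(cfg, network=net_cfg)
        for rep, child in enumerate(root.spawn(cfg.n_replicates)):
            s_build, s_settle = (np.random.default_rng(c) for c in child.spawn(2))
            topo = build_network(net_cfg, s_build)
            state = init_state(topo, cfg.sim)
            res = settle(topo, state, sub, s_settle)
            summ = summarize(res.raster, cfg=cfg.metrics)
            rates, _ = firing_rate(res.raster)
            idx = connectivity_index(topo)
            ok = ~np.isnan(idx)
            r = float(np.corrcoef(idx[ok], rates[ok])[0, 1]) if ok.sum() > 2 else float("nan")
            row = {"frac_exc": fe, "replicate": rep, "index_rate_r": r}
            row.update({k: v for k, v in summ.to_dict().items() if k in METRIC_COLS})
            rows.append(row)
    table = pd.DataFrame(rows)
    base = table[table["frac_exc"] == 0.80][METRIC_COLS].mean()
    for col in METRIC_COLS:
        denom = base[col]
        table[col + "_norm"] = table[col] / denom if denom and np.isfinite(denom) else np.nan
    return table
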