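"""End-to-end seeded pipeline: simulate -> render -> analyze -> report.

One global seed is expanded into deterministic per-stage substreams, so a
run is fully reproducible from its emitted config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .geometry import make_hex_layout
from .kmc import arc_length_distribution, initiation_survival, simulate_ring
from .kymo import pre_pore_II_lifetimes, segment_trace, step_statistics, extract_trace
from .movie import (
    assign_states,
    estimate_propagation_rates,
    opening_rate,
    propagation_direction,
    transition_time,
    unbend_layout,
)
from .runlength import fit_run_lengths, pmf_mode
from .synthetic import render_movie, sample_kymo_ensemble


def _stage_rngs(seed: int, n_rings: int):
    ss = np.random.SeedSequence(seed)
    sim_ss, render_ss, kymo_ss = ss.spawn(3)
    return sim_ss.spawn(n_rings), render_ss, kymo_ss


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the full synthetic study and return the JSON-able report.

    Stages: ring KMC ensemble; batched movie rendering + unbending + state
    assignment; opening/initiation/propagation/direction/arc estimates;
    kymograph ensemble segmentation (step heights, speeds, pre-pore-II
    lifetime); run-length model fit of the simulated arc distribution.
    Any stage failure aborts with a stage-tagged error.
    """
    report: dict = {
        "porewave_version": __version__,
        "config": config.to_dict(),
    }
    sim_children, render_ss, kymo_ss = _stage_rngs(config.seed, config.n_rings)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    # --- simulate
    trajs = stage("simulate")(
        lambda: [
            simulate_ring(
                config.rates, config.duration_s,
                seed=np.random.default_rng(child), ring_id=i,
            )
            for i, child in enumerate(sim_children)
        ]
    )

    # --- render + analyze movies in batches
    def render_and_assign():
        render_children = render_ss.spawn(
            (len(trajs) + config.render_batch - 1) // config.render_batch
        )
        states = []
        direction_scores = []
        for b, child in enumerate(render_children):
            batch = trajs[b * config.render_batch : (b + 1) * config.render_batch]
            layout = make_hex_layout(
                len(batch), pixel_size=config.pixel_size_nm,
                ring_radius=config.ring_radius_nm,
            )
            movie, _truth = render_movie(
                layout, batch, config.conventions,
                frame_interval=config.frame_interval_s,
                seed=np.random.default_rng(child),
            )
            for tm in unbend_layout(movie, layout):
                sm = assign_states(tm)
                states.append(sm)
                try:
                    direction_scores.append(propagation_direction(sm))
                except ValueError:
                    pass
        return states, direction_scores

    states, direction_scores = stage("render+assign")(render_and_assign)

    def analyze():
        opening = opening_rate(states)
        surv = initiation_survival(trajs)
        k12, k23 = estimate_propagation_rates(states)
        arcs = arc_length_distribution(trajs)
        fit = fit_run_lengths(arcs)
        ttimes = [transition_time(sm) for sm in states]
        ttimes = [t for t in ttimes if t is not None]
        return {
            "opening_rate_per_s": {
                "value": opening.rate, "ci95": opening.ci95, "n_events": opening.n_events,
                "truth": config.rates.k_open,
            },
            "initiation_tau_s": {
                "value": surv.tau, "ci95": surv.ci95, "n_events": surv.n_events,
                "truth": 1.0 / (config.rates.k_open * config.rates.q_nucleate)
                if config.rates.q_nucleate > 0 else None,
            },
            "k12_per_s": {"value": k12.rate, "ci95": k12.ci95, "n_events": k12.n_events,
                          "truth": config.rates.k12},
            "k23_per_s": {"value": k23.rate, "ci95": k23.ci95, "n_events": k23.n_events,
                          "truth": config.rates.k23},
            "direction_score": {
                "value": float(np.mean(direction_scores)) if direction_scores else None,
                "n": len(direction_scores), "truth": 1.0,
            },
            "mean_transition_time_s": {
                "value": float(np.mean(ttimes)) if ttimes else None, "n": len(ttimes),
            },
            "arc_length_mode": {
                "value": int(np.argmax(arcs.counts)) + 1 if arcs.n_arcs else None,
                "fitted_s": fit.params.s, "fitted_n0": fit.params.n0,
                "fitted_mode": pmf_mode(fit.params), "n_arcs": arcs.n_arcs,
            },
        }

    report["movie"] = stage("movie-analysis")(analyze)

    def kymo_part():
        ens = sample_kymo_ensemble(
            config.kymo.n_traces, seed=kymo_ss,
            conv=config.conventions, tau_II=config.kymo.tau_II_ms / 1e3,
            line_interval=config.kymo.line_interval_s, jitter=config.kymo.jitter,
        )
        segs = [
            segment_trace(extract_trace(k, width=3), k.line_interval, trace_id=i)
            for i, (k, _t) in enumerate(ens)
        ]
        stats = step_statistics(segs)
        _dwells, fit = pre_pore_II_lifetimes(segs)
        out = stats.summary()
        out["tau_II_ms"] = {
            "value": fit.tau * 1e3, "ci95": [c * 1e3 for c in fit.ci95],
            "n_dwells": fit.n_events, "truth": config.kymo.tau_II_ms,
        }
        return out

    report["kymograph"] = stage("kymograph-analysis")(kymo_part)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
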