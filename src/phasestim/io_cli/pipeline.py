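"""Orchestration of the closed-loop simulation and offline analysis stack.

simulate -> track -> schedule -> evaluate -> ERSP -> classify, with every
report written to the output directory carrying the config hash and seed.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .. import classify as _classify
from .. import evaluate as _eval
from .. import scheduler as _sched
from .. import spectral as _spec
from .. import synth as _synth
from .. import tracker as _track
from .config import RunConfig, config_hash
from .container import (
    save_recording,
    write_ersp,
    write_estimates,
    write_events,
    write_json,
    write_stim_events,
)

__all__ = ["run_pipeline", "interval_for_condition"]

log = logging.getLogger("phasestim.pipeline")


def interval_for_condition(condition: str) -> _sched.PhaseInterval | None:
    """Gating interval for a condition; None for ungated conditions."""
    return {"RPS": _sched.RISING, "FPS": _sched.FALLING}.get(condition)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run the full synthetic pipeline; returns the in-memory report bundle.

    Writes: recording container + trial event table, phase-estimate table,
    stimulus event table, PLV / rose-histogram / trial-flag reports, per-
    channel ERSP matrices and band-ERD summary, band-energy curves, and the
    cross-validation report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    log.info("run config hash %s (seed %d, condition %s)", meta["config_hash"],
             cfg.seed, cfg.condition)

    # -- simulate -------------------------------------------------------------
    rec = _stage("simulate", _synth.generate_session, cfg.synth)
    save_recording(outdir / "recording.npz", rec, meta=meta)
    ev_meta = dict(meta, fs=rec.fs)
    write_events(outdir / "events.tsv", rec.events, meta=ev_meta)
    log.info("simulated %d trials, %.0f s, %d channels", len(rec.events),
             rec.duration, rec.n_channels)

    # -- track ----------------------------------------------------------------
    estimates = _stage("track", _track.track_stream, rec, cfg.channel, cfg.tracker)
    write_estimates(outdir / "estimates.tsv", estimates, meta=meta)
    log.info("tracker emitted %d estimates", len(estimates))

    # -- schedule -------------------------------------------------------------
    iv = interval_for_condition(cfg.condition)
    stim_events: list[_sched.StimulusEvent] = []
    if iv is not None:
        windows = _synth.task_windows(rec, cfg.synth.task_window)
        for win in windows:
            stim_events.extend(
                _stage("schedule", _sched.schedule, estimates, iv,
                       refractory_ms=cfg.refractory_ms, mode=cfg.condition,
                       window=win)
            )
    log.info("scheduled %d stimulus events", len(stim_events))

    # -- evaluate -------------------------------------------------------------
    phase_truth = _stage(
        "evaluate", _eval.hilbert_phase, rec.channel(cfg.channel), rec.fs,
        cfg.tracker.band,
    )
    idx = np.array([int(round(e.t * rec.fs)) for e in estimates])
    valid = idx < rec.n_samples
    report = _eval.plv(np.array([e.phi for e in estimates])[valid],
                       phase_truth[idx[valid]])
    plv_doc = {
        "pooled": {"plv": report.plv, "circ_mean_error": report.circ_mean_error,
                   "n": report.n},
        "per_trial": [],
    }
    trial_spans = _synth.task_windows(rec, cfg.synth.task_window)
    est_t = np.array([e.t for e in estimates])
    est_phi = np.array([e.phi for e in estimates])
    for trial_id, (t0, t1) in enumerate(trial_spans):
        sel = (est_t >= t0) & (est_t < t1) & (idx < rec.n_samples)
        if sel.sum() >= 1:
            r = _eval.plv(est_phi[sel], phase_truth[idx[sel]])
            plv_doc["per_trial"].append(
                {"trial": trial_id, "plv": r.plv, "n": r.n}
            )
    write_json(outdir / "plv.json", plv_doc, meta=meta)

    flags_doc = {"kept": [], "removed": []}
    rose_doc = {"counts": [], "bin_edges": []}
    if stim_events:
        stim_events, counts, edges = _eval.realized_stimulus_phases(
            stim_events, rec, cfg.channel, band=cfg.tracker.band,
            n_bins=cfg.rose_bins,
        )
        rose_doc = {"counts": counts, "bin_edges": edges}
        by_trial = {
            i: [ev for ev in stim_events if t0 <= ev.onset < t1]
            for i, (t0, t1) in enumerate(trial_spans)
        }
        kept, removed = _eval.flag_bad_trials(by_trial, iv, cfg.max_out_fraction)
        flags_doc = {"kept": kept, "removed": removed}
    write_stim_events(outdir / "stim_events.tsv", stim_events, meta=meta)
    write_json(outdir / "rose.json", rose_doc, meta=meta)
    write_json(outdir / "trial_flags.json", flags_doc, meta=meta)

    # -- spectral -------------------------------------------------------------
    car = _stage("car", _spec.car_reference, rec)
    trial_n = int(round(cfg.synth.trial_len * rec.fs))
    labels = np.array([ev.label for ev in rec.events])
    ersp_maps = {}
    erd_doc = {}
    task_win = cfg.synth.task_window
    for ch in ("C3", "C4"):
        sig = car.channel(ch)
        trials = np.stack(
            [sig[ev.onset_sample : ev.onset_sample + trial_n] for ev in rec.events]
        )
        per_class = {}
        for cls in ("MI", "rest"):
            emap = _stage("ersp", _spec.ersp, trials[labels == cls], rec.fs,
                          channel=ch)
            per_class[cls] = emap
            write_ersp(outdir / f"ersp_{ch}_{cls}.tsv", emap, meta=meta)
            erd_doc[f"{ch}_{cls}"] = {
                "alpha_db": _spec.band_erd(emap, _spec.ALPHA_BAND, task_win),
                "beta_db": _spec.band_erd(emap, _spec.BETA_BAND, task_win),
            }
        ersp_maps[ch] = per_class
    write_json(outdir / "band_erd.json", erd_doc, meta=meta)

    curves = {}
    sig = car.channel(cfg.channel)
    trials = np.stack(
        [sig[ev.onset_sample : ev.onset_sample + trial_n] for ev in rec.events]
    )
    with open(outdir / "band_energy.tsv", "w") as fh:
        fh.write("".join(f"# {k}={v}\n" for k, v in meta.items()))
        fh.write("class\ttime_s\tband_power\n")
        for cls in ("MI", "rest"):
            curve = _stage("band_energy", _spec.band_energy_curve,
                           trials[labels == cls], rec.fs, label=cls,
                           condition=cfg.condition)
            curves[cls] = curve
            for t, v in zip(curve.times, curve.values):
                fh.write(f"{cls}\t{t:.3f}\t{v:.8g}\n")

    # -- classify -------------------------------------------------------------
    epochs, ep_labels = _stage("epoch", _classify.epoch_for_classification, car,
                               task_onset=task_win[0])
    cv = _stage("classify", _classify.crossvalidate, epochs, ep_labels, rec.fs,
                m_pairs=cfg.m_pairs, n_repeats=cfg.cv_repeats,
                n_folds=cfg.cv_folds, seed=cfg.seed)
    write_json(
        outdir / "cv_report.json",
        {
            "mean_accuracy": cv.mean_accuracy,
            "per_repeat_means": cv.per_repeat_means,
            "fold_accuracies": cv.fold_accuracies,
        },
        meta=meta,
    )
    log.info("CV mean accuracy %.3f", cv.mean_accuracy)

    return {
        "recording": rec,
        "estimates": estimates,
        "stim_events": stim_events,
        "plv": plv_doc,
        "rose": rose_doc,
        "trial_flags": flags_doc,
        "ersp": ersp_maps,
        "band_erd": erd_doc,
        "band_energy": curves,
        "cv_report": cv,
        "meta": meta,
    }
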