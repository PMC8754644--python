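"""End-to-end orchestration: simulate/load -> segment -> track -> quantify
-> call bursts -> population stats -> autocorrelation -> reconstitution.

Every run writes a manifest (package version, seeds, config hash, per-stage
row counts) next to the CSV outputs, and is idempotent for a fixed seed:
running the same config twice produces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bursts import burst_stats, call_bursts, group_threshold, smooth
from .config import PipelineConfig
from .core import LabelMask, tracks_to_dataframe, trajectories_to_dataframe
from .io import read_masks, read_movie, write_csv, write_masks, write_movie
from .population import active_fractions, autocorrelate
from .reconstitution import DecayParams, remaining_mrna, render_pattern
from .segmentation import (crop_field, default_crop_box, max_project,
                           Method1Config, Method2Config, segment_movie,
                           apply_override)
from .spots import extract_trajectories
from .synthetic import (FieldParams, TelegraphParams, render_movie,
                        variant_presets)
from .tracking import link

log = logging.getLogger("ms2burst")

__all__ = ["run_pipeline", "simulate_from_config"]


def simulate_from_config(config: PipelineConfig):
    """Build (movie, ground truth) from the config's simulation block.

    The block holds optional ``field`` kwargs (FieldParams), plus either
    ``telegraph`` kwargs (TelegraphParams), a ``preset`` name, or a
    ``stripes`` list of ``[[x_lo, x_hi], telegraph_kwargs]`` entries.
    """
    sim = config.simulation or {}
    fp_kw = dict(sim.get("field", {}))
    if "image_shape" in fp_kw:
        fp_kw["image_shape"] = tuple(fp_kw["image_shape"])
    tg = None
    if "preset" in sim:
        tg = variant_presets(sim["preset"])
        tg = replace(tg, frame_interval=config.frame_interval)
    elif "telegraph" in sim:
        tg = TelegraphParams(frame_interval=config.frame_interval,
                             **sim["telegraph"])
    if "stripes" in sim:
        fp_kw["stripe_pattern"] = [
            ((float(lo), float(hi)),
             TelegraphParams(frame_interval=config.frame_interval, **kw))
            for (lo, hi), kw in sim["stripes"]]
    field = FieldParams(**fp_kw)
    n_frames = sim.get("n_frames")
    return render_movie(field, tg, seed=config.seed, n_frames=n_frames)


def _segmentation_config(config: PipelineConfig):
    kw = dict(config.segmentation)
    if config.segmentation_method == 1:
        return Method1Config(**kw)
    return Method2Config(**kw)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 movie_path: str | Path | None = None,
                 override_masks: str | Path | np.ndarray | None = None
                 ) -> Path:
    """Run the configured stages; returns the artifact directory.

    Input is either ``movie_path`` (a T,Z,C,Y,X TIFF) or, when absent, the
    config's simulation block.  ``override_masks`` replaces computed
    segmentation wherever non-zero (file-based stand-in for manual mask
    correction); a full override skips segmentation entirely.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"version": __version__, "python": platform.python_version(),
                      "config_hash": chash, "seed": config.seed,
                      "shuffle_seed": config.shuffle_seed, "stages": {}}
    truth = None

    stage = "input"
    try:
        if movie_path is not None:
            movie = read_movie(movie_path)
        else:
            if config.simulation is None:
                raise ValueError("no movie path and no simulation block")
            movie, truth = simulate_from_config(config)
            write_movie(out / "movie.tif", movie)
            write_masks(out / "true_masks.tif", truth.masks)
            write_csv(out / "true_tracks.csv",
                      tracks_to_dataframe(truth.tracks), chash)
            write_csv(out / "true_trajectories.csv",
                      trajectories_to_dataframe(truth.trajectories), chash)
            write_csv(out / "true_bursts.csv", truth.bursts, chash)
        n_ch = movie.shape[2]
        for ch in (config.channel_histone, config.channel_ms2):
            if not 0 <= ch < n_ch:
                raise ValueError(f"channel {ch} missing (movie has {n_ch})")
        log.info("input: movie %s", movie.shape)

        stage = "project"
        his = max_project(movie, config.channel_histone)
        ms2_proj = max_project(movie, config.channel_ms2)
        ms2_vol = movie[:, :, config.channel_ms2]
        if config.crop:
            box = default_crop_box(his.shape[-2:], config.crop)
            his = crop_field(his, box)
            ms2_proj = crop_field(ms2_proj, box)
            ms2_vol = ms2_vol[..., box[0]:box[1], box[2]:box[3]]

        stage = "segment"
        ov = None
        if override_masks is not None:
            ov = override_masks if isinstance(override_masks, np.ndarray) \
                else read_masks(override_masks)
        if ov is not None and all((ov[t] > 0).all() for t in range(ov.shape[0])):
            masks = [LabelMask(t, ov[t], method="override")
                     for t in range(ov.shape[0])]
            manifest["stages"]["segment"] = {"skipped": "full override"}
        else:
            masks = segment_movie(his, config.segmentation_method, ms2_proj,
                                  _segmentation_config(config))
            if ov is not None:
                masks = [apply_override(m, ov[m.frame]) for m in masks]
            manifest["stages"]["segment"] = {
                "n_labels_mean": float(np.mean([m.n_labels for m in masks]))}
        write_masks(out / "masks.tif",
                    np.stack([m.labels for m in masks]))
        report = pd.DataFrame(
            [(m.frame, m.n_labels, m.threshold, m.method) for m in masks],
            columns=["frame", "n_labels", "threshold", "method"])
        write_csv(out / "segmentation_report.csv", report, chash)
        log.info("segment: mean %.1f labels/frame",
                 report["n_labels"].mean())

        stage = "track"
        max_disp = config.max_disp or config.nucleus_radius
        tracks = link(masks, max_disp=max_disp)
        write_csv(out / "tracks.csv", tracks_to_dataframe(tracks), chash)
        manifest["stages"]["track"] = {"n_tracks": len(tracks)}
        log.info("track: %d tracks", len(tracks))

        stage = "quantify"
        trajs, fits = extract_trajectories(ms2_vol, masks, tracks,
                                           config.frame_interval,
                                           window=config.fit_window)
        write_csv(out / "trajectories.csv",
                  trajectories_to_dataframe(trajs), chash)
        write_csv(out / "spot_fits.csv", fits, chash)
        manifest["stages"]["quantify"] = {
            "n_trajectories": len(trajs),
            "n_invalid_fits": int((~fits["valid"]).sum())}

        stage = "callbursts"
        thr = group_threshold(trajs, window=config.smooth_window,
                              override=config.burst_threshold)
        burst_rows, stat_rows = [], []
        calls = {}
        for tr in trajs:
            s = smooth(tr.intensity, config.smooth_window)
            call = call_bursts(s, thr, min_len=config.min_len,
                               end_frac=config.end_frac, shift=config.shift,
                               nucleus_id=tr.nucleus_id)
            calls[tr.nucleus_id] = call
            st = burst_stats(call, tr, s)
            dt = config.frame_interval
            for b in call.bursts:
                burst_rows.append((tr.nucleus_id, b.start * dt, b.end * dt,
                                   b.peak_value))
            stat_rows.append((tr.nucleus_id, st.n_bursts, st.amplitude,
                              st.duration, st.total_output, st.t_first,
                              st.induction_rate))
        write_csv(out / "bursts.csv",
                  pd.DataFrame(burst_rows, columns=["nucleus_id", "start_s",
                                                    "end_s", "peak"]), chash)
        stats_df = pd.DataFrame(stat_rows, columns=[
            "nucleus_id", "n_bursts", "amplitude", "duration",
            "total_output", "t_first", "induction_rate"])
        write_csv(out / "burst_stats.csv", stats_df, chash)
        manifest["stages"]["callbursts"] = {
            "threshold": thr, "n_bursts": int(stats_df["n_bursts"].sum())}
        log.info("callbursts: %d bursts at threshold %.2f",
                 stats_df["n_bursts"].sum(), thr)

        stage = "stats"
        pop = active_fractions(trajs, fraction=config.activity_fraction)
        write_csv(out / "population.csv", pop.to_dataframe(), chash)

        stage = "autocorr"
        ac = autocorrelate(trajs, config.frame_interval,
                           window=config.smooth_window,
                           shuffle_seed=config.shuffle_seed)
        write_csv(out / "autocorr.csv",
                  pd.DataFrame({"lag_s": ac.lags_s, "mean_ac": ac.mean,
                                "null_ac": ac.null_mean}), chash)

        stage = "reconstruct"
        decay = DecayParams(half_life=config.half_life,
                            model=config.decay_model)
        amounts = {}
        final = masks[-1]
        last_frame = len(masks) - 1
        for tr_obj, traj in zip(tracks, trajs):
            if tr_obj.end_frame == last_frame:
                amounts[tr_obj.labels[-1]] = remaining_mrna(traj, decay)
        write_csv(out / "remaining_mrna.csv",
                  pd.DataFrame(sorted(amounts.items()),
                               columns=["final_label", "remaining"]), chash)
        his_last = his[-1]
        rgb = render_pattern(final, amounts, his_last)
        try:
            import imageio.v3 as iio
            iio.imwrite(out / "reconstitution.png", rgb)
        except Exception:  # rendering to disk is best-effort
            pass
        manifest["stages"]["reconstruct"] = {"n_nuclei": len(amounts)}
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("pipeline aborted at stage %r", stage)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
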