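"""Umbrella pipeline: run generation, analysis, field and heating stages
from one validated configuration, emitting a reproducible artifact manifest.
"""

from __future__ import annotations

import logging
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .acoustics import USStimulus, characterize_beam, exposure_metrics
from .behavior import rout_exclude, session_metrics
from .config import RunConfig, get_medium, get_preset, preset_pressure_range
from .neural import analyze_spike_trains, ecog_activation_map, evoked_potential
from .synth import GeneratorConfig, gen_ecog, gen_licks, gen_retina_mea
from .thermal import ultrasound_heating_scenario

__all__ = ["run_pipeline"]

log = logging.getLogger("sonosim")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes) a manifest listing inputs, outputs with content
    hashes, the seed and package version.  Any stage failure aborts with the
    stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = _pkg_version("sonosim")
    except Exception:  # not installed (e.g. source tree)
        pkg_version = "unknown"
    manifest: dict = {
        "config": config.model_dump(),
        "seed": config.seed,
        "version": pkg_version,
        "stages": {},
        "outputs": {},
    }
    order = [s for s in ("generate", "analyze", "field", "heat") if s in config.stages]
    gen_cfg = GeneratorConfig(seed=config.seed)
    for stage in order:
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            files = _STAGES[stage](config, gen_cfg, outdir)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for f in files:
            manifest["outputs"][str(Path(f).name)] = sio.sha256_of(f)
        log.info("stage %s: done (%.1fs)", stage, time.perf_counter() - t0)
    sio.write_manifest(outdir / "manifest.json", manifest)
    return manifest


def _stage_generate(config: RunConfig, gen_cfg: GeneratorConfig, outdir: Path):
    preset = get_preset(config.preset)
    pressure = preset_pressure_range(config.preset)[1]
    spikes, events, truth = gen_retina_mea(
        gen_cfg, frequency=preset.center_frequency, pressure=pressure
    )
    files = list(sio.write_spike_set(outdir / "retina", spikes))
    truth.to_csv(outdir / "retina_truth.csv", index=False)
    files.append(outdir / "retina_truth.csv")
    events_df = pd.DataFrame(
        {"onset": events.onsets, "duration": events.duration}
    )
    events_df.to_csv(outdir / "retina_events.csv", index=False)
    files.append(outdir / "retina_events.csv")

    rec, ecog_truth = gen_ecog(gen_cfg, pressure=pressure)
    files.append(sio.write_ecog(outdir / "ecog.h5", rec))
    ecog_truth.to_csv(outdir / "ecog_truth.csv", index=False)
    files.append(outdir / "ecog_truth.csv")

    sessions, lick_truth = gen_licks(gen_cfg, n_compulsive=1)
    files.append(sio.write_lick_sessions(outdir / "licks.csv", sessions))
    lick_truth.to_csv(outdir / "licks_truth.csv", index=False)
    files.append(outdir / "licks_truth.csv")
    return files


def _stage_analyze(config: RunConfig, gen_cfg: GeneratorConfig, outdir: Path):
    files = []
    spikes = sio.read_spike_set(
        outdir / "retina_spikes.csv", outdir / "retina_positions.csv"
    )
    events_df = pd.read_csv(outdir / "retina_events.csv")
    from .neural import StimulusEvents

    events = StimulusEvents(
        onsets=events_df["onset"].to_numpy(),
        duration=float(events_df["duration"].iloc[0]),
    )
    cell_table = analyze_spike_trains(spikes, events)
    cell_table.to_csv(outdir / "retina_metrics.csv", index=False)
    files.append(outdir / "retina_metrics.csv")

    rec = sio.read_ecog(outdir / "ecog.h5")
    ev = evoked_potential(rec)
    amap = ecog_activation_map(
        ev.n1_amplitude, rec.positions[["x", "y"]].to_numpy(), ev.noise_sd
    )
    pd.DataFrame(
        {
            "channel": rec.positions["channel"],
            "n1_uV": ev.n1_amplitude * 1e6,
        }
    ).to_csv(outdir / "ecog_metrics.csv", index=False)
    files.append(outdir / "ecog_metrics.csv")
    summary = {
        "activated_area_mm2": amap.activated_area * 1e6,
        "centre_x_mm": np.nan if amap.centre is None else amap.centre[0] * 1e3,
        "centre_y_mm": np.nan if amap.centre is None else amap.centre[1] * 1e3,
        "noise_sd_uV": ev.noise_sd * 1e6,
    }
    pd.DataFrame([summary]).to_csv(outdir / "ecog_summary.csv", index=False)
    files.append(outdir / "ecog_summary.csv")

    sessions = sio.read_lick_sessions(outdir / "licks.csv")
    metrics = [session_metrics(s) for s in sessions]
    spont = np.array([m.spontaneous_rate for m in metrics])
    excluded = rout_exclude(spont)
    rows = [
        {
            "animal_id": s.animal_id,
            "pressure_mpa": s.pressure / 1e6,
            "success_rate_pct": m.success_rate,
            "anticipatory_rate_hz": m.anticipatory_rate,
            "spontaneous_rate_hz": m.spontaneous_rate,
            "first_lick_latency_ms": m.first_lick_latency * 1e3,
            "excluded": bool(e),
        }
        for s, m, e in zip(sessions, metrics, excluded)
    ]
    pd.DataFrame(rows).to_csv(outdir / "behavior_metrics.csv", index=False)
    files.append(outdir / "behavior_metrics.csv")
    return files


def _stage_field(config: RunConfig, gen_cfg: GeneratorConfig, outdir: Path):
    medium = get_medium("water")
    metrics = {}
    transducer = get_preset(config.preset)
    m, profiles = characterize_beam(transducer, medium)
    metrics[config.preset] = m
    files = [sio.write_beam_metrics(outdir / "beam_metrics.csv", metrics)]
    prof = pd.DataFrame(
        {"x_mm": profiles["x"] * 1e3, "pressure": profiles["lateral_pressure"]}
    )
    prof.to_csv(outdir / "lateral_profile.csv", index=False)
    files.append(outdir / "lateral_profile.csv")
    return files


def _stage_heat(config: RunConfig, gen_cfg: GeneratorConfig, outdir: Path):
    transducer = get_preset(config.preset)
    pressure = preset_pressure_range(config.preset)[1]
    stimulus = USStimulus(peak_pressure=pressure, burst_duration=0.02)
    # desk-scale run: small focal subdomain, single burst
    result = ultrasound_heating_scenario(
        transducer,
        stimulus,
        lateral_halfwidth=1.0e-3,
        axial_halfwidth=4.0e-3,
        dx=75e-6,
        dz=400e-6,
    )
    trace = pd.DataFrame(
        {"t_s": result.trace_times, "rise_degc": result.rise_trace}
    )
    trace.to_csv(outdir / "heat_rise_trace.csv", index=False)
    exp = exposure_metrics(stimulus, averaging_period=None)
    pd.DataFrame(
        [
            {
                "peak_rise_degc": result.rise,
                "isppa_w_cm2": exp["isppa"],
                "isptp_w_cm2": exp["isptp"],
            }
        ]
    ).to_csv(outdir / "heat_summary.csv", index=False)
    return [outdir / "heat_rise_trace.csv", outdir / "heat_summary.csv"]


_STAGES = {
    "generate": _stage_generate,
    "analyze": _stage_analyze,
    "field": _stage_field,
    "heat": _stage_heat,
}
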