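"""Session container: a directory of TSV tables plus a YAML meta file.

Layout (schema version 1)::

    <session_dir>/
      meta.yaml          sample_rate, geometry, schema_version, config
      timeline.tsv       time_s, position_cm, corridor_id, wheel_cm,
                         speed_cm_s, gain, trial_id, lick, reward,
                         pupil_size, pupil_az, pupil_el
      spikes.tsv         neuron_id, time_s
      neurons.tsv        neuron_id, region, depth_um, waveform_us
      lfp.tsv            time_s, value, true_phase_deg
      ground_truth.tsv   generator parameters per neuron (optional)

Floats are written with 17 significant digits, so a write/read round trip
is bit-exact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import TrackGeometry
from .session import SessionTimeline, SpikeTrainSet
from .synth import GeneratorConfig, Session

SCHEMA_VERSION = 1
_REQUIRED = ("meta.yaml", "timeline.tsv", "spikes.tsv", "neurons.tsv", "lfp.tsv")
_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Missing table or incompatible on-disk schema version."""


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a directory of TSV tables; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tl = session.timeline
    timeline = pd.DataFrame(
        {
            "time_s": tl.time,
            "position_cm": tl.position,
            "corridor_id": tl.corridor_id,
            "wheel_cm": tl.wheel,
            "speed_cm_s": tl.speed,
            "gain": tl.gain,
            "trial_id": tl.trial_id,
            "lick": tl.lick,
            "reward": tl.reward.astype(int),
        }
    )
    for name, series in tl.covariates.items():
        timeline[name] = series
    _write_tsv(timeline, path / "timeline.tsv")

    st = session.spikes
    spikes = pd.DataFrame(
        {
            "neuron_id": np.repeat(
                st.meta["neuron_id"].to_numpy(), [len(t) for t in st.spike_times]
            ),
            "time_s": np.concatenate(st.spike_times) if len(st) else np.empty(0),
        }
    )
    _write_tsv(spikes, path / "spikes.tsv")
    _write_tsv(
        st.meta[["neuron_id", "region", "depth_um", "waveform_us"]], path / "neurons.tsv"
    )
    _write_tsv(
        pd.DataFrame(
            {"time_s": tl.time, "value": session.lfp, "true_phase_deg": session.theta_phase}
        ),
        path / "lfp.tsv",
    )
    if session.ground_truth is not None:
        _write_tsv(session.ground_truth, path / "ground_truth.tsv")

    geom = tl.geometry
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sample_rate": float(tl.sample_rate),
        "geometry": {
            "corridor_length": float(geom.corridor_length),
            "landmarks": [float(x) for x in geom.landmarks],
            "reward_center": float(geom.reward_center),
            "reward_halfwidth": float(geom.reward_halfwidth),
        },
        "config": _config_to_dict(session.config),
        "covariates": list(tl.covariates.keys()),
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def _config_to_dict(config: GeneratorConfig | None):
    if config is None:
        return None
    d = dataclasses.asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _config_from_dict(d) -> GeneratorConfig | None:
    if d is None:
        return None
    fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in d.items() if k in fields
    }
    return GeneratorConfig(**kwargs)


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    for name in _REQUIRED:
        if not (path / name).exists():
            raise SchemaError(f"session container is missing required table {name!r}")
    meta = yaml.safe_load((path / "meta.yaml").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version {meta.get('schema_version')!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    geom = TrackGeometry(
        corridor_length=meta["geometry"]["corridor_length"],
        landmarks=tuple(meta["geometry"]["landmarks"]),
        reward_center=meta["geometry"]["reward_center"],
        reward_halfwidth=meta["geometry"]["reward_halfwidth"],
    )
    timeline_df = pd.read_csv(path / "timeline.tsv", sep="\t", float_precision="round_trip")
    covariates = {
        name: timeline_df[name].to_numpy(dtype=float)
        for name in meta.get("covariates", [])
    }
    timeline = SessionTimeline(
        time=timeline_df["time_s"].to_numpy(dtype=float),
        position=timeline_df["position_cm"].to_numpy(dtype=float),
        corridor_id=timeline_df["corridor_id"].to_numpy(dtype=int),
        wheel=timeline_df["wheel_cm"].to_numpy(dtype=float),
        speed=timeline_df["speed_cm_s"].to_numpy(dtype=float),
        gain=timeline_df["gain"].to_numpy(dtype=float),
        trial_id=timeline_df["trial_id"].to_numpy(dtype=int),
        lick=timeline_df["lick"].to_numpy(dtype=int),
        reward=timeline_df["reward"].to_numpy(dtype=bool),
        covariates=covariates,
        sample_rate=float(meta["sample_rate"]),
        geometry=geom,
    )
    neurons = pd.read_csv(path / "neurons.tsv", sep="\t", float_precision="round_trip")
    spikes_df = pd.read_csv(path / "spikes.tsv", sep="\t", float_precision="round_trip")
    spike_times = [
        spikes_df.loc[spikes_df["neuron_id"] == nid, "time_s"].to_numpy(dtype=float)
        for nid in neurons["neuron_id"]
    ]
    spikes = SpikeTrainSet(spike_times, neurons)
    lfp_df = pd.read_csv(path / "lfp.tsv", sep="\t", float_precision="round_trip")
    gt_path = path / "ground_truth.tsv"
    ground_truth = pd.read_csv(gt_path, sep="\t", float_precision="round_trip") if gt_path.exists() else None
    return Session(
        timeline=timeline,
        spikes=spikes,
        lfp=lfp_df["value"].to_numpy(dtype=float),
        theta_phase=lfp_df["true_phase_deg"].to_numpy(dtype=float),
        ground_truth=ground_truth,
        config=_config_from_dict(meta.get("config")),
    )
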