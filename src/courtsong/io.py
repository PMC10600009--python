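"""Readers/writers for the shared on-disk formats, and the pipeline runner.

Formats (all plain text):

- trajectory: CSV with header exactly
  ``t,mfDist,mfAngle,fmAngle,mFV,fFV,mLS,fLS,mRS,fRS`` (seconds, mm,
  degrees, mm/s, rad/s as typed on :class:`~courtsong.types.CourtshipTrajectory`);
- song: JSON document, schema ``courtsong-song/1`` (bouts -> trains ->
  events, optional noise segment);
- taps: JSON, schema ``courtsong-taps/1``;
- trials: JSON, schema ``courtsong-trials/1``.

All times are serialized as float seconds from recording start.
``run_pipeline`` ties the stages together: synthesize -> annotate ->
fit -> GLM, writing versioned outputs and a manifest of seeds and
parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from courtsong import annotate, fit, glm, synth
from courtsong.circuit import default_model
from courtsong.types import (
    TRAJECTORY_FIELDS,
    Bout,
    CourtshipTrajectory,
    SongAnnotation,
    TapSeries,
    Train,
    Trial,
    TrialSet,
)

SONG_SCHEMA = "courtsong-song/1"
TAPS_SCHEMA = "courtsong-taps/1"
TRIALS_SCHEMA = "courtsong-trials/1"


def write_trajectory(traj: CourtshipTrajectory, path: str | Path) -> None:
    df = pd.DataFrame({k: getattr(traj, k) for k in TRAJECTORY_FIELDS})
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path: str | Path) -> CourtshipTrajectory:
    """Read the canonical trajectory CSV; rejects unknown or missing
    columns and non-uniform time grids, naming the first bad line."""
    df = pd.read_csv(path)
    cols = tuple(df.columns)
    if cols != TRAJECTORY_FIELDS:
        extra = set(cols) - set(TRAJECTORY_FIELDS)
        missing = set(TRAJECTORY_FIELDS) - set(cols)
        raise ValueError(
            f"trajectory header mismatch: extra columns {sorted(extra)}, "
            f"missing columns {sorted(missing)}"
        )
    t = df["t"].to_numpy(float)
    if t.size > 1:
        dt = np.diff(t)
        bad = np.where(dt <= 0)[0]
        if bad.size:
            raise ValueError(f"non-increasing time at line {bad[0] + 3} of {path}")
        bad = np.where(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-7))[0]
        if bad.size:
            raise ValueError(f"gap in time grid at line {bad[0] + 3} of {path}")
    return CourtshipTrajectory(
        **{k: df[k].to_numpy(float) for k in TRAJECTORY_FIELDS}
    )


def _train_to_dict(tr: Train) -> dict:
    d = {"mode": tr.mode, "start": tr.start, "end": tr.end}
    if np.isfinite(tr.amplitude):
        d["amplitude"] = tr.amplitude
    if tr.events:
        d["events"] = list(map(float, tr.events))
    return d


def write_song(song: SongAnnotation, path: str | Path) -> None:
    doc = {
        "schema": SONG_SCHEMA,
        "clock_origin": song.clock_origin,
        "bouts": [
            {"trains": [_train_to_dict(tr) for tr in b.trains]} for b in song.bouts
        ],
        "noise_segment": (
            None
            if song.noise_segment is None
            else np.round(song.noise_segment, 6).tolist()
        ),
    }
    Path(path).write_text(json.dumps(doc))


def read_song(path: str | Path) -> SongAnnotation:
    """Read a song JSON document; the schema version is checked and
    overlapping bouts are rejected."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SONG_SCHEMA:
        raise ValueError(
            f"unsupported song schema {doc.get('schema')!r}; expected {SONG_SCHEMA}"
        )
    bouts = [
        Bout(
            trains=[
                Train(
                    mode=tr["mode"],
                    start=float(tr["start"]),
                    end=float(tr["end"]),
                    amplitude=float(tr.get("amplitude", "nan")),
                    events=[float(e) for e in tr.get("events", [])],
                )
                for tr in b["trains"]
            ]
        )
        for b in doc["bouts"]
    ]
    noise = doc.get("noise_segment")
    return SongAnnotation(
        bouts=bouts,
        noise_segment=None if noise is None else np.asarray(noise, float),
        clock_origin=float(doc.get("clock_origin", 0.0)),
    )


def write_taps(taps: TapSeries, path: str | Path) -> None:
    doc = {
        "schema": TAPS_SCHEMA,
        "t0": float(taps.t[0]),
        "rate": float(1.0 / (taps.t[1] - taps.t[0])) if len(taps) > 1 else 0.0,
        "is_tap": [int(v) for v in taps.is_tap],
    }
    Path(path).write_text(json.dumps(doc))


def read_taps(path: str | Path) -> TapSeries:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != TAPS_SCHEMA:
        raise ValueError(f"unsupported taps schema {doc.get('schema')!r}")
    is_tap = np.asarray(doc["is_tap"], int)
    t = doc["t0"] + np.arange(is_tap.size) / doc["rate"]
    return TapSeries(t=t, is_tap=is_tap)


def write_trials(trials: TrialSet, path: str | Path) -> None:
    doc = {
        "schema": TRIALS_SCHEMA,
        "trials": [
            {
                "block_id": tr.block_id,
                "irradiance": tr.irradiance,
                "duty_cycle": tr.duty_cycle,
                "t_start": tr.t_start,
                "t_end": tr.t_end,
                "stim_intervals": [list(iv) for iv in tr.stim_intervals],
            }
            for tr in trials.trials
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_trials(path: str | Path) -> TrialSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != TRIALS_SCHEMA:
        raise ValueError(f"unsupported trials schema {doc.get('schema')!r}")
    return TrialSet(
        trials=[
            Trial(
                block_id=int(tr["block_id"]),
                irradiance=float(tr["irradiance"]),
                duty_cycle=float(tr["duty_cycle"]),
                t_start=float(tr["t_start"]),
                t_end=float(tr["t_end"]),
                stim_intervals=[tuple(iv) for iv in tr["stim_intervals"]],
            )
            for tr in doc["trials"]
        ]
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    duration: float = 1200.0  # s of synthetic courtship
    synth: dict = dataclasses.field(default_factory=dict)
    snippet_length: float = 200.0
    ga: dict = dataclasses.field(default_factory=dict)
    glm_n_fits: int = 11
    glm_frac: float = 0.70

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute synthesize -> annotate -> fit -> GLM, writing artifacts.

    Writes trajectory CSV, song/taps JSON, bout-statistics CSV, the GA
    fit result and GLM summary as JSON, and a manifest recording seeds
    and a hash of the configuration. Returns the artifact directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = synth.SynthParams(seed=config.seed, **config.synth)

    traj = synth.generate_trajectory(params, config.duration)
    song = synth.generate_song(traj, params)
    taps = synth.generate_taps(traj, song, params)
    write_trajectory(traj, out / "trajectory.csv")
    write_song(song, out / "song.json")
    write_taps(taps, out / "taps.json")

    clean = annotate.merge_close_bouts(annotate.filter_bouts_by_snr(song))
    rows = []
    for context in (None, "far", "near"):
        dist = annotate.bout_distribution(clean, traj, context=context)
        for typ, freq in dist.freqs.items():
            rows.append(
                {
                    "context": context or "all",
                    "bout_type": typ,
                    "count": dist.counts[typ],
                    "frequency": freq,
                }
            )
    pd.DataFrame(rows).to_csv(out / "bout_statistics.csv", index=False)

    snippet = fit.select_snippet(
        clean, traj, length=config.snippet_length, seed=config.seed
    )
    cfg = fit.GAConfig(seed=config.seed, **config.ga)
    fit_res = fit.run_ga(default_model(), snippet, cfg)
    (out / "fit_result.json").write_text(
        json.dumps(
            {
                "params": fit_res.params,
                "objective": fit_res.objective,
                "trace": fit_res.trace,
                "variant": fit_res.variant,
                "n_bout_sim": fit_res.n_bout_sim,
                "n_bout_target": fit_res.n_bout_target,
            },
            indent=1,
        )
    )

    p1a = glm.p1a_rate_from_taps(taps)
    smoothed = glm.smooth_features(traj)
    X = glm.extract_histories(smoothed, clean, extra_features={"P1_rate": p1a.rate})
    glm_res = glm.resample_fits(
        X, n_fits=config.glm_n_fits, frac=config.glm_frac, seed=config.seed
    )
    (out / "glm_summary.json").write_text(
        json.dumps(
            {
                "mean_deviance_reduction": glm_res.mean_dr,
                "mad_deviance_reduction": glm_res.mad_dr,
                "n_fits": glm_res.n_fits,
                "frac": glm_res.frac,
            },
            indent=1,
        )
    )

    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_bouts_raw": len(song.bouts),
        "n_bouts_clean": len(clean.bouts),
        "stages": ["synth", "annotate", "fit", "glm"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


__all__ = [
    "SONG_SCHEMA",
    "TAPS_SCHEMA",
    "TRIALS_SCHEMA",
    "read_trajectory",
    "write_trajectory",
    "read_song",
    "write_song",
    "read_taps",
    "write_taps",
    "read_trials",
    "write_trials",
    "RunConfig",
    "run_pipeline",
]
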