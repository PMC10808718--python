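"""File formats, experiment configuration and dataset (de)serialization.

Everything on disk is plain text: events files are tab-separated with the
BIDS events columns (onset, duration, trial_type; seconds, time origin at
the first retained volume), per-run ROI/feedback series are tab-separated
tables with one row per volume, results are CSV, ground truth is JSONL and
the experiment configuration is a key = value text file. Every table
carries a comment header recording the master seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ALL_GROUPS,
    BlockDesign,
    CohortDataset,
    EffectScenario,
    GroupSpec,
    Participant,
    RunRecording,
    SimulationConfig,
    make_block_design,
    null_scenario,
    reference_scenario,
)
from .online import ChainSettings

_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
_CHAIN_FIELDS = {f.name: f.type for f in dataclasses.fields(ChainSettings)}


@dataclass
class ExperimentConfig:
    """Complete description of one simulated experiment."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    chain: ChainSettings = field(default_factory=ChainSettings)
    scenario: str = "reference"
    output_dir: str = "faceloop-out"

    def scenario_obj(self) -> EffectScenario:
        if self.scenario == "null":
            return null_scenario()
        if self.scenario == "reference":
            return reference_scenario()
        raise ValueError(f"unknown scenario {self.scenario!r}")


def _coerce(raw: str, typ: str):
    if "bool" in str(typ):
        return raw.lower() in ("1", "true", "yes")
    if "int" in str(typ):
        return int(raw)
    if "float" in str(typ):
        return float(raw)
    return raw


def write_config(cfg: ExperimentConfig, path: str | Path) -> None:
    lines = [f"# faceloop experiment config (v{__version__})"]
    for name in _CONFIG_FIELDS:
        lines.append(f"simulation.{name} = {getattr(cfg.simulation, name)}")
    for name in _CHAIN_FIELDS:
        lines.append(f"chain.{name} = {getattr(cfg.chain, name)}")
    lines.append(f"scenario = {cfg.scenario}")
    lines.append(f"output_dir = {cfg.output_dir}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> ExperimentConfig:
    sim_kw, chain_kw, top = {}, {}, {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = (s.strip() for s in line.partition("="))
        if key.startswith("simulation."):
            name = key.split(".", 1)[1]
            if name not in _CONFIG_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            sim_kw[name] = _coerce(raw, _CONFIG_FIELDS[name])
        elif key.startswith("chain."):
            name = key.split(".", 1)[1]
            if name not in _CHAIN_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            chain_kw[name] = _coerce(raw, _CHAIN_FIELDS[name])
        elif key in ("scenario", "output_dir"):
            top[key] = raw
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return ExperimentConfig(
        simulation=SimulationConfig(**sim_kw),
        chain=ChainSettings(**chain_kw),
        **top,
    )


# ------------------------------------------------------------------- writers


def _header(seed: int) -> str:
    return f"# faceloop v{__version__} seed={seed}\n"


def events_frame(design: BlockDesign) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"onset": onset, "duration": dur, "trial_type": kind}
            for onset, dur, kind in design.blocks
        ]
    )


def write_events(design: BlockDesign, path: str | Path) -> None:
    events_frame(design).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_frame(rec: RunRecording) -> pd.DataFrame:
    """Per-volume table: ROI BOLD, online-chain outputs and morph trace."""
    df = pd.DataFrame(
        rec.roi_bold, columns=[f"bold_{r}" for r in ("V1", "FFA", "Amy", "mOFC")]
    )
    df["amy_raw"] = rec.amy_feedback_raw
    df["amy_despiked"] = rec.despiked
    df["norm_feedback"] = rec.norm_feedback
    df["morph_index"] = rec.morph_trace
    for j in range(rec.motion_nuisance.shape[1]):
        df[f"motion_{j + 1}"] = rec.motion_nuisance[:, j]
    return df


def write_table(df: pd.DataFrame, path: str | Path, seed: int, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_dataset(dataset: CohortDataset, out_dir: str | Path, force: bool = False) -> Path:
    """Write a simulated cohort: per-participant per-run events + series
    tables, ground-truth JSONL and a manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    seed = dataset.config.seed
    n_records = 0
    truth_path = out / "ground_truth.jsonl"
    with open(truth_path, "w") as truth:
        for p in dataset.participants:
            pdir = out / p.id
            pdir.mkdir(exist_ok=True)
            for rec in p.runs:
                stem = f"{p.id}_run-{rec.run_index}"
                write_events(rec.design, pdir / f"{stem}_events.tsv")
                write_table(run_frame(rec), pdir / f"{stem}_series.tsv", seed)
                n_records += 1
            truth.write(
                json.dumps(
                    {
                        "participant_id": p.id,
                        "group": p.group.name,
                        "congruent": p.group.congruent,
                        "age": p.age,
                        "gender": p.gender,
                        "A": np.asarray(p.params.A).tolist(),
                        "B_face": np.asarray(p.params.B_face).tolist(),
                        "B_int": np.asarray(p.params.B_int).tolist(),
                        "C": np.asarray(p.params.C).tolist(),
                        "scores": p.scores,
                    }
                )
                + "\n"
            )
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "scenario": dataset.scenario.name,
        "n_participants": len(dataset.participants),
        "n_run_records": n_records,
        "groups": [g.name for g in ALL_GROUPS],
        "simulation": dataclasses.asdict(dataset.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def load_dataset(in_dir: str | Path) -> CohortDataset:
    """Reconstruct a cohort from a written dataset directory.

    The latent neural trajectories are not serialized; reloaded recordings
    carry an empty ``neural_truth``.
    """
    root = Path(in_dir)
    manifest_path = root / "manifest.json"
    truth_path = root / "ground_truth.jsonl"
    missing = [str(p) for p in (manifest_path, truth_path) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"dataset incomplete, missing: {missing}")
    manifest = json.loads(manifest_path.read_text())
    sim_kw = manifest["simulation"]
    config = SimulationConfig(**sim_kw)
    design = make_block_design(config)
    from .cohort import NeuralParams

    participants = []
    for line in truth_path.read_text().splitlines():
        info = json.loads(line)
        cond, direction = info["group"].split("-")
        group = GroupSpec(cond, direction)
        params = NeuralParams(
            A=np.array(info["A"]),
            B_face=np.array(info["B_face"]),
            B_int=np.array(info["B_int"]),
            C=np.array(info["C"]),
        )
        runs = []
        pdir = root / info["participant_id"]
        for r in range(1, config.n_runs + 1):
            series = pdir / f"{info['participant_id']}_run-{r}_series.tsv"
            if not series.exists():
                raise FileNotFoundError(f"missing series file: {series}")
            df = read_table(series)
            motion_cols = [c for c in df.columns if c.startswith("motion_")]
            runs.append(
                RunRecording(
                    roi_bold=df[
                        ["bold_V1", "bold_FFA", "bold_Amy", "bold_mOFC"]
                    ].to_numpy(),
                    amy_feedback_raw=df["amy_raw"].to_numpy(),
                    norm_feedback=df["norm_feedback"].to_numpy(),
                    despiked=df["amy_despiked"].to_numpy(),
                    morph_trace=df["morph_index"].to_numpy(int),
                    neural_truth=np.empty((0, 4)),
                    design=design,
                    motion_nuisance=df[motion_cols].to_numpy(),
                    group=group,
                    run_index=r,
                )
            )
        scores = {k: tuple(v) for k, v in info["scores"].items()}
        participants.append(
            Participant(
                id=info["participant_id"],
                group=group,
                params=params,
                runs=runs,
                scores=scores,
                age=info["age"],
                gender=info["gender"],
            )
        )
    scenario = (
        null_scenario() if manifest["scenario"] == "null" else reference_scenario()
    )
    return CohortDataset(config=config, scenario=scenario, participants=participants)
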