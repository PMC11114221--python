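"""End-to-end pipeline orchestration and file validation.

Chains the stages of the artificial olfactory system: synthesize
receptor-array responses → refine them into 9 × 3 binary patterns → train
the device-aware network → evaluate → sensor statistics (PCA, detection
limits, mixture combinatorics).  One global seed drives everything; each
stage derives its own seed as a stable hash of (global seed, stage name),
so any stage can be replayed in isolation and rerunning a config
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ann import AnnConfig, init_network, train
from .device import DeviceParams
from .refine import (
    MIXED_CLASSES,
    SINGLE_CLASSES,
    OdorPattern,
    RegionScheme,
    build_datasets,
)
from .stats import detection_limit, enumerate_mixtures, pca_responses
from .synth import (
    AffinityProfile,
    default_affinity_profile,
    make_calibration,
    sample_responses,
)

__all__ = [
    "PipelineConfig",
    "TASK_DEFAULTS",
    "stage_seed",
    "run_pipeline",
    "validate_files",
]

logger = logging.getLogger(__name__)

#: per-task defaults: dataset sizes, architecture and training length
TASK_DEFAULTS = {
    "single": {
        "classes": SINGLE_CLASSES,
        "n_train": 216,
        "n_infer": 40,
        "n_hidden": 14,
        "total_steps": 1000,
    },
    "mixed": {
        "classes": MIXED_CLASSES,
        "n_train": 2194,
        "n_infer": 366,
        "n_hidden": 27,
        "total_steps": 150_000,
    },
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed, a hash of (global seed, stage name)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one end-to-end run, under a single global seed."""

    seed: int = 0
    device: DeviceParams = field(default_factory=lambda: DeviceParams(g_min=100.0, g_max=170.3, a_p=100.0, a_d=100.0))
    profile: AffinityProfile = field(default_factory=default_affinity_profile)
    scheme: RegionScheme | None = None  # optional override of the fitted scheme
    n_train: int | None = None
    n_infer: int | None = None
    total_steps: int | None = None
    ann_overrides: dict = field(default_factory=dict)

    def ann_config(self, task: str, n_classes: int) -> AnnConfig:
        d = TASK_DEFAULTS[task]
        kwargs = dict(
            n_input=27,
            n_hidden=d["n_hidden"],
            n_output=n_classes,
            total_steps=self.total_steps if self.total_steps is not None else d["total_steps"],
            seed=stage_seed(self.seed, f"train-{task}"),
        )
        kwargs.update(self.ann_overrides)
        return AnnConfig(**kwargs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "device": json.loads(self.device.to_json()),
                "profile": json.loads(self.profile.to_json()),
                "scheme": None if self.scheme is None else json.loads(self.scheme.to_json()),
                "n_train": self.n_train,
                "n_infer": self.n_infer,
                "total_steps": self.total_steps,
                "ann_overrides": self.ann_overrides,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        return cls(
            seed=int(d.get("seed", 0)),
            device=DeviceParams.from_json(json.dumps(d["device"]))
            if d.get("device")
            else DeviceParams(g_min=100.0, g_max=170.3),
            profile=AffinityProfile.from_json(json.dumps(d["profile"]))
            if d.get("profile")
            else default_affinity_profile(),
            scheme=RegionScheme.from_json(json.dumps(d["scheme"])) if d.get("scheme") else None,
            n_train=d.get("n_train"),
            n_infer=d.get("n_infer"),
            total_steps=d.get("total_steps"),
            ann_overrides=d.get("ann_overrides", {}),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, task: str, out_dir) -> dict:
    """Run synthesize → refine → train → evaluate → stats into ``out_dir``.

    Writes every intermediate artifact (datasets, scheme, trained state,
    accuracy trajectory) plus a ``report.json`` with the headline numbers
    and per-file checksums, and returns the report as a dict.
    """
    if task not in TASK_DEFAULTS:
        raise ValueError(f"task must be one of {sorted(TASK_DEFAULTS)}, got {task!r}")
    defaults = TASK_DEFAULTS[task]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    classes = defaults["classes"]
    n_train = config.n_train if config.n_train is not None else defaults["n_train"]
    n_infer = config.n_infer if config.n_infer is not None else defaults["n_infer"]

    logger.info("stage=datasets task=%s n_train=%d n_infer=%d seed=%d",
                task, n_train, n_infer, stage_seed(config.seed, f"datasets-{task}"))
    scheme, train_set, infer_set = build_datasets(
        config.profile,
        classes,
        n_train=n_train,
        n_infer=n_infer,
        seed=stage_seed(config.seed, f"datasets-{task}"),
        scheme=config.scheme,
    )

    (out / "config.json").write_text(config.to_json())
    (out / "scheme.json").write_text(scheme.to_json())
    train_set.to_jsonl(out / "train.jsonl")
    infer_set.to_jsonl(out / "inference.jsonl")

    cfg = config.ann_config(task, len(train_set.class_names))
    logger.info("stage=train arch=%dx%dx%d steps=%d seed=%d",
                cfg.n_input, cfg.n_hidden, cfg.n_output, cfg.total_steps, cfg.seed)
    state = init_network(cfg, config.device, seed=stage_seed(config.seed, f"init-{task}"))
    traj = train(state, train_set, infer_set, cfg, seed=cfg.seed)
    traj.to_tsv(out / "trajectory.tsv")
    (out / "state.json").write_text(state.to_json())

    # sensor statistics on the single-odorant response structure
    stats_seed = stage_seed(config.seed, "stats")
    rng_children = np.random.SeedSequence(stats_seed).spawn(
        len(config.profile.odorants) * (1 + len(config.profile.channels))
    )
    child = iter(rng_children)
    pca_rows = []
    for odorant in config.profile.odorants:
        recs = sample_responses(
            config.profile, {odorant: 1.0}, n_replicates=10, seed=next(child)
        )
        for i in range(0, len(recs), len(config.profile.channels)):
            pca_rows.append([r.gmax for r in recs[i : i + len(config.profile.channels)]])
    pca = pca_responses(np.array(pca_rows))

    lods = {}
    for odorant in config.profile.odorants:
        for channel in config.profile.channels:
            curve = make_calibration(config.profile, channel, odorant, seed=next(child))
            lods[f"{channel}/{odorant}"] = detection_limit(curve)

    report = {
        "task": task,
        "seed": config.seed,
        "n_train": len(train_set),
        "n_infer": len(infer_set),
        "classes": list(train_set.class_names),
        "final_accuracy_pct": traj.final,
        "peak_accuracy_pct": traj.peak,
        "accuracy_at_first_epoch_pct": float(traj.accuracy[1]) if len(traj.accuracy) > 1 else None,
        "pca_explained_variance_ratio": np.round(pca.explained_variance_ratio, 6).tolist(),
        "detection_limits_ppm": {k: round(v, 6) for k, v in lods.items()},
        "n_two_odorant_mixtures": len(enumerate_mixtures(config.profile.odorants, 2)),
        "n_three_odorant_mixtures": len(enumerate_mixtures(config.profile.odorants, 3)),
    }
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "report.json"
    }
    report["checksums_sha256"] = checksums
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# file validation


def _validate_patterns_jsonl(path: Path, messages: list) -> None:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if "class_names" not in header or "split" not in header:
            messages.append("line 1: missing class_names/split header")
            return
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                OdorPattern.from_record(json.loads(line))
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                messages.append(f"line {ln}: {exc}")


def _validate_tsv(path: Path, messages: list) -> None:
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"sample_id", "composition", "total_ppm", "channel", "gmax_uS"} <= cols:
        from .synth import frame_to_records

        for i in range(len(df)):
            try:
                frame_to_records(df.iloc[[i]])
            except (ValueError, KeyError) as exc:
                messages.append(f"line {i + 2}: {exc}")
    elif {"phase", "pulse_index", "conductance_uS"} <= cols:
        bad = df[~df["phase"].isin(["potentiation", "depression"])]
        for i in bad.index:
            messages.append(f"line {i + 2}: unknown phase {df.loc[i, 'phase']!r}")
        if df[["pulse_index", "conductance_uS"]].isna().any().any():
            messages.append("missing pulse_index/conductance values")
    elif {"step", "accuracy_pct"} <= cols:
        acc = df["accuracy_pct"].to_numpy(dtype=float)
        if df[["step", "accuracy_pct"]].isna().any().any():
            bad_line = int(df[df.isna().any(axis=1)].index[0]) + 2
            messages.append(f"line {bad_line}: missing step/accuracy value")
        elif np.any((acc < 0) | (acc > 100)):
            messages.append("accuracy values outside [0, 100]")
        elif np.any(np.diff(df["step"].to_numpy()) <= 0):
            messages.append("steps not strictly increasing")
    else:
        messages.append(f"unrecognized column set: {sorted(cols)}")


def _validate_json(path: Path, messages: list) -> None:
    d = json.loads(path.read_text())
    try:
        if {"g_min_uS", "g_max_uS", "p_max"} <= set(d):
            DeviceParams.from_json(path.read_text())
        elif {"channels", "odorants", "mean_gmax_uS"} <= set(d):
            AffinityProfile.from_json(path.read_text())
        elif {"n_regions", "boundaries_uS", "range_uS"} <= set(d):
            RegionScheme.from_json(path.read_text())
        elif "slope_uS_per_ppm" in d:
            from .synth import CalibrationCurve

            CalibrationCurve.from_json(path.read_text())
        # other JSON documents (configs, reports, states) are schema-free
    except (ValueError, KeyError) as exc:
        messages.append(str(exc))


def validate_files(paths) -> list:
    """Schema-check every supported artifact file.

    Returns one ``{"path", "ok", "messages"}`` dict per input; content
    errors are reported, never raised.
    """
    report = []
    for p in map(Path, paths):
        messages: list = []
        if not p.exists():
            messages.append("file does not exist")
        else:
            try:
                if p.suffix == ".jsonl":
                    _validate_patterns_jsonl(p, messages)
                elif p.suffix in (".tsv", ".txt"):
                    _validate_tsv(p, messages)
                elif p.suffix == ".json":
                    _validate_json(p, messages)
                else:
                    messages.append(f"unsupported file type {p.suffix!r}")
            except Exception as exc:  # truncated/corrupt files land here
                messages.append(f"unreadable: {exc}")
        report.append({"path": str(p), "ok": not messages, "messages": messages})
    return report
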