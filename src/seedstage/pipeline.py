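"""End-to-end runs: synthetic scene -> preprocessing -> classifier ->
smoothing -> per-pot event timings and metrics.

The biological deliverable is the kinetics table: for every pot, the first
frame (and wall-clock time) of emergence (Soil -> FA), cotyledon opening
(FA -> OC) and first-leaf appearance (OC -> FL).  A stage is annotated as a
*period*, so the event is the period start: the first frame at or after
which the smoothed, monotone label equals the stage.  Events whose frame is
the first frame of a photoperiod are flagged ``gap_adjacent`` — the true
transition may have happened overnight, when no frames exist.

Data splits follow the held-out-tray convention: train/validation/test sets
never share a tray, so no pot sequence leaks across splits.  Single-tray
parameter-recovery experiments use ``split="resubstitution"`` explicitly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import synthgen
from .errors import ConfigurationError, OntologyViolation
from .evalkit import confusion_matrix, summary_metrics
from .stagenet import (NetworkSpec, TrainingConfig, build_network,
                       chained_predict, predict_frames, train_model)
from .stages import STAGE_NAMES, StageLabel
from .temporal import SmoothingConfig, postprocess

__all__ = ["EventTiming", "RunConfig", "RunResult", "derive_event_times",
           "run_pipeline", "ARCHITECTURES"]

log = logging.getLogger("seedstage")

ARCHITECTURES = ("cnn", "cnn2class", "cnnlstm", "convlstm")
_EVENTS = ("FA", "OC", "FL")


@dataclasses.dataclass
class EventTiming:
    """First frame / wall-clock time of each developmental event for one
    pot; ``None`` marks "not reached"."""

    pot: tuple[int, int, int]
    frames: dict[str, int | None]
    times: dict[str, _dt.datetime | None]
    gap_adjacent: dict[str, bool]


def derive_event_times(labels, config: synthgen.SceneConfig | None = None,
                       pot=(0, 0, 0)) -> EventTiming:
    """Event frames from a monotone label sequence.

    Raises ``OntologyViolation`` on a regressing sequence (post-process
    first).  With a ``SceneConfig``, wall-clock timestamps and night-gap
    flags are attached.
    """
    lab = np.asarray(labels, dtype=np.int64)
    if np.any(np.diff(lab) < 0):
        raise OntologyViolation(
            "label sequence regresses; apply temporal.postprocess before "
            "deriving event times")
    frames: dict[str, int | None] = {}
    times: dict[str, _dt.datetime | None] = {}
    gaps: dict[str, bool] = {}
    for name in _EVENTS:
        code = int(StageLabel[name])
        hit = np.nonzero(lab >= code)[0]
        f = int(hit[0]) if hit.size else None
        frames[name] = f
        times[name] = config.timestamp(f) if (config and f is not None) else None
        gaps[name] = bool(config and f is not None and f > 0
                          and f % config.frames_per_day == 0)
    return EventTiming(pot=tuple(pot), frames=frames, times=times,
                       gap_adjacent=gaps)


@dataclasses.dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    scene: synthgen.SceneConfig
    arch: str = "cnnlstm"
    preset: str = "small"               # "small" | "baseline"
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    smoothing: SmoothingConfig = dataclasses.field(default_factory=SmoothingConfig)
    split: str = "by_tray"              # "by_tray" | "resubstitution"
    test_trays: tuple[int, ...] | None = None
    remove_background: bool = True
    germination_prob: float = 0.9
    delay_params: dict | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.arch!r}; choose from "
                f"{ARCHITECTURES}")
        if self.preset not in ("small", "baseline"):
            raise ConfigurationError("preset must be 'small' or 'baseline'")
        if self.split not in ("by_tray", "resubstitution"):
            raise ConfigurationError("split must be 'by_tray' or 'resubstitution'")
        if self.split == "by_tray" and self.scene.n_trays < 2:
            raise ConfigurationError(
                "by_tray split needs >= 2 trays; use split='resubstitution' "
                "for single-tray parameter-recovery runs")
        if self.preset == "baseline" and self.scene.pot_size_px != 89:
            raise ConfigurationError(
                "the baseline preset expects 89x89 pot crops")

    def network_spec(self, temporal: str, n_classes: int = 4,
                     class_pair=None) -> NetworkSpec:
        if self.preset == "baseline":
            return NetworkSpec.baseline(temporal=temporal,
                                        n_classes=n_classes,
                                        class_pair=class_pair)
        return NetworkSpec.small(temporal=temporal, n_classes=n_classes,
                                 class_pair=class_pair,
                                 input_size=self.scene.pot_size_px)

    def dataset_summary(self) -> dict[str, int]:
        s = self.scene
        pots = s.grid_rows * s.grid_cols
        return {"n_trays": s.n_trays, "pots_per_tray": pots,
                "n_sequences": s.n_trays * pots,
                "total_images": s.n_trays * pots * s.frames_total}


@dataclasses.dataclass
class RunResult:
    config: RunConfig
    timings: pd.DataFrame
    metrics_raw: "object"
    metrics_post: "object"
    event_abs_errors: np.ndarray       # per recovered event, |pred - true| frames
    traces: list
    smoothed: list
    models: list
    split_manifest: dict[str, list]

    @property
    def event_mae(self) -> float:
        """Median absolute event-frame error over all recovered events."""
        return float(np.median(self.event_abs_errors)) \
            if self.event_abs_errors.size else float("nan")


def _preprocess_tray(config: synthgen.SceneConfig,
                     schedule: synthgen.StageSchedule, tray: int,
                     remove_bg: bool) -> np.ndarray:
    """Render, rectify and crop one tray; returns (rows, cols, T, s, s, 3)."""
    s = config.pot_size_px
    gh, gw = config.grid_shape_px
    out = np.empty((config.grid_rows, config.grid_cols, config.frames_total,
                    s, s, 3), dtype=np.uint8)
    landmarks = angle = None
    for f in range(config.frames_total):
        frame = synthgen.render_tray_frame(config, schedule, f, tray)
        if landmarks is None:
            # landmarks and tray pose are static; estimate on the first frame
            landmarks = pp.detect_landmarks(frame)
            try:
                angle = pp.estimate_tray_orientation(frame)
            except pp.OrientationUndefined:
                angle = 0.0
        rect = pp.rectify_tray(frame, landmarks, angle, (gh, gw))
        for crop in pp.extract_pots(rect, config.grid_rows, config.grid_cols, s):
            px = crop["pixels"]
            if remove_bg:
                px = pp.remove_background(px)
            out[crop["row"], crop["col"], f] = px
    return out


def _train_architecture(cfg: RunConfig, x_train: np.ndarray,
                        y_train: np.ndarray) -> list:
    """x_train: (n_seq, T, s, s, 3); returns the trained model(s)."""
    temporal = {"cnn": "none", "cnn2class": "none", "cnnlstm": "lstm",
                "convlstm": "convlstm"}[cfg.arch]
    if cfg.arch == "cnn2class":
        frames = x_train.reshape((-1,) + x_train.shape[2:])
        labels = y_train.reshape(-1)
        models = []
        for pair in ((0, 1), (1, 2), (2, 3)):
            spec = cfg.network_spec("none", n_classes=2, class_pair=pair)
            model = build_network(spec, seed=cfg.training.seed)
            sel = np.isin(labels, pair)
            xb, yb = frames[sel], (labels[sel] == pair[1]).astype(np.int64)
            train_model(model, xb, yb, cfg.training)
            models.append(model)
        return models
    spec = cfg.network_spec(temporal)
    model = build_network(spec, seed=cfg.training.seed)
    if temporal == "none":
        train_model(model, x_train.reshape((-1,) + x_train.shape[2:]),
                    y_train.reshape(-1), cfg.training)
    else:
        train_model(model, x_train, y_train, cfg.training)
    return [model]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and return (and optionally write) the run
    artifacts: models, per-pot traces, event timings, metrics."""
    scene = config.scene
    log.info("run: arch=%s preset=%s seed=%d summary=%s", config.arch,
             config.preset, config.seed, config.dataset_summary())
    schedule = synthgen.sample_stage_schedule(scene, config.germination_prob,
                                              config.delay_params)
    truth_all = schedule.label_array(scene.frames_total)

    if config.split == "by_tray":
        test_trays = (list(config.test_trays) if config.test_trays is not None
                      else [scene.n_trays - 1])
        train_trays = [t for t in range(scene.n_trays) if t not in test_trays]
        if not train_trays:
            raise ConfigurationError("no trays left for training")
    else:
        train_trays = test_trays = list(range(scene.n_trays))

    pots_per_tray = scene.grid_rows * scene.grid_cols
    crops: dict[int, np.ndarray] = {}
    for tray in sorted(set(train_trays) | set(test_trays)):
        log.info("preprocessing tray %d", tray)
        crops[tray] = _preprocess_tray(scene, schedule, tray,
                                       config.remove_background)

    def stack(trays):
        xs = [crops[t].reshape((pots_per_tray, scene.frames_total)
                               + crops[t].shape[3:]) for t in trays]
        ys = [truth_all[t].reshape(pots_per_tray, scene.frames_total)
              for t in trays]
        return np.concatenate(xs), np.concatenate(ys)

    x_train, y_train = stack(train_trays)
    models = _train_architecture(config, x_train, y_train)

    traces, smoothed, timings_rows = [], [], []
    abs_errors = []
    for tray in test_trays:
        for r in range(scene.grid_rows):
            for c in range(scene.grid_cols):
                seq = crops[tray][r, c]
                if config.arch == "cnn2class":
                    tr = chained_predict(*models, seq, pot=(tray, r, c))
                else:
                    tr = predict_frames(models[0], seq, pot=(tray, r, c))
                sm = postprocess(tr, config.smoothing)
                traces.append(tr)
                smoothed.append(sm)
                ev = derive_event_times(sm.labels, scene, pot=(tray, r, c))
                row = {"tray": tray, "row": r, "col": c}
                for name in _EVENTS:
                    f = ev.frames[name]
                    row[f"frame_{name}"] = f
                    row[f"time_{name}"] = (ev.times[name].isoformat()
                                           if ev.times[name] else None)
                    row[f"gap_adjacent_{name}"] = ev.gap_adjacent[name]
                    t_true = {"FA": schedule.t_fa, "OC": schedule.t_oc,
                              "FL": schedule.t_fl}[name][tray, r, c]
                    # a stage observed in truth but never predicted counts
                    # as an error out to the recording horizon
                    observed = 0 <= t_true < scene.frames_total
                    if observed:
                        f_eff = f if f is not None else scene.frames_total
                        abs_errors.append(abs(f_eff - int(t_true)))
                timings_rows.append(row)

    timings = pd.DataFrame(timings_rows)
    y_test = np.concatenate(
        [truth_all[t].reshape(-1) for t in test_trays])
    pred_raw = np.concatenate([tr.labels for tr in traces])
    pred_post = np.concatenate([sm.labels for sm in smoothed])
    metrics_raw = summary_metrics(confusion_matrix(y_test, pred_raw))
    metrics_post = summary_metrics(confusion_matrix(y_test, pred_post))

    manifest = {"train": [(t, r, c) for t in train_trays
                          for r in range(scene.grid_rows)
                          for c in range(scene.grid_cols)],
                "test": [(t, r, c) for t in test_trays
                         for r in range(scene.grid_rows)
                         for c in range(scene.grid_cols)]}
    if config.split == "by_tray":
        assert not set(manifest["train"]) & set(manifest["test"])

    result = RunResult(config=config, timings=timings,
                       metrics_raw=metrics_raw, metrics_post=metrics_post,
                       event_abs_errors=np.asarray(abs_errors, dtype=float),
                       traces=traces, smoothed=smoothed, models=models,
                       split_manifest=manifest)
    if config.out_dir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: RunResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.timings.to_csv(out / "timings.csv", index=False)
    result.metrics_post.to_json(out / "metrics.json")
    (out / "trace").mkdir(exist_ok=True)
    for tr, sm in zip(result.traces, result.smoothed):
        t, r, c = tr.pot
        df = tr.to_frame()
        df["label_smoothed"] = sm.labels
        df.to_csv(out / "trace" / f"tray{t}_pot{r}_{c}.csv", index=False)
    for i, model in enumerate(result.models):
        model.save(out / (f"model{i}.ckpt.npz" if len(result.models) > 1
                          else "model.ckpt.npz"))
    cfg = dataclasses.asdict(result.config)
    cfg["event_mae_frames"] = result.event_mae
    with open(out / "run.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
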