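"""End-to-end pipeline: recognize -> lifelog -> cluster -> suggest.

Ties the stages together over the plain-text interchange formats
(sensor CSV, food-log CSV, manual-entry CSV, profile JSON) and persists
every stage's output. All randomness flows from one root seed, split per
stage, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity_recognition import GmmClassifier, extract_features
from .behavior_clustering import (
    BehaviorCluster,
    CanonicalTrajectory,
    cluster_lifelog,
)
from .energy import FoodTable, MetTable
from .lifelog import (
    FoodLogEntry,
    LifeEvent,
    ManualEntry,
    aggregate_minute,
    assemble_lifelog,
    build_mixed_events,
    merge_contiguous,
    write_jsonl,
)
from .suggestion_engine import (
    EngineConfig,
    avoid_food_suggestions,
    draw_generic_suggestions,
    generate_daily_batch,
    load_generic_pool,
)
from .synthetic_data import labeled_feature_set

logger = logging.getLogger(__name__)

RECOG_WINDOW_S = 60  # classify one-minute windows of the 1 Hz stream
TRACE_STRIDE_S = 15  # GPS samples attached to events


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sensors_path: Path
    food_path: Path
    manual_path: Path
    profile_path: Path
    out_dir: Path
    seed: int = 0
    engine: EngineConfig = field(default_factory=EngineConfig)
    met_table_path: Path | None = None
    food_table_path: Path | None = None

    def tables(self) -> tuple[MetTable, FoodTable]:
        met = MetTable.from_csv(self.met_table_path) if self.met_table_path else MetTable.default()
        food = (
            FoodTable.from_csv(self.food_table_path)
            if self.food_table_path
            else FoodTable.default()
        )
        return met, food


def validate_inputs(paths: dict[str, Path]) -> list[dict]:
    """Schema-check the CSV inputs; reports violations, never throws."""
    violations: list[dict] = []

    def flag(name, row, msg):
        violations.append(dict(file=str(name), row=row, message=msg))

    schemas = {
        "sensors": ["timestamp", "ax", "ay", "az", "lat", "lon"],
        "food": ["timestamp", "food_id", "quantity"],
        "manual": ["start", "end", "activity_name"],
    }
    for key, cols in schemas.items():
        path = paths.get(key)
        if path is None:
            continue
        if not Path(path).exists():
            flag(path, -1, "file does not exist")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            flag(path, -1, f"unreadable: {exc}")
            continue
        missing = [c for c in cols if c not in df.columns]
        if missing:
            flag(path, 0, f"missing columns: {missing}")
            continue
        tcol = "timestamp" if "timestamp" in cols else "start"
        ts = pd.to_datetime(df[tcol], errors="coerce")
        for i in np.flatnonzero(ts.isna().to_numpy()):
            flag(path, int(i) + 1, f"unparseable {tcol}")
        good = ts.dropna()
        if key == "sensors" and len(good) > 1:
            non_mono = np.flatnonzero(np.diff(good.to_numpy()) < np.timedelta64(0))
            for i in non_mono[:20]:
                flag(path, int(i) + 2, "non-monotone timestamp")
        if "lat" in df.columns:
            bad_lat = np.flatnonzero(~df["lat"].between(-90, 90).to_numpy())
            for i in bad_lat[:20]:
                flag(path, int(i) + 1, "latitude outside WGS84 range")
            bad_lon = np.flatnonzero(~df["lon"].between(-180, 180).to_numpy())
            for i in bad_lon[:20]:
                flag(path, int(i) + 1, "longitude outside WGS84 range")
    return violations


def train_default_classifier(seed: int) -> GmmClassifier:
    """Classifier trained on the 4-class surrogate accelerometer model."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
    X, y = labeled_feature_set(rng, n_per_class=60)
    return GmmClassifier(n_components=2, seed=seed & 0x7FFFFFFF).fit(X, y)


def recognize_stream(sensor: pd.DataFrame, clf: GmmClassifier) -> list[str]:
    """Per-second labels for a 1 Hz stream.

    One-minute windows are classified and the window label is broadcast to
    its seconds (the per-second cadence of the label stream is preserved;
    a trailing partial window inherits the last full window's label).
    """
    acc = sensor[["ax", "ay", "az"]].to_numpy()
    n = len(acc)
    n_win = n // RECOG_WINDOW_S
    if n_win == 0:
        raise PipelineError("recognize", "stream shorter than one window")
    feats = np.empty((n_win, 12))
    for i in range(n_win):
        w = acc[i * RECOG_WINDOW_S : (i + 1) * RECOG_WINDOW_S]
        feats[i] = extract_features(w, 1.0).values
    win_labels = clf.classify(feats)
    labels = np.repeat(win_labels, RECOG_WINDOW_S)
    if n > len(labels):
        labels = np.concatenate([labels, np.repeat(win_labels[-1], n - len(labels))])
    return labels[:n].tolist()


def attach_traces(events: list[LifeEvent], sensor: pd.DataFrame) -> list[LifeEvent]:
    """Attach downsampled GPS traces from the stream to activity events."""
    from dataclasses import replace

    ts = sensor["timestamp"].to_numpy()
    lat = sensor["lat"].to_numpy()
    lon = sensor["lon"].to_numpy()
    out = []
    for ev in events:
        if ev.kind in ("activity", "mixed"):
            i0, i1 = np.searchsorted(ts, np.datetime64(ev.start)), np.searchsorted(
                ts, np.datetime64(ev.end)
            )
            sl = slice(i0, i1, TRACE_STRIDE_S)
            trace = np.column_stack([lat[sl], lon[sl]])
            out.append(replace(ev, trace=trace if len(trace) else None))
        else:
            out.append(ev)
    return out


def load_inputs(cfg: PipelineConfig):
    for name, p in (
        ("sensors", cfg.sensors_path),
        ("food log", cfg.food_path),
        ("manual entries", cfg.manual_path),
        ("profile", cfg.profile_path),
    ):
        if not Path(p).exists():
            raise PipelineError("inputs", f"missing {name} file: {p}")
    if cfg.food_table_path and not Path(cfg.food_table_path).exists():
        raise PipelineError("inputs", f"missing food table: {cfg.food_table_path}")
    if cfg.met_table_path and not Path(cfg.met_table_path).exists():
        raise PipelineError("inputs", f"missing MET table: {cfg.met_table_path}")
    sensor = pd.read_csv(cfg.sensors_path, parse_dates=["timestamp"])
    food = pd.read_csv(cfg.food_path, parse_dates=["timestamp"])
    manual = pd.read_csv(cfg.manual_path, parse_dates=["start", "end"])
    profile = json.loads(Path(cfg.profile_path).read_text())
    return sensor, food, manual, profile


def cluster_to_json(c: BehaviorCluster) -> dict:
    rep = c.representative
    if isinstance(rep, CanonicalTrajectory):
        rep = {"trajectory": rep.points.round(6).tolist(), "length_m": round(rep.length_m, 1)}
    elif isinstance(rep, tuple):
        rep = {"point": [round(rep[0], 6), round(rep[1], 6)]}
    return dict(
        cluster_id=c.cluster_id,
        cluster_type=c.cluster_type,
        label=c.label,
        member_event_ids=c.member_event_ids,
        frequency=c.frequency,
        representative=rep,
        per_instance_calories=round(c.per_instance_calories, 2),
        per_instance_duration=round(c.per_instance_duration, 2),
        meta=c.meta,
    )


def cluster_from_json(d: dict) -> BehaviorCluster:
    rep = d["representative"]
    if isinstance(rep, dict) and "trajectory" in rep:
        pts = np.asarray(rep["trajectory"], dtype=float)
        rep = CanonicalTrajectory(points=pts, length_m=float(rep["length_m"]))
    elif isinstance(rep, dict) and "point" in rep:
        rep = tuple(rep["point"])
    return BehaviorCluster(
        cluster_id=d["cluster_id"],
        cluster_type=d["cluster_type"],
        member_event_ids=d["member_event_ids"],
        frequency=d["frequency"],
        representative=rep,
        per_instance_calories=d["per_instance_calories"],
        per_instance_duration=d["per_instance_duration"],
        label=d.get("label", ""),
        meta=d.get("meta", {}),
    )


def suggestions_json(batch, date, category) -> dict:
    return dict(
        date=str(date),
        category=category,
        suggestions=[
            dict(
                rank=s.rank,
                arm=s.arm,
                cluster_id=s.target_cluster_id,
                projected_weekly_kcal=round(s.projected_weekly_kcal, 2),
                text=s.text,
            )
            for s in batch
        ],
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and persist outputs under ``cfg.out_dir``.

    Returns a summary dict with per-stage counts and timings.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, p in (("food table", cfg.food_table_path), ("MET table", cfg.met_table_path)):
        if p is not None and not Path(p).exists():
            raise PipelineError("inputs", f"missing {name}: {p}")
    met_table, food_table = cfg.tables()
    summary: dict = {"stages": {}}

    def timed(stage):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                res = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            dt = time.perf_counter() - t0
            summary["stages"][stage] = {"seconds": round(dt, 3)}
            logger.info("stage %s done in %.2fs", stage, dt)
            return res

        return wrap

    sensor, food_df, manual_df, profile = timed("inputs")(lambda: load_inputs(cfg))
    weight = float(profile["weight_kg"])
    goal = profile.get("goal", "maintain")

    clf = timed("train")(lambda: train_default_classifier(cfg.seed))
    labels = timed("recognize")(lambda: recognize_stream(sensor, clf))
    summary["stages"]["recognize"]["seconds_labeled"] = len(labels)

    def build_log():
        minute = aggregate_minute(labels)
        t0 = sensor["timestamp"].iloc[0]
        merged = merge_contiguous(minute, t0)
        mixed = build_mixed_events(merged)
        mixed = attach_traces(mixed, sensor)
        food_entries = [
            FoodLogEntry(timestamp=r.timestamp, food_id=r.food_id, quantity=float(r.quantity))
            for r in food_df.itertuples()
        ]
        manual_entries = [
            ManualEntry(start=r.start, end=r.end, activity_name=r.activity_name)
            for r in manual_df.itertuples()
        ]
        return assemble_lifelog(
            mixed, food_entries, manual_entries,
            weight_kg=weight, met_table=met_table, food_table=food_table,
        )

    lifelog = timed("lifelog")(build_log)
    write_jsonl(lifelog, out / "lifelog.jsonl")
    summary["stages"]["lifelog"]["events"] = len(lifelog)

    clusters = timed("cluster")(lambda: cluster_lifelog(lifelog, food_table))
    (out / "clusters.json").write_text(
        json.dumps([cluster_to_json(c) for c in clusters], indent=1)
    )
    summary["stages"]["cluster"]["clusters"] = len(clusters)

    def suggest_all():
        days = sorted({ev.start.normalize() for ev in lifelog})
        sugg_dir = out / "suggestions"
        sugg_dir.mkdir(exist_ok=True)
        n_batches = 0
        for di, day in enumerate(days):
            day_end = day + pd.Timedelta(days=1)
            visible = [ev for ev in lifelog if ev.start < day_end]
            day_clusters = cluster_lifelog(visible, food_table)
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 7001, di])
            )
            payload = {}
            for category in ("activity", "food"):
                batch = generate_daily_batch(
                    day_clusters, category,
                    weight_kg=weight, met_table=met_table, config=cfg.engine, rng=rng,
                )
                payload[category] = suggestions_json(batch, day.date(), category)
            payload["avoid"] = suggestions_json(
                avoid_food_suggestions(day_clusters, goal, cfg.engine), day.date(), "food-avoid"
            )
            (sugg_dir / f"{day.date()}.json").write_text(json.dumps(payload, indent=1))
            n_batches += 2
        return n_batches

    n_batches = timed("suggest")(suggest_all)
    summary["stages"]["suggest"]["batches"] = n_batches
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def control_suggestions(seed: int, n: int = 10) -> list[str]:
    """Control-arm daily suggestions: uniform draw from the generic pool."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 9001]))
    return draw_generic_suggestions(load_generic_pool(), n, rng)
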