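"""Seeded synthetic users, sensor streams, food logs and two-arm trials.

The generator emulates routine daily behavior with known ground truth so
every downstream stage — recognition, life-log aggregation, clustering,
suggestion generation, trial statistics — is testable without any real
deployment data. The day template is:

* stationary at home overnight and in the evening;
* a morning commute walk home -> office along a fixed per-user jittered
  polyline (and the reverse in the late afternoon), each leg occurring
  with probability ``routine_walks_per_week / 14`` per day;
* stationary at the office through the working day;
* an occasional evening gym visit, logged manually;
* three meals inside fixed windows (07-09, 12-14, 18-21 local) plus
  Poisson snacks, with lognormal calorie draws realized through the
  food-log ``quantity`` field.

GPS points are the true path plus isotropic Gaussian noise in the local
tangent plane. Accelerometer channels are class-separable surrogate
signals (alternating gait component plus autoregressive noise), not
realistic waveforms. An ``intervention_effect`` lengthens walks and
trims meal calories from the second week onward, giving trials a planted,
recoverable behavior change.

Each user draws from an independent random stream derived from
``(seed, user_id)``, so adding users to a scenario never perturbs the
data of existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import haversine_m, offset_latlon

SAMPLE_RATE_HZ = 1.0  # sensor stream rate
SECONDS_PER_DAY = 86400

#: (hour, jitter window) meal schedule inside the canonical meal windows
MEAL_SLOTS = (("breakfast", 7, 9), ("lunch", 12, 14), ("dinner", 18, 21))

#: ground-truth food groups: user-preferred items per meal slot / snacks.
FOOD_GROUPS = {
    "breakfast": ["F013", "F014", "F015", "F016"],
    "lunch": ["F005", "F006", "F007", "F017", "F019"],
    "dinner": ["F001", "F002", "F008", "F010", "F011", "F012", "F020"],
    "snack": ["F021", "F022", "F023", "F024", "F025", "F026", "F027", "F028"],
}

#: per-class accelerometer surrogate parameters:
#: (gait amplitude, white noise sd, AR(1) coefficient, AR noise sd)
ACCEL_MODEL = {
    "stationary": (0.0, 0.0, 0.95, 0.005),
    "walking": (0.15, 0.05, 0.0, 0.0),
    "running": (0.50, 0.10, 0.0, 0.0),
    "driving": (0.0, 0.0, 0.50, 0.05),
}
GRAVITY_G = 1.0

#: manual exercise types; each user favors one and samples the rest rarely
EXERCISE_TYPES = ("gym_workout", "cycling", "swimming", "strength_training", "yoga")


@dataclass(frozen=True)
class UserProfile:
    user_id: str
    weight_kg: float
    height_cm: float
    goal: str  # lose | maintain | gain
    home: tuple[float, float]  # lat, lon
    office: tuple[float, float]

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ValueError("weight must be strictly positive")
        if self.height_cm <= 0:
            raise ValueError("height must be strictly positive")
        if self.goal not in ("lose", "maintain", "gain"):
            raise ValueError(f"unknown goal {self.goal!r}")
        d = haversine_m(*self.home, *self.office)
        if d < 500.0:
            raise ValueError(f"home and office must be >= 500 m apart (got {d:.0f} m)")


@dataclass(frozen=True)
class ScenarioConfig:
    days: int = 21
    seed: int = 0
    routine_walks_per_week: float = 10.0  # commute legs (2/workday x ~5 days)
    gym_visits_per_week: float = 3.0  # exercise sessions across preferred types
    lunch_walks_per_week: float = 3.0  # short office-loop walks
    evening_walks_per_week: float = 1.5  # long scenic loop from home
    snacks_per_day: float = 1.5
    walk_minutes_mean: float = 30.0
    walk_minutes_sd: float = 5.0
    lunch_walk_minutes_mean: float = 14.0
    evening_walk_minutes_mean: float = 45.0
    gym_minutes_mean: float = 60.0
    gym_minutes_sd: float = 10.0
    meal_kcal_mean: float = 600.0
    meal_kcal_sd: float = 150.0
    snack_kcal_mean: float = 180.0
    snack_kcal_sd: float = 60.0
    gps_noise_sd: float = 20.0  # meters
    intervention_effect: float = 0.0  # applied to walks (+) and meal kcal (-) from week 2

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for name in ("routine_walks_per_week", "gym_visits_per_week", "snacks_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gps_noise_sd < 0:
            raise ValueError("gps_noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruthEvent:
    start: pd.Timestamp
    end: pd.Timestamp
    label: str  # stationary | walking | gym_workout | food
    trajectory_id: str | None = None  # e.g. "home->office"
    meal_cluster_id: str | None = None  # e.g. "lunch"
    food_id: str | None = None
    kcal: float | None = None

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def to_json(self) -> str:
        d = {"start": self.start.isoformat(), "end": self.end.isoformat(), "label": self.label}
        for k in ("trajectory_id", "meal_cluster_id", "food_id", "kcal"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return json.dumps(d)


@dataclass
class SimulatedUser:
    profile: UserProfile
    config: ScenarioConfig
    sensor: pd.DataFrame | None  # 1 Hz: timestamp, ax, ay, az, lat, lon
    food_log: pd.DataFrame  # timestamp, food_id, quantity
    manual_entries: pd.DataFrame  # start, end, activity_name
    ground_truth: list[GroundTruthEvent]


def user_rng(seed: int, user_id: str) -> np.random.Generator:
    """Independent, reproducible stream per (scenario seed, user)."""
    digest = hashlib.sha256(user_id.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws parameterized by target mean and sd."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def sample_accel_window(label: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """An (n, 3) surrogate accelerometer window for one activity class.

    Channels combine gravity on the z axis, a sign-alternating gait
    component (amplitude per class) and either white or AR(1) noise, so
    mean / variance / zero-crossing statistics separate the four classes.
    """
    amp, wn_sd, phi, ar_sd = ACCEL_MODEL[label]
    out = np.empty((n, 3))
    for axis in range(3):
        scale = 1.0 if axis == 2 else 0.6
        if amp > 0:
            gait = amp * scale * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
            x = gait + rng.normal(0.0, wn_sd, n)
        else:
            e = rng.normal(0.0, ar_sd * scale, n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = phi * x[t - 1] + e[t]
        out[:, axis] = x
    out[:, 2] += GRAVITY_G
    return out


def labeled_feature_set(
    rng: np.random.Generator,
    n_per_class: int = 50,
    window_samples: int = 60,
    sample_rate_hz: float = SAMPLE_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled feature vectors from the 4-class accelerometer model.

    The standard training/evaluation set for the activity classifier.
    """
    from .activity_recognition import extract_features

    X, y = [], []
    for label in ACCEL_MODEL:
        for _ in range(n_per_class):
            w = sample_accel_window(label, window_samples, rng)
            X.append(extract_features(w, sample_rate_hz).values)
            y.append(label)
    return np.array(X), np.array(y)


def _commute_polyline(profile: UserProfile, rng: np.random.Generator, n_way: int = 12) -> np.ndarray:
    """Fixed per-user jittered polyline home -> office (lat/lon)."""
    home = np.array(profile.home)
    office = np.array(profile.office)
    ts = np.linspace(0.0, 1.0, n_way)
    pts = home[None, :] * (1 - ts[:, None]) + office[None, :] * ts[:, None]
    # perpendicular jitter up to ~60 m, fixed for the user (same path daily)
    jit_n = rng.normal(0.0, 60.0, n_way)
    jit_e = rng.normal(0.0, 60.0, n_way)
    jit_n[[0, -1]] = 0.0
    jit_e[[0, -1]] = 0.0
    lat, lon = offset_latlon(float(home[0]), float(home[1]), jit_n, jit_e)
    dlat, dlon = lat - home[0], lon - home[1]
    return np.column_stack([pts[:, 0] + dlat, pts[:, 1] + dlon])


def _loop_polyline(
    anchor: tuple[float, float], rng: np.random.Generator, radius_m: float, n_way: int = 10
) -> np.ndarray:
    """Fixed closed loop starting and ending at the anchor point."""
    theta0 = rng.uniform(0.0, 2 * np.pi)
    angles = theta0 + np.linspace(0.0, 2 * np.pi, n_way)
    r = radius_m * (1.0 + rng.uniform(-0.2, 0.2, n_way))
    dn = r * np.cos(angles)
    de = r * np.sin(angles)
    dn[[0, -1]] = 0.0
    de[[0, -1]] = 0.0
    lat, lon = offset_latlon(anchor[0], anchor[1], dn, de)
    return np.column_stack([lat, lon])


def _user_paths(profile: UserProfile, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """The user's fixed trajectories, keyed by ground-truth trajectory id.

    Consumed from the user stream in a fixed order so daily behavior draws
    that follow are reproducible.
    """
    commute = _commute_polyline(profile, rng)
    office_loop = _loop_polyline(profile.office, rng, radius_m=250.0)
    home_loop = _loop_polyline(profile.home, rng, radius_m=500.0)
    return {
        "home->office": commute,
        "office->home": commute[::-1].copy(),
        "office-loop": office_loop,
        "home-loop": home_loop,
    }


def _favorite_exercise(rng: np.random.Generator) -> np.ndarray:
    """Per-user sampling weights over exercise types (one clear favorite)."""
    fav = rng.integers(len(EXERCISE_TYPES))
    w = np.full(len(EXERCISE_TYPES), 0.5 / (len(EXERCISE_TYPES) - 1))
    w[fav] = 0.5
    return w


def _walk_minutes(config: ScenarioConfig, rng: np.random.Generator, day: int) -> float:
    m = _lognormal(rng, config.walk_minutes_mean, config.walk_minutes_sd)
    if day >= 7:
        m *= 1.0 + config.intervention_effect
    return float(np.clip(m, 5.0, 120.0))


def _meal_kcal(config: ScenarioConfig, rng: np.random.Generator, day: int, snack: bool) -> float:
    mean = config.snack_kcal_mean if snack else config.meal_kcal_mean
    sd = config.snack_kcal_sd if snack else config.meal_kcal_sd
    k = _lognormal(rng, mean, sd)
    if day >= 7 and not snack:
        k *= 1.0 - config.intervention_effect
    return float(max(k, 30.0))


def _plan_day(
    profile: UserProfile,
    config: ScenarioConfig,
    rng: np.random.Generator,
    day: int,
    paths: dict[str, np.ndarray],
    exercise_weights: np.ndarray,
) -> tuple[list[dict], list[dict], list[dict]]:
    """Schedule one day: activity segments, food entries, manual entries.

    Segments are (start_s, end_s, label, extra) within the day; the day is
    then backfilled with stationary home/office so every second carries
    exactly one ground-truth label.
    """
    segments: list[dict] = []
    p_leg = min(config.routine_walks_per_week / 14.0, 1.0)
    out_leg = rng.random() < p_leg
    back_leg = rng.random() < p_leg

    if out_leg:
        dur = _walk_minutes(config, rng, day)
        start = int(rng.uniform(7.8, 8.3) * 3600)
        segments.append(
            dict(start=start, end=start + int(dur * 60), label="walking",
                 trajectory_id="home->office", path=paths["home->office"])
        )
    if back_leg:
        dur = _walk_minutes(config, rng, day)
        start = int(rng.uniform(16.8, 17.3) * 3600)
        segments.append(
            dict(start=start, end=start + int(dur * 60), label="walking",
                 trajectory_id="office->home", path=paths["office->home"])
        )
    if out_leg and rng.random() < min(config.lunch_walks_per_week / 7.0, 1.0):
        dur = float(np.clip(rng.normal(config.lunch_walk_minutes_mean, 2.0), 8.0, 14.9))
        start = int(rng.uniform(12.1, 13.2) * 3600)
        segments.append(
            dict(start=start, end=start + int(dur * 60), label="walking",
                 trajectory_id="office-loop", path=paths["office-loop"])
        )
    if rng.random() < min(config.evening_walks_per_week / 7.0, 1.0):
        dur = float(np.clip(rng.normal(config.evening_walk_minutes_mean, 8.0), 20.0, 90.0))
        start = int(rng.uniform(19.6, 20.4) * 3600)
        segments.append(
            dict(start=start, end=start + int(dur * 60), label="walking",
                 trajectory_id="home-loop", path=paths["home-loop"])
        )

    manual: list[dict] = []
    if rng.random() < min(config.gym_visits_per_week / 7.0, 1.0):
        name = EXERCISE_TYPES[int(rng.choice(len(EXERCISE_TYPES), p=exercise_weights))]
        dur = float(np.clip(rng.normal(config.gym_minutes_mean, config.gym_minutes_sd), 20, 120))
        start = int(rng.uniform(18.2, 19.0) * 3600)
        manual.append(dict(start=start, end=start + int(dur * 60), activity_name=name))
        segments.append(
            dict(start=start, end=start + int(dur * 60), label="running",
                 trajectory_id=None, path=None, manual=name)
        )

    food: list[dict] = []
    for slot, lo, hi in MEAL_SLOTS:
        t = int(rng.uniform(lo, hi) * 3600)
        fid = str(rng.choice(FOOD_GROUPS[slot]))
        food.append(dict(t=t, food_id=fid, kcal=_meal_kcal(config, rng, day, snack=False),
                         meal_cluster_id=slot))
    for _ in range(rng.poisson(config.snacks_per_day)):
        t = int(rng.uniform(9.5, 21.5) * 3600)
        fid = str(rng.choice(FOOD_GROUPS["snack"]))
        food.append(dict(t=t, food_id=fid, kcal=_meal_kcal(config, rng, day, snack=True),
                         meal_cluster_id="snack"))
    food.sort(key=lambda f: f["t"])
    return segments, food, manual


def _resolve_overlaps(segments: list[dict]) -> list[dict]:
    """Drop later-starting segments that overlap earlier ones (rare)."""
    segments.sort(key=lambda s: s["start"])
    out = []
    t = 0
    for s in segments:
        if s["start"] >= t:
            out.append(s)
            t = s["end"]
    return out


def simulate_user(
    profile: UserProfile,
    config: ScenarioConfig,
    include_sensors: bool = True,
) -> SimulatedUser:
    """Simulate one user's full scenario with ground truth.

    With ``include_sensors=False`` only the food log, manual entries and
    ground-truth events are produced (the event-level view used by trial
    simulations), skipping the 1 Hz stream synthesis.
    """
    rng = user_rng(config.seed, profile.user_id)
    paths = _user_paths(profile, rng)
    exercise_weights = _favorite_exercise(rng)
    t0 = pd.Timestamp("2024-01-01T00:00:00")

    all_truth: list[GroundTruthEvent] = []
    food_rows: list[dict] = []
    manual_rows: list[dict] = []
    sensor_frames: list[pd.DataFrame] = []
    from .energy import FoodTable

    food_table = FoodTable.default()

    for day in range(config.days):
        day0 = t0 + pd.Timedelta(days=day)
        segments, food, manual = _plan_day(profile, config, rng, day, paths, exercise_weights)
        segments = _resolve_overlaps(segments)

        # fill the day with stationary home/office around the scheduled bouts
        def site_at(sec: int) -> tuple[str, tuple[float, float]]:
            # office between the first and second commute leg when both exist
            walk_spans = [(s["start"], s["end"], s.get("trajectory_id")) for s in segments
                          if s["label"] == "walking"]
            at_office = False
            for st, en, tid in walk_spans:
                if sec >= en and tid == "home->office":
                    at_office = True
                if sec >= en and tid == "office->home":
                    at_office = False
            return ("office", profile.office) if at_office else ("home", profile.home)

        timeline: list[dict] = []
        cursor = 0
        for s in segments + [dict(start=SECONDS_PER_DAY, end=SECONDS_PER_DAY, label=None)]:
            if s["start"] > cursor:
                site, loc = site_at(cursor)
                timeline.append(dict(start=cursor, end=s["start"], label="stationary",
                                     site=site, loc=loc, path=None, trajectory_id=None))
            if s["label"] is not None:
                timeline.append(s)
            cursor = max(cursor, s["end"])

        day_truth: list[GroundTruthEvent] = []
        for seg in timeline:
            if seg.get("manual"):
                label = seg["manual"]
            else:
                label = seg["label"]
            day_truth.append(
                GroundTruthEvent(
                    start=day0 + pd.Timedelta(seconds=seg["start"]),
                    end=day0 + pd.Timedelta(seconds=seg["end"]),
                    label=label,
                    # for stationary events the "trajectory" slot records the site
                    trajectory_id=seg.get("trajectory_id") or seg.get("site"),
                )
            )
        for f in food:
            kcal = f["kcal"]
            unit = food_table[f["food_id"]].kcal_per_unit
            qty = kcal / unit
            ts = day0 + pd.Timedelta(seconds=f["t"])
            food_rows.append(dict(timestamp=ts, food_id=f["food_id"], quantity=qty))
            day_truth.append(
                GroundTruthEvent(
                    start=ts, end=ts + pd.Timedelta(minutes=1), label="food",
                    meal_cluster_id=f["meal_cluster_id"], food_id=f["food_id"], kcal=kcal,
                )
            )
        for m in manual:
            manual_rows.append(
                dict(start=day0 + pd.Timedelta(seconds=m["start"]),
                     end=day0 + pd.Timedelta(seconds=m["end"]),
                     activity_name=m["activity_name"])
            )
        all_truth.extend(sorted(day_truth, key=lambda e: e.start))

        if include_sensors:
            sensor_frames.append(
                _synthesize_day_stream(timeline, day0, profile, config, rng)
            )

    sensor = pd.concat(sensor_frames, ignore_index=True) if include_sensors else None
    food_log = pd.DataFrame(food_rows, columns=["timestamp", "food_id", "quantity"])
    manual_df = pd.DataFrame(manual_rows, columns=["start", "end", "activity_name"])
    return SimulatedUser(profile, config, sensor, food_log, manual_df, all_truth)


def _synthesize_day_stream(
    timeline: list[dict],
    day0: pd.Timestamp,
    profile: UserProfile,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = SECONDS_PER_DAY
    ax = np.empty(n)
    ay = np.empty(n)
    az = np.empty(n)
    lat = np.empty(n)
    lon = np.empty(n)
    for seg in timeline:
        s, e = seg["start"], seg["end"]
        m = e - s
        if m <= 0:
            continue
        acc = sample_accel_window(seg["label"], m, rng)
        ax[s:e], ay[s:e], az[s:e] = acc[:, 0], acc[:, 1], acc[:, 2]
        if seg.get("path") is not None:
            path = np.asarray(seg["path"], dtype=float)
            # constant-speed traversal of the polyline over the segment
            seg_len = haversine_m(path[:-1, 0], path[:-1, 1], path[1:, 0], path[1:, 1])
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            pos = np.linspace(0.0, cum[-1], m)
            lat[s:e] = np.interp(pos, cum, path[:, 0])
            lon[s:e] = np.interp(pos, cum, path[:, 1])
        else:
            loc = seg.get("loc", profile.home)
            lat[s:e] = loc[0]
            lon[s:e] = loc[1]
    if config.gps_noise_sd > 0:
        # isotropic tangent-plane noise centered on each true point
        from .geo import EARTH_RADIUS_M

        dn = rng.normal(0.0, config.gps_noise_sd, n)
        de = rng.normal(0.0, config.gps_noise_sd, n)
        lat = lat + np.degrees(dn / EARTH_RADIUS_M)
        lon = lon + np.degrees(de / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    ts = day0 + pd.to_timedelta(np.arange(n), unit="s")
    return pd.DataFrame({"timestamp": ts, "ax": ax, "ay": ay, "az": az, "lat": lat, "lon": lon})


@dataclass
class TrialUser:
    profile: UserProfile
    arm: str  # experimental | control
    data: SimulatedUser


@dataclass
class TrialData:
    users: list[TrialUser]
    config: ScenarioConfig

    def arms(self) -> dict[str, list[TrialUser]]:
        out: dict[str, list[TrialUser]] = {"experimental": [], "control": []}
        for u in self.users:
            out[u.arm].append(u)
        return out


def _random_profile(user_id: str, rng: np.random.Generator) -> UserProfile:
    base_lat = 42.44 + rng.uniform(-0.05, 0.05)
    base_lon = -76.50 + rng.uniform(-0.05, 0.05)
    # office 1.5-3 km from home in a random direction
    dist = rng.uniform(1500.0, 3000.0)
    theta = rng.uniform(0.0, 2 * np.pi)
    olat, olon = offset_latlon(base_lat, base_lon, dist * np.cos(theta), dist * np.sin(theta))
    return UserProfile(
        user_id=user_id,
        weight_kg=float(np.clip(rng.normal(75.0, 12.0), 50.0, 110.0)),
        height_cm=float(np.clip(rng.normal(170.0, 10.0), 150.0, 200.0)),
        goal="lose",
        home=(base_lat, base_lon),
        office=(float(olat), float(olon)),
    )


def simulate_trial(
    n_experimental: int,
    n_control: int,
    config: ScenarioConfig,
    include_sensors: bool = False,
) -> TrialData:
    """Two-arm trial: experimental users receive the intervention effect
    from week 2 onward; control users none. Arm assignment is recorded.

    Defaults mirror a small feasibility trial (9 vs 8 at the caller's
    choice); sensor streams are skipped by default because trial analysis
    consumes event-level data only.
    """
    if n_experimental < 1 or n_control < 1:
        raise ValueError("both arms need >= 1 user")
    users: list[TrialUser] = []
    for arm, n_arm, eff in (
        ("experimental", n_experimental, config.intervention_effect),
        ("control", n_control, 0.0),
    ):
        for i in range(n_arm):
            uid = f"{arm[:3]}_{i:02d}"
            prof = _random_profile(uid, user_rng(config.seed, uid + "/profile"))
            ucfg = replace(config, intervention_effect=eff)
            users.append(TrialUser(prof, arm, simulate_user(prof, ucfg, include_sensors)))
    return TrialData(users=users, config=config)


def metric_events(sim: SimulatedUser) -> pd.DataFrame:
    """Event table for trend analysis: day index, kind, value.

    Walks contribute duration in minutes; meals (not snacks) contribute
    kcal per item.
    """
    t0 = min(ev.start for ev in sim.ground_truth).normalize()
    rows = []
    for ev in sim.ground_truth:
        day = int((ev.start.normalize() - t0).days)
        if ev.label == "walking":
            rows.append(dict(day=day, kind="walk", value=ev.duration_minutes))
        elif ev.label == "food" and ev.meal_cluster_id != "snack":
            rows.append(dict(day=day, kind="meal", value=ev.kcal))
    return pd.DataFrame(rows, columns=["day", "kind", "value"])


def ground_truth_lifelog(sim: SimulatedUser, trace_points: int = 24):
    """Convert ground truth into life-log events with synthetic GPS traces.

    This is the oracle-side shortcut: it produces the life log the pipeline
    would ideally recover, with traces drawn fresh from the user's true
    commute polyline plus GPS noise (deterministic per user). Useful for
    exercising clustering and suggestion stages without sensor synthesis.
    """
    from .energy import FoodTable, MetTable, activity_kcal
    from .geo import EARTH_RADIUS_M
    from .lifelog import LifeEvent

    met = MetTable.default()
    food_table = FoodTable.default()
    rng = user_rng(sim.config.seed, sim.profile.user_id + "/truthtrace")
    path_rng = user_rng(sim.config.seed, sim.profile.user_id)
    paths = _user_paths(sim.profile, path_rng)

    def noisy(points: np.ndarray) -> np.ndarray:
        if sim.config.gps_noise_sd == 0:
            return points.copy()
        dn = rng.normal(0.0, sim.config.gps_noise_sd, len(points))
        de = rng.normal(0.0, sim.config.gps_noise_sd, len(points))
        lat = points[:, 0] + np.degrees(dn / EARTH_RADIUS_M)
        lon = points[:, 1] + np.degrees(
            de / (EARTH_RADIUS_M * np.cos(np.radians(points[:, 0])))
        )
        return np.column_stack([lat, lon])

    def densify(path: np.ndarray) -> np.ndarray:
        seg = haversine_m(path[:-1, 0], path[:-1, 1], path[1:, 0], path[1:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        ts = np.linspace(0.0, cum[-1], trace_points)
        return np.column_stack([np.interp(ts, cum, path[:, 0]), np.interp(ts, cum, path[:, 1])])

    dense = {tid: densify(p) for tid, p in paths.items()}

    events = []
    for ev in sim.ground_truth:
        if ev.label == "stationary":
            loc = sim.profile.office if ev.trajectory_id == "office" else sim.profile.home
            pts = noisy(np.tile(np.array(loc), (8, 1)))
            events.append(LifeEvent(ev.start, ev.end, "activity", "stationary",
                                    calories=activity_kcal("stationary", ev.duration_minutes,
                                                           sim.profile.weight_kg, met),
                                    trace=pts))
        elif ev.label == "walking":
            pts = dense[ev.trajectory_id]
            events.append(LifeEvent(ev.start, ev.end, "activity", "walking",
                                    calories=activity_kcal("walking", ev.duration_minutes,
                                                           sim.profile.weight_kg, met),
                                    trace=noisy(pts)))
        elif ev.label == "food":
            events.append(LifeEvent(ev.start, ev.end, "food", ev.food_id,
                                    calories=float(ev.kcal)))
        else:  # manual exercise (gym)
            events.append(LifeEvent(ev.start, ev.end, "manual_exercise", ev.label,
                                    calories=activity_kcal(ev.label, ev.duration_minutes,
                                                           sim.profile.weight_kg, met)))
    return events


def write_outputs(sim: SimulatedUser, out_dir) -> None:
    """Persist one simulated user as the plain-text interchange formats."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sim.sensor is not None:
        df = sim.sensor.copy()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(out / "sensors.csv", index=False, float_format="%.6f")
    fl = sim.food_log.copy()
    if len(fl):
        fl["timestamp"] = fl["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    fl.to_csv(out / "food_log.csv", index=False, float_format="%.4f")
    me = sim.manual_entries.copy()
    if len(me):
        me["start"] = me["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        me["end"] = me["end"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    me.to_csv(out / "manual.csv", index=False)
    with open(out / "ground_truth.jsonl", "w") as fh:
        for ev in sim.ground_truth:
            fh.write(ev.to_json() + "\n")
    with open(out / "profile.json", "w") as fh:
        json.dump(
            dict(user_id=sim.profile.user_id, weight_kg=sim.profile.weight_kg,
                 height_cm=sim.profile.height_cm, goal=sim.profile.goal,
                 home=list(sim.profile.home), office=list(sim.profile.office)),
            fh, indent=1,
        )
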