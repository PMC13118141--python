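"""Synthetic cohort generator for VPN flow-metadata studies.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without any participant data:

* low-level always-on background traffic (per-10-second-window Bernoulli
  emission with lognormal byte volumes) to shared OS/infrastructure
  domains — phones are never completely silent;
* app sessions (Poisson daily counts, bursty runs of 10-second windows)
  emitting to a mix of the app's unique domains and shared-infrastructure
  domains, with a higher upload share than background;
* person-specific diurnal structure: a sleep interval with day-to-day
  jitter, during which upload volume drops to a configurable fraction of
  the wake rate (default 10%), and an evening usage peak;
* two behavioral phenotypes — "routine" (small sleep jitter, near-zero
  night activity) and "fragmented" (large jitter, frequent night
  sessions);
* VPN off-gaps from reboots (lognormal reactivation delays: short gaps
  common, rare long lapses) and optional deliberate-off intervals;
* staggered onboarding across the cohort.

Every emitted flow lies inside a VPN-on interval, and all randomness flows
from a single seed (fixed seed → bit-identical output).  Ground truth
(sleep intervals, app sessions, off intervals, phenotype labels) is
returned alongside the log for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WINDOWS_PER_DAY = 8640  # 10-second windows
SECONDS_PER_WINDOW = 10


@dataclass(frozen=True)
class AppSpec:
    """One synthetic app: identity, domains, and traffic behavior.

    ``unique_domains`` are registered domains used by this app only;
    ``shared_domains`` come from a global infrastructure pool touched by
    several apps.  ``deep_domains`` are app-unique domains that surface
    only during prolonged naturalistic ("deep-state") use, never in brief
    scripted launches.
    """

    bundle_id: str
    name: str
    genre: str
    unique_domains: frozenset[str]
    shared_domains: frozenset[str]
    session_rate: float = 3.0  # expected sessions/day at mix weight 1/n_apps
    session_upload_scale: float = 50_000.0  # expected upload bytes per session
    deep_domains: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PhenotypeConfig:
    """Behavioral phenotype driving a participant's diurnal structure.

    Clock fields are minutes after local midnight.  ``routine`` phenotypes
    have small sleep jitter and near-zero night activity; ``fragmented``
    ones have large jitter and a substantial probability of night-time app
    sessions.
    """

    label: str
    sleep_onset_minute: float = 1410.0  # 23:30 (episodes cross midnight)
    sleep_duration_minutes: float = 480.0  # 8 h
    sleep_jitter_sd_minutes: float = 20.0
    night_activity_prob: float = 0.0
    wake_check_prob: float = 0.9  # morning phone-check burst at sleep offset
    daytime_amplitude: float = 1.0  # scales session intensity
    background_prob: float = 0.15  # P(emit) per 10-s window
    background_up_bytes: float = 120.0  # lognormal scale of upload volume
    background_down_bytes: float = 600.0
    sleep_upload_factor: float = 0.1  # sleep upload rate relative to wake
    app_mix: Mapping[str, float] | None = None  # bundle_id -> weight; None = uniform


ROUTINE = PhenotypeConfig(
    label="routine",
    sleep_jitter_sd_minutes=20.0,
    night_activity_prob=0.02,
    wake_check_prob=1.0,
)
FRAGMENTED = PhenotypeConfig(
    label="fragmented",
    sleep_onset_minute=120.0,
    sleep_duration_minutes=420.0,
    sleep_jitter_sd_minutes=150.0,
    night_activity_prob=0.35,
    wake_check_prob=0.5,
    daytime_amplitude=0.8,
)


@dataclass(frozen=True)
class DropoutModel:
    """VPN off-gap model: reboots with lognormal reactivation delays.

    ``reboot_prob_per_day`` is the chance of one reboot on a given day;
    the reactivation delay is lognormal with the given median (hours), so
    short gaps are common and multi-day lapses rare.  ``deliberate_off``
    lists forced off intervals as (day index, start hour, duration hours).
    """

    reboot_prob_per_day: float = 0.1
    reactivation_median_hours: float = 2.0
    reactivation_sigma: float = 1.0
    deliberate_off: tuple[tuple[int, float, float], ...] = ()


NO_DROPOUT = DropoutModel(reboot_prob_per_day=0.0)


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 24
    days: int = 14
    start_date: date = date(2024, 3, 4)  # a Monday
    stagger_max_days: int = 6
    tz_offset_minutes: int = -300
    dropout: DropoutModel = DropoutModel()
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-participant truth for parameter-recovery tests."""

    participant_id: str
    label: str
    start_day: date
    tz_offset_minutes: int
    sleep_intervals: list[tuple[pd.Timestamp, pd.Timestamp]]
    sessions: list[dict]  # {bundle_id, start, end, bytes_up}
    vpn_off_intervals: list[tuple[pd.Timestamp, pd.Timestamp]]


#: Shared infrastructure domains used by background traffic and several apps.
INFRA_POOL = (
    "cdnhub.example",
    "app-metrics.example",
    "adnet.example",
    "push-gateway.example",
    "telemetry-os.example",
    "cloudsync.example",
)

_SUBDOMAIN_PREFIXES = ("", "api.", "cdn.", "v2.edge.")


def default_apps() -> list[AppSpec]:
    """A small realistic app catalog spanning several genres.

    Most apps carry a name-matching unique domain (semantically
    identifiable); ``PhotoShare`` deliberately uses an opaque unique domain
    (never identifiable), and ``Quietly`` is identifiable only through a
    deep-state domain that scripted launches never surface.
    """
    mk = frozenset
    return [
        AppSpec("com.ex.chatterbox", "ChatterBox", "Social",
                mk({"chatterbox.example", "chatterbox-media.example"}),
                mk({"cdnhub.example", "app-metrics.example"}), 4.0, 40_000.0),
        AppSpec("com.ex.streamflix", "StreamFlix", "Entertainment",
                mk({"streamflix.example"}),
                mk({"cdnhub.example", "adnet.example"}), 3.0, 30_000.0),
        AppSpec("com.ex.snackdash", "SnackDash", "Food & Drink",
                mk({"snackdash.example"}),
                mk({"app-metrics.example", "adnet.example"}), 1.5, 25_000.0),
        AppSpec("com.ex.pixelraiders", "PixelRaiders", "Games",
                mk({"pixelraiders.example"}),
                mk({"adnet.example", "cdnhub.example"}), 2.5, 60_000.0),
        AppSpec("com.ex.maildesk", "MailDesk", "Business",
                mk({"maildesk.example"}),
                mk({"cloudsync.example", "cdnhub.example"}), 3.0, 35_000.0),
        AppSpec("com.ex.tunewave", "TuneWave", "Music",
                mk({"tunewave.example"}),
                mk({"cdnhub.example", "app-metrics.example"}), 2.0, 20_000.0),
        AppSpec("com.ex.photoshare", "PhotoShare", "Photo & Video",
                mk({"zz-img9.example"}),
                mk({"cdnhub.example", "adnet.example"}), 2.0, 45_000.0),
        AppSpec("com.ex.quietly", "Quietly", "Health & Fitness",
                mk({"qt-api7.example"}),
                mk({"telemetry-os.example", "app-metrics.example"}), 1.5, 15_000.0,
                deep_domains=mk({"quietly.example"})),
    ]


def _mix_weights(phenotype: PhenotypeConfig, apps: Sequence[AppSpec]) -> np.ndarray:
    if phenotype.app_mix is None:
        w = np.ones(len(apps))
    else:
        w = np.array([phenotype.app_mix.get(a.bundle_id, 0.0) for a in apps], dtype=float)
    if w.sum() <= 0:
        raise ValueError("app mix weights must sum to a positive value")
    return w / w.sum()


def _interval_mask(n_windows: int, intervals_min: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(n_windows, dtype=bool)
    for start_min, end_min in intervals_min:
        a = max(0, int(start_min * 6))
        b = min(n_windows, int(end_min * 6))
        if b > a:
            mask[a:b] = True
    return mask


def _to_timestamps(start_day: date, idx: np.ndarray, tz_offset_minutes: int) -> pd.DatetimeIndex:
    tz = timezone(timedelta(minutes=tz_offset_minutes))
    base = pd.Timestamp(datetime.combine(start_day, datetime.min.time()))
    return (base + pd.to_timedelta(idx * SECONDS_PER_WINDOW, unit="s")).tz_localize(tz)


def simulate_participant(
    participant_id: str,
    phenotype: PhenotypeConfig,
    days: int,
    apps: Sequence[AppSpec],
    seed: int,
    start_day: date = date(2024, 3, 4),
    tz_offset_minutes: int = -300,
    dropout: DropoutModel = NO_DROPOUT,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one participant's flow log and its ground truth.

    Returns a flow-log DataFrame in the canonical schema (timestamps carry
    the participant's fixed UTC offset) and a :class:`GroundTruth` with
    true sleep intervals, app sessions and VPN-off intervals.  Fully
    deterministic under the seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if not apps:
        raise ValueError("app set must be non-empty")
    rng = np.random.default_rng(seed)
    n_windows = days * WINDOWS_PER_DAY
    total_min = days * 1440.0
    tz = timezone(timedelta(minutes=tz_offset_minutes))

    # --- sleep intervals (minutes from local midnight of start_day) ---
    # day -1 included so episodes crossing midnight cover the first morning
    sleep_min: list[tuple[float, float]] = []
    for d in range(-1, days):
        onset = d * 1440 + phenotype.sleep_onset_minute + rng.normal(0, phenotype.sleep_jitter_sd_minutes)
        dur = max(120.0, phenotype.sleep_duration_minutes + rng.normal(0, phenotype.sleep_jitter_sd_minutes / 2))
        a, b = max(0.0, onset), min(total_min, onset + dur)
        if b > a:
            sleep_min.append((a, b))
    sleep_mask = _interval_mask(n_windows, sleep_min)

    # --- VPN off intervals: reboots + deliberate disabling ---
    off_min: list[tuple[float, float]] = []
    for d in range(days):
        if rng.random() < dropout.reboot_prob_per_day:
            start = d * 1440 + rng.uniform(0, 1440)
            delay_h = rng.lognormal(np.log(dropout.reactivation_median_hours), dropout.reactivation_sigma)
            off_min.append((start, min(total_min, start + delay_h * 60)))
    for d, start_hour, dur_h in dropout.deliberate_off:
        off_min.append((d * 1440 + start_hour * 60, min(total_min, d * 1440 + (start_hour + dur_h) * 60)))
    vpn_on = ~_interval_mask(n_windows, off_min)

    # --- background traffic: Bernoulli emission, lognormal volumes ---
    emit = (rng.random(n_windows) < phenotype.background_prob) & vpn_on
    bg_idx = np.flatnonzero(emit)
    k = bg_idx.size
    bg_up = rng.lognormal(np.log(phenotype.background_up_bytes), 0.8, size=k)
    bg_up = np.where(sleep_mask[bg_idx], bg_up * phenotype.sleep_upload_factor, bg_up)
    bg_down = rng.lognormal(np.log(phenotype.background_down_bytes), 1.0, size=k)
    hosts = [p + d for d in INFRA_POOL for p in _SUBDOMAIN_PREFIXES]
    bg_host_idx = rng.integers(0, len(hosts), size=k)

    idx_parts = [bg_idx]
    up_parts = [np.maximum(1, bg_up).astype(np.int64)]
    down_parts = [np.maximum(1, bg_down).astype(np.int64)]
    host_parts = [np.array(hosts, dtype=object)[bg_host_idx]]

    # --- app sessions ---
    weights = _mix_weights(phenotype, apps)
    total_rate = sum(a.session_rate for a in apps) * phenotype.daytime_amplitude
    wake_peak = 20 * 60  # evening usage bump (minutes)
    session_specs: list[tuple[int, float, float]] = []  # (app index, start min, duration min)

    def avoid_sleep(start: float, dur: float, d: int) -> float:
        """Shift a wake-time session start out of any overlapping sleep block."""
        for a, b in sleep_min:
            if start < b and a < start + dur:
                before = a - dur - 1.0
                start = before if before >= d * 1440 else b + rng.uniform(0, 10)
        return start

    for ai, (app, w) in enumerate(zip(apps, weights)):
        lam = total_rate * w * days
        for _ in range(rng.poisson(lam)):
            d = int(rng.integers(0, days))
            day_sleeps = [
                (a, b)
                for a, b in sleep_min
                if (d * 1440 <= a < (d + 1) * 1440) or (a < d * 1440 < b)
            ]
            dur = rng.uniform(2, 8)  # minutes
            if day_sleeps and rng.random() < phenotype.night_activity_prob:
                a, b = day_sleeps[int(rng.integers(0, len(day_sleeps)))]
                start = rng.uniform(max(a, d * 1440.0), min(b, (d + 1) * 1440.0))
            else:
                if rng.random() < 0.5:
                    start = d * 1440 + float(np.clip(rng.normal(wake_peak, 120), 0, 1439))
                else:
                    start = d * 1440 + rng.uniform(8 * 60, 23 * 60)
                start = avoid_sleep(start, dur, d)
            session_specs.append((ai, start, dur))

    # morning phone-in-bed burst right after each night's sleep offset
    for a, b in sleep_min:
        if 0 < b < total_min and rng.random() < phenotype.wake_check_prob:
            ai = int(rng.choice(len(apps), p=weights))
            session_specs.append((ai, b + rng.uniform(0, 10), rng.uniform(25, 45)))

    sessions: list[dict] = []
    for ai, start, dur in session_specs:
        if start >= total_min or start < 0:
            continue
        app = apps[ai]
        app_hosts = sorted(app.unique_domains) + sorted(app.shared_domains)
        n_unique = len(app.unique_domains)
        end = min(total_min, start + dur)
        w0, w1 = int(start * 6), max(int(start * 6) + 1, int(end * 6))
        widx = np.arange(w0, min(w1, n_windows))
        widx = widx[vpn_on[widx]]
        if widx.size == 0:
            continue
        per_win_up = rng.lognormal(np.log(app.session_upload_scale / max(1, widx.size)), 0.6, widx.size)
        per_win_down = per_win_up * rng.uniform(2, 6)
        unique_pick = rng.random(widx.size) < 0.5 if n_unique else np.zeros(widx.size, bool)
        h = np.where(
            unique_pick,
            [app_hosts[rng.integers(0, n_unique)] if n_unique else "" for _ in range(widx.size)],
            [app_hosts[rng.integers(n_unique, len(app_hosts))] for _ in range(widx.size)],
        )
        idx_parts.append(widx)
        up_parts.append(np.maximum(1, per_win_up).astype(np.int64))
        down_parts.append(np.maximum(1, per_win_down).astype(np.int64))
        host_parts.append(h.astype(object))
        t0 = _to_timestamps(start_day, np.array([w0]), tz_offset_minutes)[0]
        sessions.append(
            {
                "bundle_id": app.bundle_id,
                "start": t0,
                "end": t0 + pd.Timedelta(minutes=float(end - start)),
                "bytes_up": int(per_win_up.sum()),
            }
        )

    idx = np.concatenate(idx_parts)
    up = np.concatenate(up_parts)
    down = np.concatenate(down_parts)
    hostname = np.concatenate(host_parts)
    order = np.argsort(idx, kind="stable")
    idx, up, down, hostname = idx[order], up[order], down[order], hostname[order]

    frame = pd.DataFrame(
        {
            "participant_id": participant_id,
            "window_start": _to_timestamps(start_day, idx, tz_offset_minutes),
            "duration_s": SECONDS_PER_WINDOW,
            "hostname": hostname,
            "bytes_up": up,
            "bytes_down": down,
            "packets_up": np.maximum(1, up // 1400 + 1),
            "packets_down": np.maximum(1, down // 1400 + 1),
        }
    )

    def minutes_to_ts(pairs: list[tuple[float, float]]) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        base = pd.Timestamp(datetime.combine(start_day, datetime.min.time()), tz=tz)
        return [
            (base + pd.Timedelta(minutes=a), base + pd.Timedelta(minutes=b)) for a, b in pairs
        ]

    truth = GroundTruth(
        participant_id=participant_id,
        label=phenotype.label,
        start_day=start_day,
        tz_offset_minutes=tz_offset_minutes,
        sleep_intervals=minutes_to_ts(sleep_min),
        sessions=sessions,
        vpn_off_intervals=minutes_to_ts(sorted(off_min)),
    )
    return frame, truth


def _participant_ids(n: int, seed: int) -> list[str]:
    """Opaque, deterministic participant identifiers."""
    out = []
    for i in range(n):
        h = hashlib.sha1(f"{seed}:{i}".encode()).hexdigest()[:6]
        out.append(f"SP{h}")
    return out


def simulate_cohort(
    config: CohortConfig,
    phenotypes: Sequence[PhenotypeConfig] | None = None,
    apps: Sequence[AppSpec] | None = None,
) -> tuple[pd.DataFrame, dict[str, GroundTruth]]:
    """Simulate a cohort flow log with staggered onboarding.

    ``phenotypes`` are assigned round-robin (default: alternating routine
    and fragmented).  Returns the concatenated cohort log sorted by
    participant and time, and a manifest mapping opaque participant IDs to
    their :class:`GroundTruth`.
    """
    if config.n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    apps = list(apps) if apps is not None else default_apps()
    phenotypes = list(phenotypes) if phenotypes is not None else [ROUTINE, FRAGMENTED]
    rng = np.random.default_rng(config.seed)
    ids = _participant_ids(config.n_participants, config.seed)
    frames, truths = [], {}
    for i, pid in enumerate(ids):
        stagger = int(rng.integers(0, config.stagger_max_days + 1)) if config.stagger_max_days else 0
        seed_i = int(rng.integers(0, 2**31 - 1))
        frame, truth = simulate_participant(
            pid,
            phenotypes[i % len(phenotypes)],
            config.days,
            apps,
            seed=seed_i,
            start_day=config.start_date + timedelta(days=stagger),
            tz_offset_minutes=config.tz_offset_minutes,
            dropout=config.dropout,
        )
        frames.append(frame)
        truths[pid] = truth
    cohort = pd.concat(frames, ignore_index=True)
    cohort = cohort.sort_values(["participant_id", "window_start"], kind="stable").reset_index(drop=True)
    return cohort, truths


def emit_apr_reports(
    apps: Sequence[AppSpec],
    mode: str,
    seed: int = 0,
    shared_include_prob: float = 0.7,
    extra_infra: Sequence[str] = INFRA_POOL,
) -> list[dict]:
    """Emit APR-style JSON entries ({bundle_id, name, domains}) per app.

    ``scripted`` mode mimics brief controlled launches: every unique domain
    plus a random subset of the app's shared domains.  ``participant``
    (deep-state) mode mimics prolonged naturalistic use: unique domains,
    all shared domains, extra global infrastructure domains, and any
    deep-state-only unique domains — extra depth mostly surfaces shared
    infrastructure, rarely new app-identifying domains.
    """
    if mode not in ("participant", "scripted"):
        raise ValueError(f"mode must be 'participant' or 'scripted', got {mode!r}")
    rng = np.random.default_rng(seed)
    reports = []
    for app in apps:
        domains = set(app.unique_domains)
        if mode == "scripted":
            domains |= {d for d in sorted(app.shared_domains) if rng.random() < shared_include_prob}
        else:
            # deep use surfaces the full shared/OS infrastructure for every app,
            # so no infrastructure domain can masquerade as app-unique
            domains |= set(app.shared_domains)
            domains |= set(extra_infra)
            domains |= set(app.deep_domains)
        # raw hostnames occasionally carry subdomains, exercising normalization
        raw = {(("api." + d) if rng.random() < 0.3 else d) for d in domains}
        reports.append({"bundle_id": app.bundle_id, "name": app.name, "domains": sorted(raw)})
    return reports


def emit_category_map(apps: Sequence[AppSpec], path: str | Path | None = None) -> pd.DataFrame:
    """Emit the bundle_id → name → primary-genre map as a CSV-shaped frame."""
    ids = [a.bundle_id for a in apps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate bundle_id(s): {dupes}")
    frame = pd.DataFrame(
        {"bundle_id": ids, "name": [a.name for a in apps], "genre": [a.genre for a in apps]}
    )
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def write_ground_truth(truths: Mapping[str, GroundTruth], path: str | Path) -> None:
    """Serialize the ground-truth manifest to JSON."""
    def iso_pairs(pairs):
        return [[a.isoformat(), b.isoformat()] for a, b in pairs]

    payload = {
        pid: {
            "label": t.label,
            "start_day": t.start_day.isoformat(),
            "tz_offset_minutes": t.tz_offset_minutes,
            "sleep_intervals": iso_pairs(t.sleep_intervals),
            "vpn_off_intervals": iso_pairs(t.vpn_off_intervals),
            "sessions": [
                {
                    "bundle_id": s["bundle_id"],
                    "start": s["start"].isoformat(),
                    "end": s["end"].isoformat(),
                    "bytes_up": s["bytes_up"],
                }
                for s in t.sessions
            ],
        }
        for pid, t in truths.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
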