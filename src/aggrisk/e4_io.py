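"""Reading and writing Empatica E4-dialect session bundles and episode annotations.

A session bundle is a directory with one CSV per channel (``ACC.csv``,
``BVP.csv``, ``EDA.csv``) following the E4 export convention: the first row
holds the recording start time as a UNIX epoch (repeated per column for
multi-axis channels), the second row the sampling rate in Hz, and every
subsequent row one sample.  ACC samples are stored as integers in 1/64 g
units and converted to g on read.

All downstream time is session-relative seconds from the aligned session
start; per-channel sample ``i`` lives at time ``i / rate`` (0-based).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BEHAVIORS = ("SIB", "ED", "ATO")

#: canonical channel names -> (file name, default rate Hz, n axes)
CHANNEL_SPECS = {
    "acc": ("ACC.csv", 32.0, 3),
    "bvp": ("BVP.csv", 64.0, 1),
    "eda": ("EDA.csv", 4.0, 1),
}

_ACC_LSB_G = 1.0 / 64.0  # E4 stores acceleration in 1/64-g integer units

#: maximum tolerated start-time disagreement between channels, seconds
MAX_CHANNEL_SKEW_S = 1.0


class BundleError(ValueError):
    """Raised for malformed session bundles or annotation tables."""


@dataclass
class ChannelSeries:
    """One raw channel: name, absolute start epoch, rate and sample array.

    ``samples`` is shape ``(n,)`` for bvp/eda and ``(n, 3)`` for acc
    (units of g after read).
    """

    name: str
    start_epoch: float
    rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_SPECS:
            raise BundleError(f"unknown channel name {self.name!r}")
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise BundleError(f"{self.name}: non-positive sampling rate {self.rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] < 1:
            raise BundleError(f"{self.name}: empty channel")
        if self.name == "acc":
            if self.samples.ndim != 2 or self.samples.shape[1] != 3:
                raise BundleError("acc samples must be (n, 3)")
            if not np.all(np.isfinite(self.samples)):
                raise BundleError("acc samples must be finite")
        else:
            if self.samples.ndim != 1:
                raise BundleError(f"{self.name} samples must be 1-D")
        if self.name == "eda" and np.nanmin(self.samples) < 0:
            raise BundleError("eda (skin conductance) cannot be negative")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate

    def times(self) -> np.ndarray:
        """Session-relative sample times, seconds (0-based, i / rate)."""
        return np.arange(self.samples.shape[0]) / self.rate


@dataclass
class SessionRecording:
    """Three synchronized channels for one participant-session.

    Channels are trimmed to a common start (t = 0); ``duration_s`` is the
    minimum channel duration after trimming.
    """

    participant_id: str
    session_id: str
    channels: dict[str, ChannelSeries]

    def __post_init__(self) -> None:
        missing = set(CHANNEL_SPECS) - set(self.channels)
        if missing:
            raise BundleError(f"missing channel(s): {sorted(missing)}")
        starts = [c.start_epoch for c in self.channels.values()]
        if max(starts) - min(starts) > MAX_CHANNEL_SKEW_S:
            raise BundleError(
                f"channel start times differ by {max(starts) - min(starts):.2f} s "
                f"(> {MAX_CHANNEL_SKEW_S} s)"
            )
        if self.duration_s <= 0:
            raise BundleError("session has non-positive duration")

    @property
    def duration_s(self) -> float:
        return min(c.duration_s for c in self.channels.values())

    @property
    def acc(self) -> ChannelSeries:
        return self.channels["acc"]

    @property
    def bvp(self) -> ChannelSeries:
        return self.channels["bvp"]

    @property
    def eda(self) -> ChannelSeries:
        return self.channels["eda"]


@dataclass(frozen=True)
class EpisodeAnnotation:
    """One coded aggressive-behavior episode on a session timeline.

    ``behavior`` is one of SIB (self-injurious behavior), ED (emotion
    dysregulation) or ATO (aggression toward others); onset/offset are
    session-relative seconds.
    """

    participant_id: str
    session_id: str
    behavior: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise BundleError(f"unknown behavior code {self.behavior!r}")
        if not (0 <= self.onset_s < self.offset_s):
            raise BundleError(
                f"invalid episode interval [{self.onset_s}, {self.offset_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _read_channel_file(path: Path, name: str) -> ChannelSeries:
    n_axes = CHANNEL_SPECS[name][2]
    try:
        raw = pd.read_csv(path, header=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise BundleError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[0] < 3:
        raise BundleError(f"{path}: needs epoch row, rate row and >= 1 sample")
    if raw.shape[1] != n_axes:
        raise BundleError(
            f"{path}: expected {n_axes} column(s) for {name}, got {raw.shape[1]}"
        )
    if raw.isna().any().any():
        raise BundleError(f"{path}: ragged or non-numeric rows")
    start_epoch = float(raw.iloc[0, 0])
    rate = float(raw.iloc[1, 0])
    if rate <= 0:
        raise BundleError(f"{path}: non-positive rate {rate}")
    data = raw.iloc[2:].to_numpy(dtype=float)
    if name == "acc":
        samples = data * _ACC_LSB_G
    else:
        samples = data[:, 0]
    return ChannelSeries(name=name, start_epoch=start_epoch, rate=rate, samples=samples)


def read_session(
    bundle_path: str | Path, participant_id: str = "", session_id: str = ""
) -> SessionRecording:
    """Read a session bundle directory into a :class:`SessionRecording`.

    Channels are trimmed to their common overlapping interval (latest start,
    earliest end); start-time skew above :data:`MAX_CHANNEL_SKEW_S` is an
    error.  Defaults participant/session ids to the bundle directory name.
    """
    bundle = Path(bundle_path)
    if not bundle.is_dir():
        raise BundleError(f"bundle directory not found: {bundle}")
    channels: dict[str, ChannelSeries] = {}
    for name, (fname, _, _) in CHANNEL_SPECS.items():
        fpath = bundle / fname
        if not fpath.exists():
            raise BundleError(f"missing {name.upper()} channel file: {fpath}")
        channels[name] = _read_channel_file(fpath, name)

    starts = {n: c.start_epoch for n, c in channels.items()}
    ends = {n: c.start_epoch + c.duration_s for n, c in channels.items()}
    common_start = max(starts.values())
    common_end = min(ends.values())
    if max(starts.values()) - min(starts.values()) > MAX_CHANNEL_SKEW_S:
        raise BundleError(
            "channel start epochs differ by more than "
            f"{MAX_CHANNEL_SKEW_S} s: {starts}"
        )
    if common_end <= common_start:
        raise BundleError("channels have no overlapping interval")

    trimmed: dict[str, ChannelSeries] = {}
    for name, ch in channels.items():
        i0 = int(round((common_start - ch.start_epoch) * ch.rate))
        n_keep = int(math.floor((common_end - common_start) * ch.rate + 1e-9))
        n_keep = min(n_keep, ch.samples.shape[0] - i0)
        trimmed[name] = ChannelSeries(
            name=name,
            start_epoch=common_start,
            rate=ch.rate,
            samples=ch.samples[i0 : i0 + n_keep],
        )
    sid = session_id or bundle.name
    pid = participant_id or bundle.parent.name
    return SessionRecording(participant_id=pid, session_id=sid, channels=trimmed)


def write_session(rec: SessionRecording, bundle_path: str | Path) -> None:
    """Write ``rec`` as an E4-dialect bundle (inverse of :func:`read_session`).

    ACC is quantized to 1/64-g integers, so a round trip preserves ACC to
    half an LSB and BVP/EDA to float formatting precision.
    """
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)
    for name, (fname, _, n_axes) in CHANNEL_SPECS.items():
        ch = rec.channels[name]
        if name == "acc":
            body = np.round(ch.samples / _ACC_LSB_G).astype(int)
            fmt = "%d"
        else:
            body = ch.samples[:, None]
            fmt = "%.8g"
        header = np.vstack(
            [np.full(n_axes, ch.start_epoch), np.full(n_axes, ch.rate)]
        )
        with open(bundle / fname, "w") as fh:
            np.savetxt(fh, header, fmt="%.3f", delimiter=",")
            np.savetxt(fh, body, fmt=fmt, delimiter=",")


def _merge_overlapping(episodes: list[EpisodeAnnotation]) -> list[EpisodeAnnotation]:
    """Merge overlapping/touching same-behavior episodes within one session."""
    merged: list[EpisodeAnnotation] = []
    by_key: dict[tuple[str, str, str], list[EpisodeAnnotation]] = {}
    for ep in episodes:
        by_key.setdefault((ep.participant_id, ep.session_id, ep.behavior), []).append(ep)
    for key, eps in by_key.items():
        eps = sorted(eps, key=lambda e: e.onset_s)
        cur = eps[0]
        for nxt in eps[1:]:
            if nxt.onset_s <= cur.offset_s:
                logger.warning(
                    "merging overlapping %s episodes in %s/%s: "
                    "[%.2f, %.2f] + [%.2f, %.2f]",
                    key[2], key[0], key[1],
                    cur.onset_s, cur.offset_s, nxt.onset_s, nxt.offset_s,
                )
                cur = EpisodeAnnotation(
                    cur.participant_id, cur.session_id, cur.behavior,
                    cur.onset_s, max(cur.offset_s, nxt.offset_s),
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda e: (e.participant_id, e.session_id, e.onset_s, e.behavior))
    return merged


def read_annotations(path: str | Path) -> list[EpisodeAnnotation]:
    """Read an episode-annotation CSV (participant, session, behavior,
    onset_s, offset_s) into validated, merged, sorted annotations.

    Zero- or negative-length rows are dropped with a logged error; an
    unknown behavior code aborts the read.
    """
    df = pd.read_csv(path)
    required = {"participant", "session", "behavior", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise BundleError(
            f"annotation table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    episodes: list[EpisodeAnnotation] = []
    for row in df.itertuples(index=False):
        behavior = str(row.behavior)
        if behavior not in BEHAVIORS:
            raise BundleError(f"unknown behavior code {behavior!r} in {path}")
        onset, offset = float(row.onset_s), float(row.offset_s)
        if offset <= onset:
            logger.error(
                "rejecting zero/negative-length episode %s %s/%s [%s, %s]",
                behavior, row.participant, row.session, onset, offset,
            )
            continue
        episodes.append(
            EpisodeAnnotation(str(row.participant), str(row.session), behavior, onset, offset)
        )
    return _merge_overlapping(episodes)


def write_annotations(episodes: list[EpisodeAnnotation], path: str | Path) -> None:
    """Write annotations as the 5-column CSV read by :func:`read_annotations`."""
    df = pd.DataFrame(
        {
            "participant": [e.participant_id for e in episodes],
            "session": [e.session_id for e in episodes],
            "behavior": [e.behavior for e in episodes],
            "onset_s": [e.onset_s for e in episodes],
            "offset_s": [e.offset_s for e in episodes],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV (participant, session, bundle)."""
    df = pd.read_csv(path, dtype=str)
    required = {"participant", "session", "bundle"}
    if not required.issubset(df.columns):
        raise BundleError(f"manifest must have columns {sorted(required)}")
    return df


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


@dataclass
class Dataset:
    """A dataset root: manifest + annotations + loadable session bundles."""

    root: Path
    manifest: pd.DataFrame
    annotations: list[EpisodeAnnotation] = field(repr=False, default_factory=list)

    @classmethod
    def load(cls, root: str | Path) -> "Dataset":
        root = Path(root)
        manifest = read_manifest(root / "manifest.csv")
        ann_path = root / "annotations.csv"
        annotations = read_annotations(ann_path) if ann_path.exists() else []
        return cls(root=root, manifest=manifest, annotations=annotations)

    def sessions(self):
        """Yield (SessionRecording, list[EpisodeAnnotation]) per manifest row."""
        for row in self.manifest.itertuples(index=False):
            rec = read_session(
                self.root / row.bundle,
                participant_id=row.participant,
                session_id=row.session,
            )
            anns = [
                a
                for a in self.annotations
                if a.participant_id == row.participant and a.session_id == row.session
            ]
            yield rec, anns
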