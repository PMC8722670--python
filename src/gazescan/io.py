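"""Reading and validation of raw gaze exports and cohort manifests.

Raw eye-tracking exports are delimited text files with one gaze sample per
row: a timestamp in milliseconds and the point of gaze (POG) in screen
pixels, plus an optional validity column.  Screen-based remote trackers
report the POG with the origin at the bottom-left of the screen and y
growing upward; rasters use the opposite convention, and the single place
where the flip happens is :func:`gazescan.render.render_segment`.

A cohort manifest ties participants (group label, CARS severity score) to
the scanpath images rendered from their recordings.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ManifestError

#: CARS (Childhood Autism Rating Scale) bounds: the scale minimum is 15 and
#: scores above 30 indicate autism.
CARS_MIN = 15.0
CARS_AUTISM_CUTOFF = 30.0

#: Default screen of a 17-inch 1280x1024 monitor driven at 250 Hz.
DEFAULT_SCREEN = (1280, 1024)
DEFAULT_RATE_HZ = 250.0

#: Default column map for delimited gaze exports.
DEFAULT_COLUMN_MAP = {
    "t": "time_ms",
    "x": "x_px",
    "y": "y_px",
    "valid": "validity",
    "participant": "participant_id",
    "stimulus": "stimulus_id",
}

ASD = "ASD"
NON_ASD = "non-ASD"
GROUPS = (ASD, NON_ASD)


class GazeSample(NamedTuple):
    """One time-stamped point-of-gaze sample.

    ``t`` is in milliseconds, ``x``/``y`` in screen pixels (bottom-left
    origin), ``valid`` flags track quality: blinks, missing or out-of-range
    coordinates are retained as invalid samples rather than dropped so that
    downstream stroke drawing can break across them.
    """

    t: float
    x: float
    y: float
    valid: bool


@dataclass
class GazeRecording:
    """All samples of one participant x stimulus viewing.

    Samples are stored as parallel numpy arrays; timestamps are strictly
    increasing (enforced at construction).
    """

    participant_id: str
    stimulus_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    screen: tuple[int, int] = DEFAULT_SCREEN
    sampling_rate: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise DataError("sample arrays must have equal length")
        if n and (not np.all(np.isfinite(self.t)) or np.any(self.t < 0)):
            raise DataError("timestamps must be finite and non-negative")
        if n > 1:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise DataError(
                    f"timestamps not strictly increasing at row {bad[0] + 1} "
                    f"of recording {self.participant_id}/{self.stimulus_id}"
                )
        if self.screen[0] <= 0 or self.screen[1] <= 0:
            raise DataError("screen dimensions must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def nominal_dt_ms(self) -> float:
        """Nominal inter-sample interval, 1000 / sampling rate."""
        return 1000.0 / self.sampling_rate

    def samples(self) -> Iterator[GazeSample]:
        for i in range(len(self.t)):
            yield GazeSample(
                float(self.t[i]), float(self.x[i]), float(self.y[i]), bool(self.valid[i])
            )


@dataclass
class ParticipantRecord:
    """One participant: opaque ID, diagnostic group, optional CARS score."""

    participant_id: str
    group: str
    cars: float | None = None
    age_months: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ManifestError(
                f"unknown group {self.group!r} for participant {self.participant_id!r};"
                f" expected one of {GROUPS}"
            )
        if self.cars is not None:
            self.cars = float(self.cars)
            if math.isnan(self.cars):
                self.cars = None
            elif self.cars < CARS_MIN:
                raise ManifestError(
                    f"CARS score {self.cars} below scale minimum {CARS_MIN} "
                    f"for participant {self.participant_id!r}"
                )


class ImageEntry(NamedTuple):
    """One rendered scanpath image in the cohort inventory."""

    image: str
    participant_id: str
    stimulus_id: str
    segment: int


@dataclass
class CohortManifest:
    """Participants plus the inventory of their scanpath images."""

    participants: list[ParticipantRecord]
    images: list[ImageEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate participant_id(s): {dup}")
        self.images = [ImageEntry(*e) for e in self.images]
        known = set(ids)
        for e in self.images:
            if e.participant_id not in known:
                raise ManifestError(
                    f"image {e.image!r} references unknown participant "
                    f"{e.participant_id!r}"
                )

    def participant(self, participant_id: str) -> ParticipantRecord:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise ManifestError(f"unknown participant {participant_id!r}")

    def label(self, participant_id: str) -> int:
        """Binary class label: 1 for ASD, 0 for non-ASD."""
        return 1 if self.participant(participant_id).group == ASD else 0

    def images_of(self, participant_id: str) -> list[ImageEntry]:
        return [e for e in self.images if e.participant_id == participant_id]


def _coerce_valid(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None:
        return False
    s = str(value).strip().lower()
    if s in ("1", "true", "valid", "yes", "ok"):
        return True
    if s in ("0", "false", "invalid", "no", "blink", "lost", ""):
        return False
    try:
        return float(s) != 0.0
    except ValueError:
        return False


def read_gaze_records(
    path: str | Path,
    screen: tuple[int, int] = DEFAULT_SCREEN,
    column_map: dict | None = None,
    sampling_rate: float = DEFAULT_RATE_HZ,
    participant_id: str | None = None,
    stimulus_id: str | None = None,
    sep: str | None = None,
) -> list[GazeRecording]:
    """Parse a delimited gaze export into one recording per participant x stimulus.

    ``column_map`` names the timestamp / x / y columns (defaults:
    ``time_ms``, ``x_px``, ``y_px``) and, optionally, a ``valid`` column and
    the grouping columns ``participant`` / ``stimulus``.  Binocular exports
    may instead map ``x_left``/``y_left``/``x_right``/``y_right``; the two
    eyes are averaged when both are usable, otherwise the usable one is
    taken.

    Rows with track loss -- missing coordinates, coordinates outside the
    screen, or an explicit invalid marker -- become samples with
    ``valid=False``; they are never silently dropped.

    Raises
    ------
    FormatError
        If the file is empty or required columns are absent.
    DataError
        If timestamps are not strictly increasing within a recording.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"could not parse gaze export {path}: {exc}") from exc
    if df.empty or df.columns.size == 0:
        raise FormatError(f"gaze export {path} contains no samples")

    binocular = "x_left" in cmap and cmap["x_left"] in df.columns
    needed = [cmap["t"]]
    needed += (
        [cmap["x_left"], cmap["y_left"], cmap["x_right"], cmap["y_right"]]
        if binocular
        else [cmap["x"], cmap["y"]]
    )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"gaze export {path} lacks column(s) {missing}")

    w, h = screen

    def eye_ok(xs: pd.Series, ys: pd.Series) -> pd.Series:
        return xs.notna() & ys.notna() & (xs >= 0) & (xs <= w) & (ys >= 0) & (ys <= h)

    if binocular:
        xl = pd.to_numeric(df[cmap["x_left"]], errors="coerce")
        yl = pd.to_numeric(df[cmap["y_left"]], errors="coerce")
        xr = pd.to_numeric(df[cmap["x_right"]], errors="coerce")
        yr = pd.to_numeric(df[cmap["y_right"]], errors="coerce")
        okl, okr = eye_ok(xl, yl), eye_ok(xr, yr)
        x = np.where(okl & okr, (xl + xr) / 2, np.where(okl, xl, xr))
        y = np.where(okl & okr, (yl + yr) / 2, np.where(okl, yl, yr))
        coord_ok = (okl | okr).to_numpy()
    else:
        xs = pd.to_numeric(df[cmap["x"]], errors="coerce")
        ys = pd.to_numeric(df[cmap["y"]], errors="coerce")
        x, y = xs.to_numpy(float), ys.to_numpy(float)
        coord_ok = eye_ok(xs, ys).to_numpy()

    valid = coord_ok.copy()
    vcol = cmap.get("valid")
    if vcol and vcol in df.columns:
        valid &= df[vcol].map(_coerce_valid).to_numpy(bool)

    t = pd.to_numeric(df[cmap["t"]], errors="coerce").to_numpy(float)
    if np.isnan(t).any():
        row = int(np.nonzero(np.isnan(t))[0][0])
        raise FormatError(f"unparseable timestamp at row {row} of {path}")

    pcol, scol = cmap.get("participant"), cmap.get("stimulus")
    if pcol in df.columns or scol in df.columns:
        pids = df[pcol].astype(str) if pcol in df.columns else pd.Series(
            [participant_id or path.stem] * len(df)
        )
        sids = df[scol].astype(str) if scol in df.columns else pd.Series(
            ["stim0"] * len(df)
        )
        keys = pd.DataFrame({"p": pids.to_numpy(), "s": sids.to_numpy()})
        groups = keys.groupby(["p", "s"], sort=True).indices
        out = []
        for (pid, sid), idx in sorted(groups.items()):
            idx = np.sort(np.asarray(idx))
            out.append(
                GazeRecording(
                    str(pid), str(sid), t[idx], x[idx], y[idx], valid[idx],
                    screen=screen, sampling_rate=sampling_rate,
                )
            )
        return out
    pid = participant_id if participant_id is not None else path.stem
    sid = stimulus_id if stimulus_id is not None else "stim0"
    return [
        GazeRecording(pid, sid, t, x, y, valid, screen=screen, sampling_rate=sampling_rate)
    ]


def write_gaze_records(recordings: Sequence[GazeRecording], path: str | Path) -> Path:
    """Write recordings to one delimited text file in the default dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(
            ["participant_id", "stimulus_id", "time_ms", "x_px", "y_px", "validity"]
        )
        for rec in recordings:
            for s in rec.samples():
                wr.writerow(
                    [rec.participant_id, rec.stimulus_id,
                     f"{s.t:.6g}", f"{s.x:.4f}", f"{s.y:.4f}", int(s.valid)]
                )
    return path


def _manifest_from_dict(doc: dict) -> CohortManifest:
    try:
        participants = [
            ParticipantRecord(
                participant_id=str(p["participant_id"]),
                group=p["group"],
                cars=p.get("cars"),
                age_months=p.get("age_months"),
            )
            for p in doc["participants"]
        ]
        images = [
            ImageEntry(
                image=str(e["image"]),
                participant_id=str(e["participant_id"]),
                stimulus_id=str(e.get("stimulus_id", "")),
                segment=int(e.get("segment", 0)),
            )
            for e in doc.get("images", [])
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"manifest missing required field: {exc}") from exc
    return CohortManifest(participants=participants, images=images)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest from JSON (participants + images) or CSV
    (participant table only)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest {path} does not exist")
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"manifest {path} is not valid JSON: {exc}") from exc
        return _manifest_from_dict(doc)
    df = pd.read_csv(path)
    if "participant_id" not in df.columns or "group" not in df.columns:
        raise FormatError(
            f"manifest {path} needs 'participant_id' and 'group' columns"
        )
    participants = [
        ParticipantRecord(
            participant_id=str(r["participant_id"]),
            group=str(r["group"]),
            cars=r.get("cars") if "cars" in df.columns else None,
            age_months=int(r["age_months"])
            if "age_months" in df.columns and not pd.isna(r["age_months"])
            else None,
        )
        for _, r in df.iterrows()
    ]
    return CohortManifest(participants=participants)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Serialize a manifest to JSON; re-reading yields an identical manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "participants": [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "cars": p.cars,
                "age_months": p.age_months,
            }
            for p in manifest.participants
        ],
        "images": [
            {
                "image": e.image,
                "participant_id": e.participant_id,
                "stimulus_id": e.stimulus_id,
                "segment": e.segment,
            }
            for e in manifest.images
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def cohort_statistics(manifest: CohortManifest) -> dict:
    """Cohort bookkeeping: image counts and mean images per participant.

    Means are rounded to 2 decimals for reporting (e.g. 547 images over 59
    participants gives 9.27 images per child).
    """
    if not manifest.participants:
        raise ManifestError("cohort_statistics of an empty manifest")
    per_group_parts = {g: 0 for g in GROUPS}
    for p in manifest.participants:
        per_group_parts[p.group] += 1
    per_group_images = {g: 0 for g in GROUPS}
    for e in manifest.images:
        per_group_images[manifest.participant(e.participant_id).group] += 1
    n_img, n_part = len(manifest.images), len(manifest.participants)
    mean_per_group = {
        g: round(per_group_images[g] / per_group_parts[g], 2)
        if per_group_parts[g]
        else float("nan")
        for g in GROUPS
    }
    return {
        "n_images": n_img,
        "n_participants": n_part,
        "participants_per_group": per_group_parts,
        "images_per_group": per_group_images,
        "mean_images_per_participant": round(n_img / n_part, 2),
        "mean_images_per_group": mean_per_group,
    }
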