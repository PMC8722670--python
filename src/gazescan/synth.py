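"""Synthetic gaze recordings and cohorts.

The generator emulates screen-based remote eye tracking at 250 Hz on a
1280 x 1024 display: gaze alternates between jittered stationary
fixations (duration ~ normal, mean 300 ms -- within the 150-550 ms range
reported for naturalistic viewing) and constant-velocity straight-line
saccades (~60 ms, within the 30-120 ms range) toward uniformly drawn
on-screen targets.  Track loss (blinks) appears as contiguous bursts of
invalid samples.  The kinematics are deliberately simple -- no
physiological main-sequence velocity profile, no stimulus-driven gaze
placement -- but they reproduce the statistical structure the pipeline
consumes: alternating slow/fast movement, per-participant dynamics
scales, and a severity covariate linked monotonically to those scales.

Cohorts mirror the study composition this package targets: 29 ASD and 30
non-ASD participants, with the ASD profile showing a higher saccade rate
(shorter fixations) and larger saccade amplitudes, and CARS severity
scores that are an affine function of the log of each ASD participant's
individual velocity scale (clipped to the 30-45 band above the autism
cutoff) plus optional Gaussian noise.  Non-ASD participants sit at the
scale minimum, CARS = 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ConfigError
from .io import (
    ASD,
    DEFAULT_RATE_HZ,
    DEFAULT_SCREEN,
    NON_ASD,
    CohortManifest,
    GazeRecording,
    ParticipantRecord,
    write_gaze_records,
    write_manifest,
)

#: CARS band for synthetic ASD participants: above the autism cutoff (30),
#: capped at 45.
CARS_ASD_RANGE = (30.0, 45.0)
CARS_TD = 15.0


@dataclass
class GazeProfile:
    """Movement-dynamics parameters of one participant group.

    Durations in ms, amplitudes and jitter in px; ``fixation_jitter`` is
    the per-sample SD of within-fixation drift; ``dropout_rate`` the
    fraction of samples lost to blinks (placed in contiguous bursts).
    ``saccade_rate``, if set, overrides the mean fixation duration so the
    renewal process averages that many saccades per second.
    """

    fixation_duration_ms: tuple[float, float] = (300.0, 80.0)
    saccade_duration_ms: tuple[float, float] = (60.0, 15.0)
    saccade_amplitude_px: tuple[float, float] = (160.0, 60.0)
    fixation_jitter_px: float = 3.0
    dropout_rate: float = 0.05
    saccade_rate: float | None = None

    def __post_init__(self) -> None:
        for mean, sd in (
            self.fixation_duration_ms,
            self.saccade_duration_ms,
            self.saccade_amplitude_px,
        ):
            if mean <= 0 or sd < 0:
                raise ConfigError("profile means must be positive, SDs >= 0")
        if not 0.0 <= self.dropout_rate <= 0.3:
            raise ConfigError("dropout_rate must be in [0, 0.3]")
        if self.fixation_jitter_px < 0:
            raise ConfigError("fixation_jitter_px must be >= 0")

    def mean_fixation_ms(self) -> float:
        if self.saccade_rate is None:
            return self.fixation_duration_ms[0]
        period = 1000.0 / self.saccade_rate
        return max(period - self.saccade_duration_ms[0], 50.0)

    def scaled(self, velocity_scale: float) -> "GazeProfile":
        """Profile with all movement magnitudes multiplied by one factor.

        The scale acts on saccade amplitude and fixation jitter -- i.e. on
        every source of displacement -- so a participant's overall gaze
        speed is proportional to it.
        """
        amp_m, amp_s = self.saccade_amplitude_px
        return replace(
            self,
            saccade_amplitude_px=(amp_m * velocity_scale, amp_s * velocity_scale),
            fixation_jitter_px=self.fixation_jitter_px * velocity_scale,
        )


def td_profile() -> GazeProfile:
    """Default non-ASD (typically developing) movement profile.

    Fixation duration centres on the 330 ms reported for naturalistic
    scene viewing on a computer screen.
    """
    return GazeProfile(fixation_duration_ms=(330.0, 80.0))


def asd_profile() -> GazeProfile:
    """Default ASD movement profile: higher saccade rate, larger amplitude.

    The direction of the separation (more frequent, larger saccades)
    follows one consistent strand of the eye-movement literature on ASD;
    the magnitudes are configurable because that literature is not
    unanimous.
    """
    return GazeProfile(
        fixation_duration_ms=(150.0, 50.0),
        saccade_amplitude_px=(400.0, 130.0),
        fixation_jitter_px=7.5,
        dropout_rate=0.08,
    )


def generate_recording(
    profile: GazeProfile,
    duration_s: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    screen: tuple[int, int] = DEFAULT_SCREEN,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    stimulus_id: str = "stim0",
) -> GazeRecording:
    """Simulate one fixation/saccade renewal process at ``rate_hz``.

    Samples ``duration_s * rate_hz`` points (10 s at 250 Hz gives 2500
    samples).  Gaze starts at screen centre; fixations jitter around
    their centre with the profile's per-sample drift SD, saccades move at
    constant velocity toward a uniformly drawn on-screen target, with the
    jump length drawn from the profile's amplitude distribution (capped
    at the distance to the target).  Blink bursts of ~150 ms mark
    contiguous samples invalid until the profile's dropout rate is met.
    Coordinates are clamped to the screen.  Fully deterministic given the
    seed.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration_s * rate_hz))
    dt_ms = 1000.0 / rate_hz
    w, h = screen
    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([w / 2.0, h / 2.0])

    fix_mean = profile.mean_fixation_ms()
    fix_sd = profile.fixation_duration_ms[1]
    sac_mean, sac_sd = profile.saccade_duration_ms
    amp_mean, amp_sd = profile.saccade_amplitude_px

    i = 0
    fixating = True
    while i < n:
        if fixating:
            dur = max(rng.normal(fix_mean, fix_sd), 2 * dt_ms)
            steps = max(int(round(dur / dt_ms)), 1)
            steps = min(steps, n - i)
            centre = pos.copy()
            for _ in range(steps):
                drift = rng.normal(0.0, profile.fixation_jitter_px, size=2)
                pos = centre + drift
                x[i], y[i] = pos
                i += 1
        else:
            dur = max(rng.normal(sac_mean, sac_sd), 2 * dt_ms)
            steps = max(int(round(dur / dt_ms)), 1)
            steps = min(steps, n - i)
            target = rng.uniform([0.0, 0.0], [w, h])
            direction = target - pos
            dist_to_target = float(np.hypot(*direction))
            amp = min(
                max(rng.normal(amp_mean, amp_sd), 0.0), max(dist_to_target, 1.0)
            )
            if dist_to_target > 0:
                step_vec = direction / dist_to_target * (amp / steps)
            else:
                step_vec = np.zeros(2)
            for _ in range(steps):
                pos = pos + step_vec
                x[i], y[i] = pos
                i += 1
        fixating = not fixating

    np.clip(x, 0.0, w, out=x)
    np.clip(y, 0.0, h, out=y)

    valid = np.ones(n, dtype=bool)
    if profile.dropout_rate > 0:
        blink_len = max(int(round(150.0 / dt_ms)), 1)
        n_lost_target = int(round(profile.dropout_rate * n))
        while n - valid.sum() < n_lost_target:
            start = int(rng.integers(0, max(n - blink_len, 1)))
            valid[start : start + blink_len] = False

    t = np.arange(n) * dt_ms
    return GazeRecording(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        t=t,
        x=x,
        y=y,
        valid=valid,
        screen=screen,
        sampling_rate=rate_hz,
    )


def default_cars_link(scale: float) -> float:
    """Affine-in-log link from a velocity scale to a CARS score.

    Maps the centre of the scale distribution (scale = 1) to the middle
    of the ASD band; strictly increasing in the scale.
    """
    lo, hi = CARS_ASD_RANGE
    return (lo + hi) / 2.0 + 13.0 * float(np.log(scale))


@dataclass
class CohortSpec:
    """Composition and generation parameters of a synthetic cohort."""

    n_asd: int = 29
    n_td: int = 30
    profile_asd: GazeProfile = field(default_factory=asd_profile)
    profile_td: GazeProfile = field(default_factory=td_profile)
    cars_link: Callable[[float], float] = default_cars_link
    cars_noise_sd: float = 1.5  # 10% of the 30-45 ASD band
    scale_sigma: float = 0.5  # SD of log individual velocity scale
    recordings_per_participant: int = 2
    duration_s: float = 4.0
    sampling_rate: float = DEFAULT_RATE_HZ
    screen: tuple[int, int] = DEFAULT_SCREEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 0 or self.n_td < 0:
            raise ConfigError("participant counts must be >= 0")
        if self.cars_noise_sd < 0 or self.scale_sigma < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.recordings_per_participant < 1:
            raise ConfigError("recordings_per_participant must be >= 1")


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[CohortManifest, list[GazeRecording]]:
    """Generate a full synthetic cohort: participants plus raw recordings.

    Each participant draws an individual velocity scale (log-normal,
    sigma = ``spec.scale_sigma``); ASD participants receive CARS =
    ``cars_link(scale)`` plus Gaussian noise, clipped to the 30-45 band,
    while non-ASD participants receive the constant scale minimum 15.
    Recordings use the group profile scaled by the individual factor.
    The manifest's image inventory is left empty -- rendering fills it.
    Deterministic given ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    participants: list[ParticipantRecord] = []
    recordings: list[GazeRecording] = []
    roster = [(ASD, i) for i in range(spec.n_asd)] + [
        (NON_ASD, i) for i in range(spec.n_td)
    ]
    for group, idx in roster:
        pid = f"{'asd' if group == ASD else 'td'}{idx:03d}"
        scale = float(np.exp(rng.normal(0.0, spec.scale_sigma)))
        if group == ASD:
            cars = spec.cars_link(scale)
            if spec.cars_noise_sd > 0:
                cars += rng.normal(0.0, spec.cars_noise_sd)
            cars = float(np.clip(cars, *CARS_ASD_RANGE))
            base = spec.profile_asd
        else:
            cars = CARS_TD
            base = spec.profile_td
        participants.append(
            ParticipantRecord(participant_id=pid, group=group, cars=cars)
        )
        profile = base.scaled(scale)
        for r in range(spec.recordings_per_participant):
            recordings.append(
                generate_recording(
                    profile,
                    duration_s=spec.duration_s,
                    rate_hz=spec.sampling_rate,
                    screen=spec.screen,
                    seed=rng,
                    participant_id=pid,
                    stimulus_id=f"stim{r}",
                )
            )
    return CohortManifest(participants=participants), recordings


def write_cohort(
    spec: CohortSpec, outdir: str | Path
) -> tuple[Path, list[Path]]:
    """Generate a cohort and write it in the formats ``gazescan.io`` reads.

    One delimited gaze file per recording plus a JSON manifest; returns
    the manifest path and the gaze file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, recordings = generate_cohort(spec)
    paths = [
        write_gaze_records(
            [rec], outdir / "gaze" / f"{rec.participant_id}_{rec.stimulus_id}.csv"
        )
        for rec in recordings
    ]
    manifest_path = write_manifest(manifest, outdir / "manifest.json")
    return manifest_path, paths
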