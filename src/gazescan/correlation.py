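"""Velocity-severity correlation analysis.

Each scanpath image summarises to one number -- the mean clipped gaze
speed over its transitions -- and pairs with the CARS score of the
participant it came from, so a participant with several images
contributes several pairs; this repeats the severity score with respect
to velocity and damps the effect of outlier images.  The dependence of
the two variables, which is visibly nonlinear in practice, is scored
with the maximal information coefficient (:func:`gazescan.mic.mic_score`).

Non-ASD participants all carry the scale-minimum CARS of 15; including a
constant-valued block can inflate apparent dependence, so they are
excluded by default (``include_non_asd=True`` restores them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ASD, CohortManifest
from .mic import DEFAULT_ALPHA, DEFAULT_CLUMPS, MIN_POINTS, mic_score
from .render import ScanpathSegment, clip_dynamics


def mean_velocity_per_image(segment: ScanpathSegment, clipped: bool = True) -> float:
    """Arithmetic mean transition speed of one segment, in px/ms.

    By default speeds are clipped at the quarter-diagonal displacement
    bound, matching what the rendered image encodes; ``clipped=False``
    averages the raw speeds.
    """
    trace = segment.velocity_trace()
    if len(trace) == 0:
        raise DataError("segment has no gap-free transitions to average")
    if clipped:
        trace = clip_dynamics(trace, segment.screen)
    return float(np.mean(trace.speeds))


@dataclass
class VelocitySeverityPairs:
    """Per-image (mean velocity, CARS) pairs plus provenance columns."""

    table: pd.DataFrame  # columns: velocity, cars, participant_id, image

    def __post_init__(self) -> None:
        required = {"velocity", "cars", "participant_id", "image"}
        if not required.issubset(self.table.columns):
            raise DataError(f"pairs table needs columns {sorted(required)}")
        if (self.table["velocity"] < 0).any():
            raise DataError("velocities must be non-negative")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def velocity(self) -> np.ndarray:
        return self.table["velocity"].to_numpy(float)

    @property
    def cars(self) -> np.ndarray:
        return self.table["cars"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_pairs(
    manifest: CohortManifest,
    segments: Sequence[ScanpathSegment],
    include_non_asd: bool = False,
    clipped: bool = True,
) -> VelocitySeverityPairs:
    """Assemble the per-image velocity/CARS table from rendered segments.

    Images of participants without a CARS score are skipped; non-ASD
    participants (constant CARS 15) are skipped unless requested.
    """
    rows = []
    for seg in segments:
        p = manifest.participant(seg.participant_id)
        if p.cars is None:
            continue
        if not include_non_asd and p.group != ASD:
            continue
        rows.append(
            {
                "velocity": mean_velocity_per_image(seg, clipped=clipped),
                "cars": p.cars,
                "participant_id": p.participant_id,
                "image": f"{seg.participant_id}_{seg.stimulus_id}_{seg.segment_index}",
            }
        )
    return VelocitySeverityPairs(
        pd.DataFrame(rows, columns=["velocity", "cars", "participant_id", "image"])
    )


def correlate_cohort(
    manifest: CohortManifest,
    segments: Sequence[ScanpathSegment],
    include_non_asd: bool = False,
    clipped: bool = True,
    alpha: float = DEFAULT_ALPHA,
    clumps: int = DEFAULT_CLUMPS,
) -> tuple[float, VelocitySeverityPairs]:
    """MIC between per-image mean velocity and CARS over a cohort.

    Returns the MIC score together with the pairs table (for plotting or
    export).  Requires at least 30 usable pairs.
    """
    pairs = build_pairs(
        manifest, segments, include_non_asd=include_non_asd, clipped=clipped
    )
    if len(pairs) < MIN_POINTS:
        raise DataError(
            f"correlation needs >= {MIN_POINTS} velocity/CARS pairs, "
            f"got {len(pairs)}"
        )
    score = mic_score(pairs.velocity, pairs.cars, alpha=alpha, clumps=clumps)
    return score, pairs
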