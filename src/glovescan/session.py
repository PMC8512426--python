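"""Streaming-session contract: append-only buffer plus on-demand re-filtering.

The original acquisition pipeline runs two concurrent threads — one
receiving and storing samples, one filtering.  Here that is replaced by
an equivalent sequential contract with identical outputs: samples are
appended to a raw buffer that never shrinks, and every ``refilter_every``
appended samples (or on demand) the *entire* buffer is re-filtered and
the result stored as a snapshot.  Each snapshot records the buffer
length that produced it, so any snapshot is reproducible by re-running
the filter on that buffer prefix with the stored configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import FilterConfig, ValidatedCloud, filter_pipeline
from .geometry import (
    ObjectFramePoint,
    PoseSample,
    ReferencePoint,
    match_reference_indices,
    to_object_frame_many,
)


@dataclass
class Snapshot:
    """One filtering pass over a buffer prefix."""

    n_raw: int
    cloud: ValidatedCloud


@dataclass
class SessionRecord:
    """Raw sample buffer, reference data and validated-cloud snapshots."""

    refs: list
    config: FilterConfig = field(default_factory=FilterConfig)
    refilter_every: int = 0  # 0 = only on demand
    reference_sensor_id: int = 0

    def __post_init__(self):
        self._glove: list[PoseSample] = []
        self._ref_stream: list[PoseSample] = []
        self.snapshots: list[Snapshot] = []
        self._since_refilter = 0

    @property
    def n_raw(self) -> int:
        return len(self._glove)

    def append(self, samples) -> None:
        """Append acquired samples; reference-sensor samples go to the
        reference stream, everything else to the raw glove buffer.

        Triggers a re-filter whenever ``refilter_every`` new glove samples
        have accumulated since the last snapshot.
        """
        for s in samples:
            if s.sensor_id == self.reference_sensor_id:
                self._ref_stream.append(s)
            else:
                self._glove.append(s)
                self._since_refilter += 1
                if self.refilter_every and self._since_refilter >= self.refilter_every:
                    self.refilter()

    def object_frame_points(self, n: int | None = None) -> list[ObjectFramePoint]:
        """Frame-compensated glove samples for the first ``n`` buffer entries.

        Without a reference stream, base-frame coordinates are passed
        through unchanged (static object assumed).
        """
        glove = self._glove if n is None else self._glove[:n]
        if not glove:
            return []
        pos = np.array([s.position for s in glove])
        if self._ref_stream:
            ref_t = np.array([r.t for r in self._ref_stream])
            idx = match_reference_indices(np.array([s.t for s in glove]), ref_t)
            ref_pos = np.array([self._ref_stream[i].position for i in idx])
            ref_q = np.array([self._ref_stream[i].orientation for i in idx])
            pos = to_object_frame_many(pos, ref_pos, ref_q)
        return [
            ObjectFramePoint(pos[i], glove[i].sensor_id, glove[i].t)
            for i in range(len(glove))
        ]

    def refilter(self, n: int | None = None) -> Snapshot:
        """Re-run the full filter over the buffer (or its first ``n`` samples)."""
        pts = self.object_frame_points(n)
        cloud = filter_pipeline(pts, self.refs, self.config) if pts else ValidatedCloud.empty()
        snap = Snapshot(n_raw=len(pts), cloud=cloud)
        self.snapshots.append(snap)
        self._since_refilter = 0
        return snap
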