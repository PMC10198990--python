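"""Containers for continuous 2-D affect rating time series.

A cohort's ratings are conceptually a long table
``(participant_id, video_id, t_s, valence, arousal)``: every participant
watches every video and continuously reports the target character's affect
on a bounded valence-arousal grid (both axes scaled to [-1, 1]).  For
computation we keep one dense ``time x participant`` block per video and
dimension; the long :class:`pandas.DataFrame` form is the on-disk
interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

DIMENSIONS = ("valence", "arousal")

RATINGS_COLUMNS = ["participant_id", "video_id", "t_s", "valence", "arousal"]

_REL_DT_TOL = 1e-6


@dataclass
class VideoBlock:
    """All raters' trajectories for one video on a shared uniform time base."""

    video_id: str
    t: np.ndarray                       # (n_samples,) seconds, uniform
    participants: list[str]             # sorted participant ids
    values: dict[str, np.ndarray]       # dimension -> (n_samples, n_participants)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.n_samples > 1 else np.nan

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt) if self.n_samples > 1 else 0.0


@dataclass
class RatingSet:
    """A cohort of affect-rating trajectories, indexed by video.

    Use :meth:`from_frame` to build a validated instance from the long
    table and :meth:`to_frame` to serialize back.  Within one video all
    participants must share the same strictly increasing, uniformly spaced
    time base; participant values must lie in [-1, 1].
    """

    blocks: dict[str, VideoBlock] = field(default_factory=dict)

    @property
    def videos(self) -> list[str]:
        return sorted(self.blocks)

    @property
    def participants(self) -> list[str]:
        out: set[str] = set()
        for b in self.blocks.values():
            out.update(b.participants)
        return sorted(out)

    @property
    def n_samples_total(self) -> int:
        return sum(b.n_samples * len(b.participants) for b in self.blocks.values())

    def block(self, video_id: str) -> VideoBlock:
        try:
            return self.blocks[video_id]
        except KeyError:
            raise KeyError(f"unknown video_id {video_id!r}") from None

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatingSet":
        missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"ratings table missing columns: {missing}")
        for dim in DIMENSIONS:
            vals = df[dim].to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isfinite(vals) | (np.abs(vals) > 1.0))
            if bad.size:
                raise ValidationError(
                    f"{dim} out of range [-1, 1] at table rows {bad[:10].tolist()}"
                    + ("..." if bad.size > 10 else "")
                )
        dup = df.duplicated(subset=["participant_id", "video_id", "t_s"])
        if dup.any():
            rows = np.flatnonzero(dup.to_numpy())
            raise ValidationError(
                f"duplicated (participant, video, t) rows at {rows[:10].tolist()}"
            )

        blocks: dict[str, VideoBlock] = {}
        for vid, vdf in df.groupby("video_id", sort=True, observed=True):
            vid = str(vid)
            wide = {
                dim: vdf.pivot(index="t_s", columns="participant_id", values=dim)
                for dim in DIMENSIONS
            }
            pw = wide["valence"]
            for pid in pw.columns:
                if pw[pid].isna().any():
                    raise StructuralError(
                        f"participant {pid!r} has an incomplete series for video {vid!r}"
                    )
            t = pw.index.to_numpy(dtype=float)
            if t.size > 1:
                dts = np.diff(t)
                if np.any(dts <= 0):
                    raise ValidationError(f"non-increasing time base in video {vid!r}")
                if not np.allclose(dts, dts[0], rtol=_REL_DT_TOL, atol=1e-9):
                    raise ValidationError(f"non-uniform time base in video {vid!r}")
            participants = sorted(str(c) for c in pw.columns)
            values = {
                dim: wide[dim].loc[:, participants].to_numpy(dtype=float)
                for dim in DIMENSIONS
            }
            blocks[vid] = VideoBlock(vid, t, participants, values)
        return cls(blocks)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for vid in self.videos:
            b = self.blocks[vid]
            n, p = b.n_samples, len(b.participants)
            parts.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(b.participants, n),
                        "video_id": vid,
                        "t_s": np.tile(b.t, p),
                        "valence": b.values["valence"].T.ravel(),
                        "arousal": b.values["arousal"].T.ravel(),
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=RATINGS_COLUMNS)
        return pd.concat(parts, ignore_index=True)[RATINGS_COLUMNS]

    # ------------------------------------------------------------------
    def equals(self, other: "RatingSet", atol: float = 0.0) -> bool:
        if self.videos != other.videos:
            return False
        for vid in self.videos:
            a, b = self.blocks[vid], other.blocks[vid]
            if a.participants != b.participants:
                return False
            if not np.allclose(a.t, b.t, atol=atol, rtol=0):
                return False
            for dim in DIMENSIONS:
                if not np.allclose(a.values[dim], b.values[dim], atol=atol, rtol=0):
                    return False
        return True
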