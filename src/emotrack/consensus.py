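"""Informal cultural consensus scoring of affect-rating trajectories.

Continuous emotion ratings have no objective ground truth; the informal
cultural consensus model replaces it with the structure of agreement
among raters.  For every video and dimension we assemble the
``time x rater`` matrix, standardize each rater's series, and take the
first principal component's factor scores — a weighted linear
combination of the ratings in which mutually consistent raters receive
the largest weights — as the consensus trajectory.  A rater's accuracy
on a video is then the Pearson correlation of their own series with the
consensus, and accuracies are pooled across videos (or raters) by
Fisher-Z averaging: ``tanh(mean(atanh(r)))``.

Zero-variance rater series (a cursor that never moved) carry no
information about agreement: they are dropped from the consensus and
their accuracy cells are recorded as missing, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, StructuralError, UndefinedCorrelationError
from .ratings import DIMENSIONS, RatingSet

logger = logging.getLogger(__name__)

#: correlations are clipped to +-(1 - FISHER_CLIP) before atanh
FISHER_CLIP = 1e-7

MIN_RATERS = 3

#: a series is treated as constant when its SD is below this relative level
_CONST_RTOL = 1e-12


def _column_sd_keep(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    scale = np.maximum(1.0, np.abs(M).max(axis=0))
    return sd > _CONST_RTOL * scale


@dataclass
class ConsensusTrajectory:
    """First-factor consensus for one (video, dimension)."""

    video_id: str
    dimension: str
    scores: np.ndarray                   # (n_samples,) factor-score series
    loadings: pd.Series                  # per-rater weight, indexed by id
    explained_variance_fraction: float
    dropped: list[str] = field(default_factory=list)  # zero-variance raters


@dataclass
class AccuracyTable:
    """Per-cell accuracies plus Fisher-Z pooled scores.

    ``cells`` is long-format ``(participant_id, video_id, dimension, r)``
    with missing cells absent; ``participant_pooled`` pools over videos,
    ``video_pooled`` over participants.
    """

    cells: pd.DataFrame
    participant_pooled: pd.DataFrame     # participant_id, dimension, accuracy
    video_pooled: pd.DataFrame           # video_id, dimension, accuracy
    consensus: dict[tuple[str, str], ConsensusTrajectory]
    missing: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def cell_matrix(self, dimension: str) -> pd.DataFrame:
        """Participant x video matrix of r values (NaN where missing)."""
        sub = self.cells[self.cells["dimension"] == dimension]
        return sub.pivot(index="participant_id", columns="video_id", values="r")

    def pooled_series(self, dimension: str) -> pd.Series:
        sub = self.participant_pooled[
            self.participant_pooled["dimension"] == dimension
        ]
        return sub.set_index("participant_id")["accuracy"].sort_index()


# ----------------------------------------------------------------------

def build_rating_matrix(rating_set: RatingSet, video_id: str, dimension: str):
    """Assemble the ``time x participant`` matrix for one video/dimension.

    Columns follow sorted participant_id.  Returns ``(matrix, ids)``.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    block = rating_set.block(video_id)
    ids = block.participants
    if len(ids) < MIN_RATERS:
        raise StructuralError(
            f"video {video_id!r} has {len(ids)} raters; consensus needs >= {MIN_RATERS}"
        )
    M = block.values[dimension]
    if not np.all(np.isfinite(M)):
        bad = [ids[j] for j in np.unique(np.nonzero(~np.isfinite(M))[1])]
        raise StructuralError(
            f"video {video_id!r}: non-finite samples for participants {bad}"
        )
    return M, list(ids)


def compute_consensus(matrix: np.ndarray, participant_ids=None,
                      video_id: str = "", dimension: str = "") -> ConsensusTrajectory:
    """First principal-component factor scores of the standardized columns.

    Columns are z-scored (correlation-matrix PCA) so rater gain and
    offset are nuisance; zero-variance columns are dropped with a logged
    warning.  The score sign is aligned so the mean loading is
    non-negative; an exact-zero mean is broken toward a non-negative
    loading for the first (sorted) rater.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("matrix must be 2-D (time x participants)")
    n, p = M.shape
    if participant_ids is None:
        participant_ids = [f"col{j}" for j in range(p)]
    if len(participant_ids) != p:
        raise ValueError("participant_ids length must match matrix columns")

    keep = _column_sd_keep(M)
    dropped = [pid for pid, k in zip(participant_ids, keep) if not k]
    if not keep.any():
        raise DegenerateInputError(
            f"all rater series constant for video {video_id!r} ({dimension})"
        )
    if dropped:
        logger.warning(
            "dropping zero-variance raters %s from consensus of %s/%s",
            dropped, video_id, dimension,
        )
    kept_ids = [pid for pid, k in zip(participant_ids, keep) if k]
    X = M[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    # SVD of the standardized data == eigendecomposition of the
    # correlation matrix; the leading right singular vector carries the
    # per-rater loadings and X @ v the factor scores over time.
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    total = float(np.sum(s ** 2))
    evf = float(s[0] ** 2 / total) if total > 0 else 1.0
    mean_loading = float(v.mean())
    tie = abs(mean_loading) <= _CONST_RTOL * np.abs(v).max()
    if (tie and v[0] < 0) or (not tie and mean_loading < 0):
        v = -v
    scores = X @ v
    return ConsensusTrajectory(
        video_id=video_id,
        dimension=dimension,
        scores=scores,
        loadings=pd.Series(v, index=kept_ids),
        explained_variance_fraction=evf,
        dropped=dropped,
    )


def score_participant(trajectory: np.ndarray, consensus: np.ndarray) -> float:
    """Pearson correlation of one rater's series with the consensus."""
    x = np.asarray(trajectory, dtype=float)
    c = np.asarray(consensus, dtype=float)
    if x.shape != c.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("trajectory and consensus must be equal-length 1-D, n >= 3")
    if not _column_sd_keep(x[:, None])[0]:
        raise UndefinedCorrelationError("rater series has zero variance")
    if not _column_sd_keep(c[:, None])[0]:
        raise UndefinedCorrelationError("consensus series has zero variance")
    xz = (x - x.mean()) / x.std()
    cz = (c - c.mean()) / c.std()
    return float(np.clip(xz @ cz / x.size, -1.0, 1.0))


def pool_fisher_z(r_values) -> float:
    """``tanh(mean(atanh(r)))`` with r clipped to +-(1 - 1e-7)."""
    r = np.asarray([v for v in np.atleast_1d(r_values) if np.isfinite(v)], dtype=float)
    if r.size == 0:
        raise ValueError("cannot pool an empty set of correlations")
    r = np.clip(r, -(1.0 - FISHER_CLIP), 1.0 - FISHER_CLIP)
    return float(np.tanh(np.mean(np.arctanh(r))))


# ----------------------------------------------------------------------

def score_study(rating_set: RatingSet, loo_consensus: bool = False) -> AccuracyTable:
    """Score every participant on every video and dimension.

    By default the consensus for a video includes the scored rater's own
    column (leave-in); with ``loo_consensus=True`` each rater is scored
    against a consensus recomputed without them.  Structural failures on
    one video are recorded and do not abort the remaining videos.
    """
    rows: list[tuple] = []
    missing: list[dict] = []
    failures: list[dict] = []
    consensus_map: dict[tuple[str, str], ConsensusTrajectory] = {}

    for vid in rating_set.videos:
        for dim in DIMENSIONS:
            try:
                M, ids = build_rating_matrix(rating_set, vid, dim)
                cons = compute_consensus(M, ids, video_id=vid, dimension=dim)
            except (StructuralError, DegenerateInputError) as exc:
                failures.append({"video_id": vid, "dimension": dim, "error": str(exc)})
                continue
            consensus_map[(vid, dim)] = cons
            for pid in cons.dropped:
                missing.append(
                    {"participant_id": pid, "video_id": vid, "dimension": dim,
                     "reason": "zero-variance trajectory"}
                )
            if loo_consensus:
                for j, pid in enumerate(ids):
                    if pid in cons.dropped:
                        continue
                    others = [k for k in range(len(ids)) if k != j]
                    try:
                        loo = compute_consensus(
                            M[:, others], [ids[k] for k in others],
                            video_id=vid, dimension=dim,
                        )
                        r = score_participant(M[:, j], loo.scores)
                    except (DegenerateInputError, UndefinedCorrelationError):
                        missing.append(
                            {"participant_id": pid, "video_id": vid,
                             "dimension": dim, "reason": "degenerate LOO consensus"}
                        )
                        continue
                    rows.append((pid, vid, dim, r))
            else:
                # r for all kept raters at once: columns of X are z-scored,
                # so r_j = z(scores) . x_j / n
                kept = [j for j, pid in enumerate(ids) if pid not in cons.dropped]
                X = M[:, kept]
                X = (X - X.mean(axis=0)) / X.std(axis=0)
                sz = (cons.scores - cons.scores.mean()) / cons.scores.std()
                r_all = np.clip(sz @ X / X.shape[0], -1.0, 1.0)
                for j, r in zip(kept, r_all):
                    rows.append((ids[j], vid, dim, float(r)))

    cells = pd.DataFrame(rows, columns=["participant_id", "video_id", "dimension", "r"])
    if not cells.empty:
        cells = cells.sort_values(
            ["dimension", "participant_id", "video_id"], ignore_index=True
        )

    def _pool(by: str, out_name: str) -> pd.DataFrame:
        if cells.empty:
            return pd.DataFrame(columns=[by, "dimension", "accuracy"])
        g = (
            cells.groupby([by, "dimension"], observed=True)["r"]
            .apply(pool_fisher_z)
            .reset_index()
            .rename(columns={"r": "accuracy"})
        )
        return g

    return AccuracyTable(
        cells=cells,
        participant_pooled=_pool("participant_id", "accuracy"),
        video_pooled=_pool("video_id", "accuracy"),
        consensus=consensus_map,
        missing=missing,
        failures=failures,
    )
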