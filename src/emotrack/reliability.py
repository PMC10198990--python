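"""Reliability diagnostics: bootstrap CIs, permutation nulls, and
random-responder detection.

Three complementary checks establish that accuracy scores reflect real
tracking rather than chance alignment:

* percentile-bootstrap confidence intervals on per-participant and
  per-video pooled accuracy;
* a permuted null for accuracy built from uniformly random *circular
  time shifts* of each rater's trajectory (the shift preserves each
  series' autocorrelation and marginal distribution while destroying
  its alignment with the consensus); shifts stay at least
  ``min_shift_s`` away from zero so the permuted series is never a
  near-copy of the original;
* the *difficulty function*: videos ranked by group-pooled accuracy.
  Each participant's own per-video accuracy vector is correlated with
  the leave-one-out group difficulty function; a participant whose
  correlation falls inside the 95% band of a video-label permutation
  null is flagged as a possible random responder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import (
    AccuracyTable,
    FISHER_CLIP,
    build_rating_matrix,
    compute_consensus,
    pool_fisher_z,
)
from .errors import ValidationError
from .ratings import DIMENSIONS, RatingSet

DEFAULT_B = 5000


@dataclass
class NullDistribution:
    statistic: str
    samples: np.ndarray
    ci95: tuple[float, float]
    mean: float

    @classmethod
    def from_samples(cls, statistic: str, samples: np.ndarray) -> "NullDistribution":
        samples = np.asarray(samples, dtype=float).ravel()
        lo, hi = np.percentile(samples, [2.5, 97.5])
        return cls(statistic, samples, (float(lo), float(hi)), float(samples.mean()))


def bootstrap_ci(values, B: int = DEFAULT_B, seed=None, statistic=np.mean):
    """Percentile bootstrap 95% CI of ``statistic`` over ``values``."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("bootstrap_ci requires a nonempty sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    if statistic is np.mean:
        stats = x[idx].mean(axis=1)
    else:
        stats = np.array([statistic(x[row]) for row in idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def difficulty_function(accuracy_table: AccuracyTable, dimension: str) -> pd.DataFrame:
    """Videos ordered by ascending pooled accuracy (hard -> easy)."""
    sub = accuracy_table.video_pooled
    sub = sub[sub["dimension"] == dimension]
    out = sub.sort_values(["accuracy", "video_id"], ignore_index=True)
    return out[["video_id", "dimension", "accuracy"]]


# ----------------------------------------------------------------------
# Circular-shift accuracy null
# ----------------------------------------------------------------------

def _circular_r_all_lags(consensus: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson r of each standardized column of X with the consensus at
    every circular lag, via FFT cross-correlation.  Shape (n_lags, p)."""
    n = X.shape[0]
    cz = (consensus - consensus.mean()) / consensus.std()
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    Xz = (X - X.mean(axis=0)) / sd
    fc = np.fft.rfft(cz)
    fx = np.fft.rfft(Xz, axis=0)
    return np.fft.irfft(fx * np.conj(fc)[:, None], n=n, axis=0) / n


def permuted_accuracy_null(rating_set: RatingSet, B: int = 1000, seed=None,
                           min_shift_s: float = 10.0,
                           dimensions=DIMENSIONS) -> dict[str, NullDistribution]:
    """Null distribution of per-participant pooled accuracy under random
    circular time shifts of every rater-video trajectory.

    Each of the ``B`` permutations re-scores every participant against
    the (unshifted) consensus after an independent uniform circular
    shift, at least ``min_shift_s`` from zero in either direction, then
    Fisher-Z pools over videos.  Returns one :class:`NullDistribution`
    per dimension whose samples are the B x n_participants pooled
    accuracies.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    participants = rating_set.participants
    p_index = {pid: i for i, pid in enumerate(participants)}
    P = len(participants)

    out: dict[str, NullDistribution] = {}
    for dim in dimensions:
        lag_tables = []          # (r_lags, col ids, allowed lag lo/hi)
        for vid in rating_set.videos:
            block = rating_set.block(vid)
            n, dt = block.n_samples, block.dt
            min_shift = int(np.ceil(min_shift_s / dt))
            if n < 2 * min_shift:
                raise ValidationError(
                    f"video {vid!r} shorter than twice the minimum shift "
                    f"({min_shift_s} s)"
                )
            M, ids = build_rating_matrix(rating_set, vid, dim)
            cons = compute_consensus(M, ids, video_id=vid, dimension=dim)
            r_lags = _circular_r_all_lags(cons.scores, M)   # (n, P_v)
            cols = np.array([p_index[i] for i in ids])
            lag_tables.append((r_lags, cols, min_shift, n - min_shift))

        z_sum = np.zeros((B, P))
        z_cnt = np.zeros((B, P))
        clip = 1.0 - FISHER_CLIP
        for r_lags, cols, lo, hi in lag_tables:
            lags = rng.integers(lo, hi + 1, size=(B, cols.size))
            r = r_lags[lags, np.arange(cols.size)[None, :]]
            z = np.arctanh(np.clip(r, -clip, clip))
            ok = np.isfinite(z)
            z_sum[:, cols] += np.where(ok, z, 0.0)
            z_cnt[:, cols] += ok
        with np.errstate(invalid="ignore"):
            pooled = np.tanh(z_sum / z_cnt)
        out[dim] = NullDistribution.from_samples(
            f"pooled_accuracy_null_{dim}", pooled[np.isfinite(pooled)]
        )
    return out


# ----------------------------------------------------------------------
# Leave-one-out difficulty correlations
# ----------------------------------------------------------------------

def loo_difficulty_correlations(accuracy_table: AccuracyTable,
                                dimension: str = "valence",
                                B: int = DEFAULT_B, seed=None) -> pd.DataFrame:
    """Correlate each participant's difficulty function with the group's.

    For participant *i*, the group per-video pooled accuracy is
    recomputed excluding *i* (leave-one-out), and the Pearson r between
    *i*'s own per-video accuracies and that group vector is compared to
    a null built by permuting the video labels of *i*'s vector B times.
    Participants with fewer than 3 non-missing videos are flagged, not
    correlated.  Returns a frame with r, the null 95% band and an
    ``inside_null`` flag per participant.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = accuracy_table.cell_matrix(dimension)          # participants x videos
    if A.shape[0] < 3 or A.shape[1] < 3:
        raise ValidationError("need >= 3 participants and >= 3 videos")
    vals = A.to_numpy(dtype=float)
    clip = 1.0 - FISHER_CLIP
    Z = np.arctanh(np.clip(vals, -clip, clip))
    finite = np.isfinite(Z)
    z_sum = np.nansum(np.where(finite, Z, 0.0), axis=0)
    z_cnt = finite.sum(axis=0)

    rows = []
    for i, pid in enumerate(A.index):
        own = vals[i]
        mask = np.isfinite(own)
        cnt = z_cnt - finite[i]
        mask &= cnt > 0
        if mask.sum() < 3:
            rows.append((pid, np.nan, np.nan, np.nan, True, int(mask.sum())))
            continue
        loo = np.tanh((z_sum - np.where(finite[i], Z[i], 0.0))[mask] / cnt[mask])
        x = own[mask]
        if x.std() == 0 or loo.std() == 0:
            rows.append((pid, np.nan, np.nan, np.nan, True, int(mask.sum())))
            continue
        xz = (x - x.mean()) / x.std()
        gz = (loo - loo.mean()) / loo.std()
        r_obs = float(xz @ gz / x.size)
        # permute video labels of the participant's own vector
        perms = rng.permuted(np.tile(xz, (B, 1)), axis=1)
        r_null = perms @ gz / x.size
        lo_b, hi_b = np.percentile(r_null, [2.5, 97.5])
        inside = bool(lo_b <= r_obs <= hi_b)
        rows.append((pid, r_obs, float(lo_b), float(hi_b), inside, int(mask.sum())))

    return pd.DataFrame(
        rows,
        columns=["participant_id", "r", "null_low", "null_high",
                 "inside_null", "n_videos"],
    )


def flag_inconsistent_participants(loo_result: pd.DataFrame) -> list[str]:
    """Participants whose difficulty-function correlation is null-consistent."""
    flagged = loo_result.loc[loo_result["inside_null"], "participant_id"]
    return sorted(flagged.astype(str))
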