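"""Monte-Carlo item analysis: which videos carry the accuracy–trait effect.

Treating videos as test items, these procedures ask how many items (and
which ones) are needed to recover the correlation between pooled
tracking accuracy and a trait score (AQ):

* :func:`subset_effect_curve` — for each subset size k, repeatedly draw
  k videos without replacement, pool each participant's accuracy over
  them (Fisher-Z), correlate with the trait, and Fisher-Z-average the
  iteration rhos;
* :func:`min_videos_for_threshold` — smallest k whose curve magnitude
  reaches a fraction (default 75%) of the full-set effect;
* :func:`best_videos` — rank videos by the per-video accuracy–trait
  Spearman correlation in the hypothesized (negative) direction;
* :func:`crossval_correlation` — split-sample reliability: random
  five-chunk partitions, per-chunk Spearman, Fisher-Z averaged, over
  many iterations;
* :func:`group_split_comparison` — median or quartile trait splits with
  two-sided bootstrap tests on group accuracy differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import FISHER_CLIP
from .errors import DegenerateInputError, ValidationError

DEFAULT_ITERS = 5000
_CLIP = 1.0 - FISHER_CLIP


@dataclass
class SubsetCurve:
    k: np.ndarray                # subset sizes
    mean_rho: np.ndarray         # Fisher-Z mean Spearman rho per k
    iterations: int
    full_rho: float              # rho with every video (exact, no sampling)


@dataclass
class GroupSplit:
    mode: str                                  # "median" | "quartile"
    groups: dict[str, list[str]]               # label -> participant ids
    group_accuracy: dict[str, float]           # Fisher-Z mean accuracy
    pairwise_p: dict[tuple[str, str], float]   # two-sided bootstrap p
    B: int = 0
    notes: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------

def _align(accuracy_cells: pd.DataFrame, trait: pd.Series):
    """Common participants; returns (cells ndarray P x V, trait ndarray, ids, vids)."""
    trait = trait.dropna()
    common = accuracy_cells.index.intersection(trait.index).sort_values()
    if len(common) < 4:
        raise ValidationError("need >= 4 participants with trait scores")
    cells = accuracy_cells.loc[common].to_numpy(dtype=float)
    return (cells, trait.loc[common].to_numpy(dtype=float),
            list(common), list(accuracy_cells.columns))


def _pool_rows(z: np.ndarray, col_idx: np.ndarray) -> np.ndarray:
    """Fisher-Z pool each row of a (P x V) z-matrix over selected columns."""
    sub = z[:, col_idx]
    ok = np.isfinite(sub)
    with np.errstate(invalid="ignore"):
        return np.tanh(np.where(ok, sub, 0.0).sum(axis=1) / ok.sum(axis=1))


def _spearman_fast(x: np.ndarray, y_rank_z: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    s = rx.std()
    if s == 0:
        return np.nan
    return float(np.clip((rx - rx.mean()) / s @ y_rank_z / x.size, -1.0, 1.0))


def subset_effect_curve(accuracy_cells: pd.DataFrame, trait: pd.Series,
                        k_min: int = 5, k_max: Optional[int] = None,
                        iters: int = DEFAULT_ITERS, seed=None) -> SubsetCurve:
    """Fisher-Z mean accuracy–trait Spearman rho as a function of the
    number of randomly drawn videos.

    ``accuracy_cells`` is the participant x video accuracy matrix (NaN
    for missing cells); ``trait`` a participant-indexed Series.  At
    ``k = V`` every draw is the full set, so the curve value equals the
    full-sample rho exactly.
    """
    cells, t, _, vids = _align(accuracy_cells, trait)
    V = len(vids)
    k_max = V if k_max is None else k_max
    if not (1 <= k_min <= k_max <= V):
        raise ValidationError(f"k range [{k_min}, {k_max}] outside [1, {V}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.arctanh(np.clip(cells, -_CLIP, _CLIP))
    rt = stats.rankdata(t, method="average")
    rtz = (rt - rt.mean()) / rt.std()

    full_rho = _spearman_fast(_pool_rows(z, np.arange(V)), rtz)
    ks = np.arange(k_min, k_max + 1)
    means = np.empty(ks.size)
    for i, k in enumerate(ks):
        if k == V:
            means[i] = full_rho
            continue
        rhos = np.empty(iters)
        for b in range(iters):
            idx = rng.choice(V, size=k, replace=False)
            rhos[b] = _spearman_fast(_pool_rows(z, idx), rtz)
        rhos = rhos[np.isfinite(rhos)]
        means[i] = float(np.tanh(np.mean(np.arctanh(np.clip(rhos, -_CLIP, _CLIP)))))
    return SubsetCurve(k=ks, mean_rho=means, iterations=iters, full_rho=full_rho)


def min_videos_for_threshold(curve: SubsetCurve, full_rho: Optional[float] = None,
                             fraction: float = 0.75):
    """Smallest k whose curve magnitude reaches ``fraction`` of the full
    effect.  Returns ``(k_star, threshold)``; ``k_star`` is None when the
    threshold is never reached."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    full = curve.full_rho if full_rho is None else full_rho
    threshold = fraction * abs(full)
    hits = np.flatnonzero(np.abs(curve.mean_rho) >= threshold)
    k_star = int(curve.k[hits[0]]) if hits.size else None
    return k_star, float(threshold)


def best_videos(accuracy_cells: pd.DataFrame, trait: pd.Series,
                n_best: int = 7, direction: str = "negative"):
    """The ``n_best`` videos whose per-video accuracy–trait Spearman rho
    is strongest in the hypothesized direction (default: most negative).

    Returns ``(video_ids, per_video_table)``; ties and ordering are
    broken by sorted video_id so the result is independent of input row
    order.
    """
    cells, t, _, vids = _align(accuracy_cells, trait)
    V = len(vids)
    if not (1 <= n_best <= V):
        raise ValidationError(f"n_best must be in [1, {V}]")
    rt = stats.rankdata(t, method="average")
    rows = []
    for j, vid in enumerate(vids):
        col = cells[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 4:
            rows.append((vid, np.nan, int(ok.sum())))
            continue
        rx = stats.rankdata(col[ok], method="average")
        ry = stats.rankdata(rt[ok], method="average")
        if rx.std() == 0 or ry.std() == 0:
            rows.append((vid, np.nan, int(ok.sum())))
            continue
        rho = float(np.corrcoef(rx, ry)[0, 1])
        rows.append((vid, rho, int(ok.sum())))
    table = pd.DataFrame(rows, columns=["video_id", "rho", "n"])
    ranked = table.dropna(subset=["rho"]).sort_values(
        ["rho", "video_id"], ascending=[direction == "negative", True],
        ignore_index=True,
    )
    if len(ranked) < n_best:
        raise ValidationError("too few videos with a defined correlation")
    return list(ranked["video_id"].iloc[:n_best]), table


def crossval_correlation(scores: pd.Series, trait: pd.Series, folds: int = 5,
                         iters: int = DEFAULT_ITERS, seed=None,
                         min_valid_chunks: int = 3):
    """Split-sample reliability of the accuracy–trait correlation.

    Each iteration partitions participants into ``folds`` near-equal
    random chunks, computes the Spearman rho per chunk and Fisher-Z
    averages them; chunks with a constant variable are skipped (an
    iteration needs at least ``min_valid_chunks``).  Returns
    ``(mean_rho, (ci_low, ci_high), n_used_iterations)``.
    """
    df = pd.concat({"s": scores, "t": trait}, axis=1).dropna()
    n = len(df)
    if n < folds * 4:
        raise ValidationError(f"need at least {folds * 4} participants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = df["s"].to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    means = np.empty(iters)
    used = 0
    for b in range(iters):
        order = rng.permutation(n)
        chunks = np.array_split(order, folds)
        zs = []
        for ch in chunks:
            sx, tx = s[ch], t[ch]
            rx = stats.rankdata(sx, method="average")
            ry = stats.rankdata(tx, method="average")
            if rx.std() == 0 or ry.std() == 0:
                continue
            rho = float(np.corrcoef(rx, ry)[0, 1])
            zs.append(np.arctanh(np.clip(rho, -_CLIP, _CLIP)))
        if len(zs) < min_valid_chunks:
            means[b] = np.nan
            continue
        means[b] = np.tanh(np.mean(zs))
        used += 1
    valid = means[np.isfinite(means)]
    if valid.size == 0:
        raise DegenerateInputError("no iteration produced enough valid chunks")
    mean_rho = float(np.tanh(np.mean(np.arctanh(np.clip(valid, -_CLIP, _CLIP)))))
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return mean_rho, (float(lo), float(hi)), used


# ----------------------------------------------------------------------
# Group splits
# ----------------------------------------------------------------------

def _quartile_sizes(n: int) -> list[int]:
    # floor(n/4) per quartile with the remainder in the top group
    # reproduces 25/25/25/27 at n=102; when n % 4 == 3 the remainder is
    # spread so group sizes never differ by more than 2
    base, r = divmod(n, 4)
    if r <= 2:
        return [base, base, base, base + r]
    return [base, base + 1, base + 1, base + 1]


def group_split_comparison(scores: pd.Series, trait: pd.Series, mode: str,
                           seed=None, B: int = 5000) -> GroupSplit:
    """Compare pooled accuracy across trait-defined groups.

    ``median`` mode sorts by (trait, participant_id) and splits in half
    — ties at the median are allocated by rank so group sizes are equal
    (±1).  ``quartile`` mode cuts the same ordering at rank quartiles.
    Each group's score is the Fisher-Z mean of members' accuracies; each
    pair is tested with a two-sided case-resampling bootstrap:
    ``p = 2 * min(P(diff* <= 0), P(diff* >= 0))``.
    """
    if mode not in ("median", "quartile"):
        raise ValidationError("mode must be 'median' or 'quartile'")
    df = pd.concat({"s": scores, "t": trait}, axis=1).dropna()
    n = len(df)
    if n < 8:
        raise ValidationError("need >= 8 participants")
    order = df.sort_values("t", kind="mergesort").index  # stable: id breaks ties
    if mode == "median":
        half = (n + 1) // 2
        sizes = [half, n - half]
        labels = ["low", "high"]
    else:
        sizes = _quartile_sizes(n)
        labels = ["q1", "q2", "q3", "q4"]
    if min(sizes) < 4:
        raise ValidationError("a split group would have fewer than 4 members")
    bounds = np.cumsum([0] + sizes)
    groups = {
        lab: list(order[bounds[i]:bounds[i + 1]]) for i, lab in enumerate(labels)
    }
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def zmean(vals: np.ndarray) -> float:
        return float(np.mean(np.arctanh(np.clip(vals, -_CLIP, _CLIP))))

    acc = {lab: float(np.tanh(zmean(df.loc[ids, "s"].to_numpy())))
           for lab, ids in groups.items()}
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = df.loc[groups[labels[i]], "s"].to_numpy(dtype=float)
            b = df.loc[groups[labels[j]], "s"].to_numpy(dtype=float)
            za = np.arctanh(np.clip(a, -_CLIP, _CLIP))
            zb = np.arctanh(np.clip(b, -_CLIP, _CLIP))
            ia = rng.integers(0, za.size, size=(B, za.size))
            ib = rng.integers(0, zb.size, size=(B, zb.size))
            diff = za[ia].mean(axis=1) - zb[ib].mean(axis=1)
            p = 2.0 * min(np.mean(diff <= 0), np.mean(diff >= 0))
            pairwise[(labels[i], labels[j])] = float(min(1.0, p))
    return GroupSplit(mode=mode, groups=groups, group_accuracy=acc,
                      pairwise_p=pairwise, B=B)
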