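"""Correlation battery between tracking accuracy and trait questionnaires.

All associations are rank-based: the Spearman correlation is computed as
the Pearson correlation of average ranks, partial Spearman correlations
rank-transform every variable and then correlate the least-squares
residuals after projecting out the covariate ranks (plus intercept), and
bootstrap means of correlations use Fisher-Z averaging.  With an empty
covariate set the partial correlation reduces *exactly* to the plain
Spearman correlation, because both are Pearson correlations of
intercept-residualized ranks.

Multiple-comparison control follows the planned-comparison convention:
Bonferroni over the declared comparison plan (17 comparisons by
default), reporting both corrected and uncorrected p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import FISHER_CLIP
from .errors import DegenerateInputError, UndefinedCorrelationError, ValidationError

DEFAULT_B = 5000
DEFAULT_M_COMPARISONS = 17

#: default comparison plan: the two tracking accuracies and the two face
#: tasks against AQ, EQ, fluid (matrices) and crystallized (vocabulary)
#: intelligence, plus the flagged-participant sensitivity re-run of the
#: headline valence-accuracy ~ AQ comparison.
DEFAULT_PLAN: list[dict] = [
    {"x": x, "y": y}
    for x in ("iet_valence", "iet_arousal", "eyes_test", "films_task")
    for y in ("aq", "eq", "matrices", "vocabulary")
] + [
    {"x": "iet_valence", "y": "aq", "label": "iet_valence~aq (without flagged)",
     "exclude_flagged": True}
]


@dataclass
class CorrelationResult:
    x: str
    y: str
    rho: float
    p_uncorrected: float
    n: int
    covariates: tuple[str, ...] = ()
    method: str = "spearman"
    m_comparisons: Optional[int] = None
    p_bonferroni: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None
    B: Optional[int] = None
    label: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "x": self.x, "y": self.y, "rho": self.rho,
            "p_uncorrected": self.p_uncorrected, "n": self.n,
            "method": self.method,
        }
        if self.covariates:
            d["covariates"] = list(self.covariates)
        if self.m_comparisons is not None:
            d["m_comparisons"] = self.m_comparisons
            d["p_bonferroni"] = self.p_bonferroni
        if self.ci95 is not None:
            d["ci95"] = list(self.ci95)
        if self.B is not None:
            d["B"] = self.B
        if self.label:
            d["label"] = self.label
        return d


# ----------------------------------------------------------------------
# Descriptives
# ----------------------------------------------------------------------

def descriptives(values, name: str = "") -> dict:
    """Mean, median, sample SD, range, skewness and excess kurtosis.

    Skewness is the adjusted Fisher–Pearson standardized third moment
    and kurtosis the bias-corrected excess kurtosis, the conventions of
    common statistical software.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size < 3:
        raise ValidationError("descriptives require n >= 3")
    return {
        "variable": name,
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "skewness": float(stats.skew(x, bias=False)),
        "kurtosis": float(stats.kurtosis(x, bias=False, fisher=True)),
    }


def descriptives_table(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame([descriptives(df[v], v) for v in variables])


# ----------------------------------------------------------------------
# Rank correlations
# ----------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant variable in correlation")
    return float(np.clip(((x - x.mean()) / sx) @ ((y - y.mean()) / sy) / x.size,
                         -1.0, 1.0))


def _t_pvalue(rho: float, dof: int) -> float:
    if dof <= 0:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(dof / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), dof))


def _listwise(*arrays) -> list[np.ndarray]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValidationError("series must be paired (equal length)")
    mask = np.ones(n, dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    return [c[mask] for c in cols]


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman rho (Pearson of average ranks) with a t-approximation p."""
    return partial_spearman(x, y, covariates=None,
                            x_name=x_name, y_name=y_name)


def partial_spearman(x, y, covariates=None, x_name: str = "x", y_name: str = "y",
                     covariate_names: Sequence[str] = ()) -> CorrelationResult:
    """Partial Spearman correlation via rank-then-residualize.

    Every variable is converted to average ranks; x-ranks and y-ranks
    are residualized on the covariate ranks plus an intercept by least
    squares, and the Pearson correlation of the residuals is returned.
    ``covariates=None`` (or an empty list) reduces exactly to the plain
    Spearman correlation.  The p-value uses the t approximation with
    ``n - 2 - k`` degrees of freedom.
    """
    cov_list = [] if covariates is None else [np.asarray(c) for c in covariates]
    arrays = _listwise(x, y, *cov_list)
    xr, yr, cov_arr = arrays[0], arrays[1], arrays[2:]
    n = xr.size
    k = len(cov_arr)
    if n < 4:
        raise ValidationError("need n >= 4 paired observations")
    if k > n - 3:
        raise ValidationError("too many covariates for the sample size")

    ranks = [stats.rankdata(a, method="average") for a in (xr, yr, *cov_arr)]
    design = np.column_stack([np.ones(n)] + ranks[2:])
    if k:
        if np.linalg.matrix_rank(design) < design.shape[1]:
            names = list(covariate_names) or [f"cov{i}" for i in range(k)]
            raise ValidationError(f"collinear covariates among {names}")
    # residualize on the intercept(+covariates); with no covariates this
    # is plain centering, so the result is exactly Spearman's rho
    coefs, *_ = np.linalg.lstsq(design, np.column_stack(ranks[:2]), rcond=None)
    resid = np.column_stack(ranks[:2]) - design @ coefs
    rho = _pearson(resid[:, 0], resid[:, 1])
    p = _t_pvalue(rho, n - 2 - k)
    return CorrelationResult(
        x=x_name, y=y_name, rho=rho, p_uncorrected=p, n=n,
        covariates=tuple(covariate_names) if k else (),
        method="partial_spearman" if k else "spearman",
    )


def bonferroni(p: float, m: int = DEFAULT_M_COMPARISONS) -> float:
    """``min(1, m * p)`` for m planned comparisons."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p must be in [0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return min(1.0, m * p)


# ----------------------------------------------------------------------
# Resampling inference
# ----------------------------------------------------------------------

def bootstrap_partial(x, y, covariates=None, B: int = DEFAULT_B, seed=None,
                      x_name: str = "x", y_name: str = "y",
                      covariate_names: Sequence[str] = (),
                      max_retries: int = 100) -> CorrelationResult:
    """Case-resampling bootstrap of the (partial) Spearman correlation.

    Resamples participants with replacement, recomputes the partial
    correlation per resample, reports the Fisher-Z mean and the 2.5/97.5
    percentile CI.  Resamples in which any variable is constant are
    redrawn (bounded retries).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cov_list = [] if covariates is None else [np.asarray(c) for c in covariates]
    arrays = _listwise(x, y, *cov_list)
    n = arrays[0].size
    point = partial_spearman(arrays[0], arrays[1], arrays[2:] or None,
                             x_name, y_name, covariate_names)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rhos = np.empty(B)
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                res = partial_spearman(
                    arrays[0][idx], arrays[1][idx],
                    [c[idx] for c in arrays[2:]] or None,
                    x_name, y_name, covariate_names,
                )
            except (UndefinedCorrelationError, ValidationError):
                if attempt == max_retries:
                    raise DegenerateInputError(
                        "could not draw a non-degenerate bootstrap resample"
                    )
                continue
            rhos[b] = res.rho
            break
    clip = 1.0 - FISHER_CLIP
    mean_rho = float(np.tanh(np.mean(np.arctanh(np.clip(rhos, -clip, clip)))))
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return CorrelationResult(
        x=x_name, y=y_name, rho=mean_rho, p_uncorrected=point.p_uncorrected,
        n=n, covariates=point.covariates, method="bootstrap_partial_spearman",
        ci95=(float(lo), float(hi)), B=B,
    )


def permutation_test(x, y, B: int = DEFAULT_B, seed=None, exact: bool = False,
                     x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Two-sided permutation test of the Spearman correlation.

    Permutes y uniformly; ``p = (1 + #{|rho*| >= |rho|}) / (B + 1)``.
    With ``exact=True`` (small n only) all n! permutations are
    enumerated and p is the exact proportion.
    """
    xr, yr = _listwise(x, y)
    n = xr.size
    if n < 4:
        raise ValidationError("need n >= 4 paired observations")
    rx = stats.rankdata(xr, method="average")
    ry = stats.rankdata(yr, method="average")
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedCorrelationError("constant variable in permutation test")
    rxz = (rx - rx.mean()) / rx.std()
    ryz = (ry - ry.mean()) / ry.std()
    rho_obs = float(np.clip(rxz @ ryz / n, -1.0, 1.0))
    tol = 1e-12
    if exact:
        if n > 8:
            raise ValidationError("exact enumeration is limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (ryz[perms] @ rxz) / n
        p = float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - tol))
        B_used = perms.shape[0]
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        perm_y = rng.permuted(np.tile(ryz, (B, 1)), axis=1)
        rho_perm = perm_y @ rxz / n
        p = float((1 + np.sum(np.abs(rho_perm) >= abs(rho_obs) - tol)) / (B + 1))
        B_used = B
    return CorrelationResult(
        x=x_name, y=y_name, rho=rho_obs, p_uncorrected=p, n=n,
        method="permutation", B=B_used,
    )


# ----------------------------------------------------------------------
# Battery
# ----------------------------------------------------------------------

def correlation_battery(scores: pd.DataFrame, questionnaires: pd.DataFrame,
                        plan: Optional[list[dict]] = None,
                        flagged_ids: Optional[Sequence[str]] = None,
                        ) -> list[CorrelationResult]:
    """Run the planned Spearman comparisons with Bonferroni correction.

    ``scores`` must carry ``participant_id`` plus accuracy columns
    (``iet_valence``, ``iet_arousal``); the two tables are inner-joined
    on ``participant_id``.  ``plan`` is a list of ``{"x":…, "y":…}``
    entries; an entry with ``exclude_flagged: True`` is recomputed with
    the ``flagged_ids`` participants removed (sensitivity re-run).  The
    Bonferroni multiplier is the plan size.
    """
    plan = DEFAULT_PLAN if plan is None else plan
    if not plan:
        raise ValidationError("empty comparison plan")
    df = scores.merge(questionnaires, on="participant_id", how="inner")
    m = len(plan)
    results = []
    for entry in plan:
        xn, yn = entry["x"], entry["y"]
        for col in (xn, yn):
            if col not in df.columns:
                raise ValidationError(f"plan references unknown variable {col!r}")
            if df[col].isna().all():
                raise ValidationError(f"variable {col!r} is entirely missing")
        sub = df
        if entry.get("exclude_flagged") and flagged_ids:
            kept = df[~df["participant_id"].isin(list(flagged_ids))]
            if len(kept) >= 4:      # too few raters left: keep full sample
                sub = kept
        res = spearman(sub[xn], sub[yn], x_name=xn, y_name=yn)
        res.m_comparisons = m
        res.p_bonferroni = bonferroni(res.p_uncorrected, m)
        res.label = entry.get("label")
        results.append(res)
    return results
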