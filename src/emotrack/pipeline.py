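"""End-to-end orchestration: score -> reliability -> associate -> select videos.

Every stage writes flat CSV/JSON artifacts into the output directory and
the run finishes with a machine-readable ``report.json`` plus a short
human-readable ``report.txt``.  All randomness flows from named
per-stage seeds held in :class:`PipelineConfig`, so a given
``(inputs, config)`` pair is a pure function of its outputs: running
twice produces byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    DEFAULT_PLAN,
    bootstrap_partial,
    correlation_battery,
    descriptives_table,
    permutation_test,
)
from .consensus import AccuracyTable, pool_fisher_z, score_study
from .errors import EmotrackError, ValidationError
from .io import read_questionnaires, read_ratings
from .ratings import RatingSet
from .reliability import (
    bootstrap_ci,
    difficulty_function,
    flag_inconsistent_participants,
    loo_difficulty_correlations,
    permuted_accuracy_null,
)
from .video_selection import (
    best_videos,
    crossval_correlation,
    group_split_comparison,
    min_videos_for_threshold,
    subset_effect_curve,
)


@dataclass
class PipelineConfig:
    ratings_path: str = "ratings.csv"
    questionnaires_path: str = "questionnaires.csv"
    out_dir: str = "emotrack_out"
    seed: int = 0
    # per-stage seeds; None -> derived deterministically from `seed`
    seed_reliability: Optional[int] = None
    seed_association: Optional[int] = None
    seed_video_selection: Optional[int] = None
    b_bootstrap: int = 5000
    b_null: int = 1000          # circular-shift accuracy null
    b_loo: int = 5000           # video-label null for difficulty functions
    iters_subset: int = 5000
    iters_crossval: int = 5000
    k_min: int = 5
    n_best: int = 7
    fraction: float = 0.75
    loo_consensus: bool = False
    drop_flagged: bool = True    # sensitivity re-run without flagged raters
    run_shift_null: bool = True
    plan: Optional[list] = None
    min_shift_s: float = 10.0

    def resolved(self) -> "PipelineConfig":
        ss = np.random.SeedSequence(self.seed).generate_state(3)
        out = replace(
            self,
            seed_reliability=(int(ss[0] % (2 ** 31)) if self.seed_reliability is None
                              else self.seed_reliability),
            seed_association=(int(ss[1] % (2 ** 31)) if self.seed_association is None
                              else self.seed_association),
            seed_video_selection=(int(ss[2] % (2 ** 31))
                                  if self.seed_video_selection is None
                                  else self.seed_video_selection),
        )
        return out

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    headline: list = field(default_factory=list)
    sensitivity: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)

    def to_text(self) -> str:
        lines = [f"emotrack {self.version} run report", ""]
        lines.append("headline comparisons (Spearman, Bonferroni over plan):")
        for row in self.headline:
            lines.append(
                f"  {row['x']:>12s} ~ {row['y']:<12s} rho={row['rho']:+.3f} "
                f"p={row['p_uncorrected']:.4g} p_bonf={row['p_bonferroni']:.4g}"
            )
        for key in sorted(self.stages):
            lines.append(f"stage {key}: {json.dumps(self.stages[key], sort_keys=True, default=_jsonify)}")
        if self.sensitivity:
            lines.append(f"sensitivity: {json.dumps(self.sensitivity, sort_keys=True, default=_jsonify)}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


# ----------------------------------------------------------------------

def _scores_frame(acc: AccuracyTable) -> pd.DataFrame:
    val = acc.pooled_series("valence").rename("iet_valence")
    aro = acc.pooled_series("arousal").rename("iet_arousal")
    return pd.concat([val, aro], axis=1).reset_index()


def run_pipeline(config: PipelineConfig,
                 rating_set: Optional[RatingSet] = None,
                 questionnaires: Optional[pd.DataFrame] = None) -> RunReport:
    """Execute the full analysis and write all artifacts.

    ``rating_set``/``questionnaires`` may be passed in-memory (e.g. from
    the synthetic generator); otherwise they are read from the paths in
    the config.  Returns the :class:`RunReport`, which is also written
    to ``out_dir/report.json`` and ``report.txt``.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(cfg), version=__version__)

    if rating_set is None:
        rating_set = read_ratings(cfg.ratings_path)
    if questionnaires is None:
        questionnaires = read_questionnaires(cfg.questionnaires_path)

    # ---- stage: consensus scoring ------------------------------------
    acc = score_study(rating_set, loo_consensus=cfg.loo_consensus)
    acc.cells.to_csv(out / "accuracy_cells.csv", index=False)
    acc.participant_pooled.to_csv(out / "accuracy_participant_pooled.csv", index=False)
    acc.video_pooled.to_csv(out / "accuracy_video_pooled.csv", index=False)
    cons_rows = []
    for (vid, dim), cons in sorted(acc.consensus.items()):
        block = rating_set.block(vid)
        cons_rows.append(pd.DataFrame({
            "video_id": vid, "dimension": dim,
            "t_s": block.t, "score": cons.scores,
        }))
    if cons_rows:
        pd.concat(cons_rows, ignore_index=True).to_csv(
            out / "consensus_trajectories.csv", index=False)
    _write_json(out / "missing_cells.json",
                {"missing": acc.missing, "failures": acc.failures})
    report.stages["score"] = {
        "n_participants": len(rating_set.participants),
        "n_videos": len(rating_set.videos),
        "n_cells": int(len(acc.cells)),
        "n_missing": len(acc.missing),
        "loo_consensus": cfg.loo_consensus,
    }
    if acc.failures:
        report.warnings.append(f"{len(acc.failures)} video/dimension failures")

    # ---- stage: reliability ------------------------------------------
    rel_rng = np.random.default_rng(cfg.seed_reliability)
    ci_rows = []
    for dim in ("valence", "arousal"):
        cells = acc.cell_matrix(dim)
        for pid, row in cells.iterrows():
            vals = row.dropna().to_numpy()
            if vals.size == 0:
                continue
            lo, hi = bootstrap_ci(vals, B=cfg.b_bootstrap, seed=rel_rng)
            ci_rows.append(("participant", pid, dim, pool_fisher_z(vals), lo, hi))
        for vid, col in cells.items():
            vals = col.dropna().to_numpy()
            if vals.size == 0:
                continue
            lo, hi = bootstrap_ci(vals, B=cfg.b_bootstrap, seed=rel_rng)
            ci_rows.append(("video", vid, dim, pool_fisher_z(vals), lo, hi))
    pd.DataFrame(
        ci_rows, columns=["unit", "id", "dimension", "accuracy", "ci_low", "ci_high"]
    ).to_csv(out / "accuracy_ci.csv", index=False)
    for dim in ("valence", "arousal"):
        difficulty_function(acc, dim).to_csv(
            out / f"difficulty_function_{dim}.csv", index=False)

    loo = loo_difficulty_correlations(acc, "valence", B=cfg.b_loo, seed=rel_rng)
    loo.to_csv(out / "loo_difficulty.csv", index=False)
    flagged = flag_inconsistent_participants(loo)
    _write_json(out / "flags.json", {"flagged_participants": flagged})
    pct_outside = 100.0 * float((~loo["inside_null"]).mean())
    report.stages["reliability"] = {
        "flagged_participants": flagged,
        "pct_outside_null": pct_outside,
    }
    if cfg.run_shift_null:
        nulls = permuted_accuracy_null(
            rating_set, B=cfg.b_null, seed=rel_rng, min_shift_s=cfg.min_shift_s)
        _write_json(out / "shift_null.json", {
            dim: {"mean": nd.mean, "ci95": list(nd.ci95)}
            for dim, nd in nulls.items()
        })
        report.stages["reliability"]["shift_null"] = {
            dim: {"mean": nd.mean, "ci95": list(nd.ci95)}
            for dim, nd in nulls.items()
        }

    # ---- stage: association ------------------------------------------
    scores = _scores_frame(acc)
    joined = scores.merge(questionnaires, on="participant_id", how="inner")
    desc_vars = [v for v in (
        "eyes_test", "films_task", "matrices", "vocabulary", "age", "swls",
        "eq", "aq", "stai_state", "stai_trait", "bdi", "cape_psychosis",
        "cape_depressive", "cape_negative", "cape_positive",
        "iet_valence", "iet_arousal",
    ) if v in joined.columns]
    descriptives_table(joined, desc_vars).to_csv(out / "descriptives.csv", index=False)

    plan = cfg.plan if cfg.plan is not None else DEFAULT_PLAN
    battery = correlation_battery(scores, questionnaires, plan=plan,
                                  flagged_ids=flagged)
    _write_json(out / "battery.json", [r.to_dict() for r in battery])
    report.headline = [r.to_dict() for r in battery]

    asc_rng = np.random.default_rng(cfg.seed_association)
    partial_specs = [
        ("iet_valence", "aq", ["matrices", "vocabulary"]),
        ("films_task", "aq", ["matrices", "vocabulary"]),
        ("eyes_test", "aq", ["matrices", "vocabulary"]),
        ("iet_valence", "aq", ["films_task", "eyes_test"]),
    ]
    partials = []
    for xn, yn, covs in partial_specs:
        if not all(c in joined.columns for c in [xn, yn, *covs]):
            continue
        res = bootstrap_partial(
            joined[xn], joined[yn], [joined[c] for c in covs],
            B=cfg.b_bootstrap, seed=asc_rng, x_name=xn, y_name=yn,
            covariate_names=covs,
        )
        partials.append(res.to_dict())
    _write_json(out / "partial_correlations.json", partials)
    report.stages["association"] = {"partials": partials}

    perm_results = []
    for xn in ("iet_valence", "films_task", "eyes_test"):
        if xn not in joined.columns:
            continue
        res = permutation_test(joined[xn], joined["aq"], B=cfg.b_bootstrap,
                               seed=asc_rng, x_name=xn, y_name="aq")
        perm_results.append(res.to_dict())
    _write_json(out / "permutation_tests.json", perm_results)
    report.stages["association"]["permutation_tests"] = perm_results

    # ---- stage: video selection --------------------------------------
    vs_rng = np.random.default_rng(cfg.seed_video_selection)
    cells_val = acc.cell_matrix("valence")
    aq = questionnaires.set_index("participant_id")["aq"]
    curve = subset_effect_curve(cells_val, aq, k_min=cfg.k_min,
                                iters=cfg.iters_subset, seed=vs_rng)
    pd.DataFrame({"k": curve.k, "mean_rho": curve.mean_rho}).to_csv(
        out / "subset_curve.csv", index=False)
    k_star, threshold = min_videos_for_threshold(curve, fraction=cfg.fraction)
    best, per_video = best_videos(cells_val, aq, n_best=cfg.n_best)
    per_video.to_csv(out / "per_video_rho.csv", index=False)

    best_pooled = cells_val[best].apply(
        lambda row: pool_fisher_z(row.dropna()) if row.notna().any() else np.nan,
        axis=1,
    )
    best_rho = None
    try:
        from .association import spearman as _spearman

        best_res = _spearman(best_pooled, aq.reindex(best_pooled.index),
                             x_name="iet_valence_best", y_name="aq")
        best_rho = best_res.to_dict()
    except EmotrackError:
        report.warnings.append("best-video correlation undefined")
    try:
        cv_mean, cv_ci, cv_used = crossval_correlation(
            best_pooled, aq.reindex(best_pooled.index),
            iters=cfg.iters_crossval, seed=vs_rng)
    except EmotrackError as exc:
        report.warnings.append(f"crossval skipped: {exc}")
        cv_mean, cv_ci, cv_used = None, (None, None), 0
    splits = {}
    for mode in ("median", "quartile"):
        try:
            gs = group_split_comparison(best_pooled, aq.reindex(best_pooled.index),
                                        mode, seed=vs_rng, B=cfg.b_bootstrap)
        except ValidationError as exc:
            report.warnings.append(f"{mode} split skipped: {exc}")
            continue
        splits[mode] = {
            "group_sizes": {k: len(v) for k, v in gs.groups.items()},
            "group_accuracy": gs.group_accuracy,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in gs.pairwise_p.items()},
        }
    _write_json(out / "video_selection.json", {
        "min_videos_for_threshold": k_star,
        "threshold_rho": threshold,
        "fraction": cfg.fraction,
        "full_rho": curve.full_rho,
        "best_videos": best,
        "best_rho": best_rho,
        "crossval": {"mean_rho": cv_mean, "ci95": list(cv_ci),
                     "iterations_used": cv_used},
        "splits": splits,
    })
    report.stages["video_selection"] = {
        "min_videos_for_threshold": k_star,
        "threshold_rho": threshold,
        "full_rho": curve.full_rho,
        "best_videos": best,
        "best_rho": None if best_rho is None else best_rho["rho"],
        "crossval_mean_rho": cv_mean,
        "crossval_ci95": list(cv_ci),
        "splits": splits,
    }

    # ---- sensitivity: drop flagged raters ----------------------------
    if cfg.drop_flagged and flagged and len(scores) - len(flagged) >= 4:
        keep = [p for p in scores["participant_id"] if p not in flagged]
        scores_kept = scores[scores["participant_id"].isin(keep)]
        battery_kept = correlation_battery(scores_kept, questionnaires, plan=plan,
                                           flagged_ids=None)
        head_full = next(r for r in battery
                         if r.x == "iet_valence" and r.y == "aq" and not r.label)
        head_kept = next(r for r in battery_kept
                         if r.x == "iet_valence" and r.y == "aq" and not r.label)
        report.sensitivity = {
            "dropped": flagged,
            "rho_full": head_full.rho,
            "rho_without_flagged": head_kept.rho,
            "rho_shift": abs(head_kept.rho - head_full.rho),
        }

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    return report
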