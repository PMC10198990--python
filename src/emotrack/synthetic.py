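"""Synthetic cohorts of continuous affect ratings with known ground truth.

The generator emulates a cohort of observers continuously rating the
valence and arousal of movie-clip characters on a bounded 2-D grid, with
a latent per-rater *tracking competency* that is correlated, through a
Gaussian copula, with self-report trait scores (most importantly the
Autism-Spectrum Quotient).  Every downstream stage of the pipeline —
consensus scoring, reliability diagnostics, the correlation battery and
the video-subset item analysis — can therefore be tested against a known
generating truth.

Generative model
----------------
* Each video has a latent affect course per dimension: a stationary
  Ornstein–Uhlenbeck (AR(1)) process with unit marginal variance and
  correlation time ``trajectory_smoothness_s``, squashed by ``tanh`` into
  the rating grid [-1, 1].
* Rater *p* watching video *v* reports::

      rating = gain_p * (m * latent_v + (1 - m) * distractor_pv)
               + bias_p + noise,        m = competency_p (optionally
                                        scaled per video)

  where the distractor is an independent draw of the same latent process
  (so low-competency raters are internally consistent but wrong), noise
  is white Gaussian with scale ``noise_sd``, and with probability
  ``lapse_prob`` per sample the cursor freezes and holds its previous
  position.  Ratings are clipped to the grid.
* Questionnaire totals are integerized Gaussian-copula draws matched to
  the observed location/scale/range of each instrument; AQ's latent
  score correlates with competency at ``trait_loading``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import ndtr, ndtri

from .errors import ValidationError
from .ratings import DIMENSIONS, RatingSet, VideoBlock

__all__ = [
    "SyntheticConfig",
    "INSTRUMENTS",
    "generate_latent_trajectory",
    "generate_cohort",
    "write_cohort",
]

# Observed location/scale/range per self-report or task instrument
# (mean, sd, min, max); generated totals are clipped to [min, max], which
# also keeps them within each instrument's admissible range.
INSTRUMENTS: dict[str, tuple[float, float, int, int]] = {
    "aq": (18.95, 5.13, 9, 33),
    "eq": (43.69, 12.45, 15, 68),
    "eyes_test": (25.17, 5.37, 5, 33),
    "films_task": (27.53, 3.45, 10, 32),
    "matrices": (28.61, 4.39, 12, 35),
    "vocabulary": (13.17, 3.60, 1, 20),
    "swls": (23.23, 6.62, 5, 35),
    "stai_state": (42.54, 12.08, 20, 70),
    "stai_trait": (45.86, 10.46, 20, 74),
    "bdi": (9.64, 7.89, 0, 37),
    "cape_psychosis": (72.33, 15.39, 46, 126),
    "cape_depressive": (16.96, 5.36, 7, 33),
    "cape_negative": (28.02, 7.68, 16, 61),
    "cape_positive": (27.35, 5.81, 16, 44),
}

# Default loadings of each instrument's latent score on the social factor,
# the general-intelligence factor, and competency directly.
_DEFAULT_LOADINGS: dict[str, tuple[float, float, float]] = {
    "eq": (0.90, 0.0, 0.0),
    "eyes_test": (0.45, 0.35, 0.0),
    "films_task": (0.35, 0.30, 0.20),
    "matrices": (0.0, 0.90, 0.15),
    "vocabulary": (0.0, 0.75, 0.10),
    "swls": (0.30, 0.0, 0.0),
    "stai_state": (-0.35, 0.0, -0.10),
    "stai_trait": (-0.40, 0.0, -0.10),
    "bdi": (-0.40, 0.0, -0.15),
    "cape_psychosis": (-0.35, -0.10, -0.10),
    "cape_depressive": (-0.35, 0.0, -0.10),
    "cape_negative": (-0.30, -0.10, -0.10),
    "cape_positive": (-0.25, 0.0, -0.05),
}

QUESTIONNAIRE_COLUMNS = (
    ["participant_id"] + list(INSTRUMENTS) + ["age", "gender"]
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the reference cohort: 102 participants, 35 video
    clips of 1–3 minutes each, sampled at 10 Hz, with competency loading
    on AQ at -0.4.
    """

    n_participants: int = 102
    n_videos: int = 35
    duration_range_s: tuple[float, float] = (60.0, 180.0)
    sample_hz: float = 10.0
    trajectory_smoothness_s: float = 4.0
    competency_range: tuple[float, float] = (0.25, 0.95)
    noise_sd: float = 0.2
    lapse_prob: float = 0.01
    trait_loading: float = -0.4
    gain_log_sd: float = 0.1
    bias_sd: float = 0.05
    seed: int = 0
    #: ratio of the hardest to the easiest video's noise scale; applied as
    #: a geometric ramp over videos when ``video_noise_scale`` is None so
    #: the cohort has a genuine difficulty function (set to 1 for
    #: homogeneous videos)
    video_difficulty_spread: float = 4.0
    # Optional structure used by planted-signal / difficulty-gradient
    # experiments; ``None`` means the default difficulty ramp.
    video_signal_scale: Optional[Sequence[float]] = None
    video_noise_scale: Optional[Sequence[float]] = None
    competencies: Optional[Sequence[float]] = None
    trait_loadings: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS)
    )

    def validate(self) -> "SyntheticConfig":
        if self.n_participants < 3:
            raise ValidationError("n_participants must be >= 3")
        if self.n_videos < 2:
            raise ValidationError("n_videos must be >= 2")
        if self.sample_hz <= 0:
            raise ValidationError("sample_hz must be positive")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValidationError("duration_range_s must satisfy 0 < lo <= hi")
        clo, chi = self.competency_range
        if not (0.0 <= clo <= chi <= 1.0):
            raise ValidationError("competency_range must be within [0, 1]")
        if abs(self.trait_loading) > 1:
            raise ValidationError("|trait_loading| must be <= 1")
        if self.trajectory_smoothness_s <= 0:
            raise ValidationError("trajectory_smoothness_s must be positive")
        if not (0.0 <= self.lapse_prob < 1.0):
            raise ValidationError("lapse_prob must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.video_difficulty_spread < 1:
            raise ValidationError("video_difficulty_spread must be >= 1")
        for name, vec in (
            ("video_signal_scale", self.video_signal_scale),
            ("video_noise_scale", self.video_noise_scale),
        ):
            if vec is not None and len(vec) != self.n_videos:
                raise ValidationError(f"{name} must have length n_videos")
        if self.competencies is not None:
            comp = np.asarray(self.competencies, dtype=float)
            if comp.shape != (self.n_participants,):
                raise ValidationError("competencies must have length n_participants")
            if np.any((comp < 0) | (comp > 1)):
                raise ValidationError("competencies must lie in [0, 1]")
        return self

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


# ----------------------------------------------------------------------
# Latent process
# ----------------------------------------------------------------------

def _ou_ar1(n: int, dt: float, tau: float, rng: np.random.Generator,
            cols: int = 1) -> np.ndarray:
    """Stationary unit-variance AR(1)/OU sample paths, shape (n, cols)."""
    phi = 0.0 if tau <= 0 else (1.0 if math.isinf(tau) else math.exp(-dt / tau))
    e = rng.standard_normal((n, cols))
    if phi == 1.0:                         # infinitely smooth: frozen draw
        return np.tile(e[:1], (n, 1))
    innov_sd = math.sqrt(max(0.0, 1.0 - phi * phi))
    e[1:] *= innov_sd                      # e[0] ~ N(0,1): stationary start
    if phi == 0.0:
        return e
    return signal.lfilter([1.0], [1.0, -phi], e, axis=0)


def generate_latent_trajectory(duration_s: float, sample_hz: float,
                               smoothness_s: float, seed) -> pd.DataFrame:
    """One video's latent affect course: tanh-squashed OU per dimension.

    Returns a frame with columns ``t_s, valence, arousal``; values lie in
    (-1, 1).  ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if duration_s <= 0 or sample_hz <= 0:
        raise ValidationError("duration_s and sample_hz must be positive")
    if smoothness_s <= 0:
        raise ValidationError("smoothness_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sample_hz))
    if n < 1:
        raise ValidationError("duration too short for one sample")
    dt = 1.0 / sample_hz
    x = _ou_ar1(n, dt, smoothness_s, rng, cols=len(DIMENSIONS))
    vals = np.tanh(x)
    t = np.arange(n, dtype=float) * dt
    return pd.DataFrame({"t_s": t, "valence": vals[:, 0], "arousal": vals[:, 1]})


# ----------------------------------------------------------------------
# Questionnaires
# ----------------------------------------------------------------------

def _questionnaires(rng: np.random.Generator, comp_z: np.ndarray,
                    cfg: SyntheticConfig, participant_ids: list[str]) -> pd.DataFrame:
    n = comp_z.shape[0]
    lam = cfg.trait_loading
    # Orthonormal innovation basis: (competency score, AQ residual,
    # social residual, g residual); every latent is a vector over it.
    u_aq = rng.standard_normal(n)
    u_soc = rng.standard_normal(n)
    u_g = rng.standard_normal(n)
    basis = np.column_stack([comp_z, u_aq, u_soc, u_g])  # (n, 4)

    v_comp = np.array([1.0, 0.0, 0.0, 0.0])
    v_aq = np.array([lam, math.sqrt(1 - lam * lam), 0.0, 0.0])
    v_soc = -0.6 * v_aq + np.array([0.0, 0.0, 0.8, 0.0])
    v_g = 0.45 * v_comp + np.array([0.0, 0.0, 0.0, math.sqrt(1 - 0.45 ** 2)])

    def score(name: str, vec: np.ndarray) -> np.ndarray:
        var = float(vec @ vec)
        if var > 1.0 + 1e-9:
            raise ValidationError(f"loadings for {name!r} imply variance > 1")
        resid = math.sqrt(max(0.0, 1.0 - var))
        z = basis @ vec + resid * rng.standard_normal(n)
        mean, sd, lo, hi = INSTRUMENTS[name]
        return np.clip(np.rint(mean + sd * z), lo, hi).astype(int)

    cols: dict[str, np.ndarray] = {}
    cols["aq"] = score("aq", v_aq)
    for name in INSTRUMENTS:
        if name == "aq":
            continue
        w_soc, w_g, w_comp = cfg.trait_loadings.get(name, (0.0, 0.0, 0.0))
        cols[name] = score(name, w_soc * v_soc + w_g * v_g + w_comp * v_comp)

    age = np.clip(18 + np.floor(rng.gamma(1.2, 1.8, size=n)), 18, 42).astype(int)
    gender = rng.choice(np.array(["female", "male"]), size=n, p=[0.62, 0.38])
    out = pd.DataFrame({"participant_id": participant_ids})
    for name in INSTRUMENTS:
        out[name] = cols[name]
    out["age"] = age
    out["gender"] = gender
    return out


# ----------------------------------------------------------------------
# Cohort
# ----------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig):
    """Generate a full synthetic cohort.

    Returns ``(rating_set, questionnaires, ground_truth)`` where
    ``ground_truth`` holds the per-video latent trajectories, the
    per-participant profiles (competency, gain, bias) and the config, for
    parameter-recovery tests.  Fixing ``config.seed`` fixes every value.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, V = config.n_participants, config.n_videos
    hz, dt = config.sample_hz, 1.0 / config.sample_hz
    tau = config.trajectory_smoothness_s

    vid_width = max(2, len(str(V)))
    pid_width = max(3, len(str(P)))
    video_ids = [f"V{i + 1:0{vid_width}d}" for i in range(V)]
    participant_ids = [f"P{i + 1:0{pid_width}d}" for i in range(P)]

    lo_d, hi_d = config.duration_range_s
    durations = rng.uniform(lo_d, hi_d, size=V)
    n_samples = np.maximum(2, np.rint(durations * hz).astype(int))

    latents = {
        vid: np.tanh(_ou_ar1(int(n), dt, tau, rng, cols=2))
        for vid, n in zip(video_ids, n_samples)
    }

    # Participant profiles
    clo, chi = config.competency_range
    if config.competencies is not None:
        # explicit competencies: copula latent from van der Waerden
        # normal scores of their ranks, so corr(competency, AQ) still
        # tracks trait_loading in rank terms
        from scipy.stats import rankdata

        comp = np.asarray(config.competencies, dtype=float)
        comp_z = ndtri(rankdata(comp, method="average") / (P + 1))
    else:
        comp_z = rng.standard_normal(P)
        comp = clo + (chi - clo) * ndtr(comp_z)
    gain = np.exp(rng.normal(0.0, config.gain_log_sd, size=P))
    bias = rng.normal(0.0, config.bias_sd, size=(P, 2))
    if config.gain_log_sd == 0:
        gain = np.ones(P)
    if config.bias_sd == 0:
        bias = np.zeros((P, 2))

    questionnaires = _questionnaires(rng, comp_z, config, participant_ids)

    sig_scale = (np.ones(V) if config.video_signal_scale is None
                 else np.asarray(config.video_signal_scale, dtype=float))
    if config.video_noise_scale is not None:
        noi_scale = np.asarray(config.video_noise_scale, dtype=float)
    else:
        s = config.video_difficulty_spread
        noi_scale = np.geomspace(1.0 / math.sqrt(s), math.sqrt(s), V)

    blocks: dict[str, VideoBlock] = {}
    for j, vid in enumerate(video_ids):
        n = int(n_samples[j])
        L = latents[vid]                                    # (n, 2)
        D = np.tanh(_ou_ar1(n, dt, tau, rng, cols=2 * P)).reshape(n, P, 2)
        m = np.clip(comp * sig_scale[j], 0.0, 1.0)          # (P,)
        raw = (gain[None, :, None]
               * (m[None, :, None] * L[:, None, :]
                  + (1.0 - m)[None, :, None] * D)
               + bias[None, :, :])
        if config.noise_sd > 0:
            raw = raw + (config.noise_sd * noi_scale[j]
                         * rng.standard_normal((n, P, 2)))
        if config.lapse_prob > 0:
            lapse = rng.random((n, P)) < config.lapse_prob
            lapse[0, :] = False              # first sample is always live
            idx = np.where(~lapse, np.arange(n)[:, None], 0)
            idx = np.maximum.accumulate(idx, axis=0)
            raw = raw[idx, np.arange(P)[None, :], :]
        raw = np.clip(raw, -1.0, 1.0)
        t = np.arange(n, dtype=float) * dt
        blocks[vid] = VideoBlock(
            vid, t, list(participant_ids),
            {"valence": raw[:, :, 0].copy(), "arousal": raw[:, :, 1].copy()},
        )

    profiles = pd.DataFrame(
        {
            "participant_id": participant_ids,
            "competency": comp,
            "gain": gain,
            "bias_valence": bias[:, 0],
            "bias_arousal": bias[:, 1],
        }
    )
    ground_truth = {"latents": latents, "profiles": profiles, "config": config}
    return RatingSet(blocks), questionnaires, ground_truth


def write_cohort(rating_set: RatingSet, questionnaires: pd.DataFrame, out_dir):
    """Write the long-format ratings CSV and the questionnaire CSV.

    Returns ``(ratings_path, questionnaires_path)``.  Raises before
    writing anything if the cohort is empty.
    """
    from pathlib import Path

    if not rating_set.blocks or not rating_set.participants:
        raise ValidationError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ratings_path = out / "ratings.csv"
    quest_path = out / "questionnaires.csv"
    rating_set.to_frame().to_csv(ratings_path, index=False)
    questionnaires.to_csv(quest_path, index=False)
    return ratings_path, quest_path
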