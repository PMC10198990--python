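"""File I/O contracts: long-format ratings CSV and questionnaire CSV."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .ratings import RATINGS_COLUMNS, RatingSet
from .synthetic import INSTRUMENTS

QUESTIONNAIRE_REQUIRED = list(INSTRUMENTS)


def read_ratings(path) -> RatingSet:
    """Read and validate a long-format ratings CSV.

    Required header: ``participant_id, video_id, t_s, valence, arousal``
    (one row per sample).  Enforces a uniform per-video time base,
    values in [-1, 1] and no duplicated samples; violations raise
    :class:`ValidationError` citing the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"ratings file not found: {path}")
    df = pd.read_csv(path, dtype={"participant_id": str, "video_id": str},
                     float_precision="round_trip")
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return RatingSet.from_frame(df)


def read_questionnaires(path) -> pd.DataFrame:
    """Read the per-participant questionnaire totals CSV."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"questionnaire file not found: {path}")
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ValidationError(f"{path}: missing participant_id column")
    if df["participant_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated participant_id rows")
    missing = [c for c in QUESTIONNAIRE_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing questionnaire columns {missing}")
    return df
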