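"""Consensus scoring: PCA factor scores, accuracy, Fisher-Z pooling."""

import numpy as np
import pandas as pd
import pytest

from emotrack import (
    SyntheticConfig,
    build_rating_matrix,
    compute_consensus,
    generate_cohort,
    pool_fisher_z,
    score_participant,
    score_study,
)
from emotrack.errors import (
    DegenerateInputError,
    StructuralError,
    UndefinedCorrelationError,
)
from emotrack.ratings import RatingSet


def eigen_oracle(matrix):
    """Independent consensus oracle: explicit covariance eigendecomposition
    of the standardized columns, same sign convention."""
    M = np.asarray(matrix, dtype=float)
    X = (M - M.mean(axis=0)) / M.std(axis=0)
    C = X.T @ X / X.shape[0]
    w, V = np.linalg.eigh(C)
    v = V[:, -1]
    if v.mean() < 0 or (v.mean() == 0 and v[0] < 0):
        v = -v
    return X @ v, w[-1] / np.trace(C)


class TestBuildMatrix:
    def test_shape_and_column_order(self, small_cohort):
        ratings, _, _ = small_cohort
        vid = ratings.videos[0]
        M, ids = build_rating_matrix(ratings, vid, "valence")
        block = ratings.block(vid)
        assert M.shape == (block.n_samples, 20)
        assert ids == sorted(ids)

    def test_too_few_raters(self):
        cfg = SyntheticConfig(
            n_participants=3, n_videos=2, duration_range_s=(10.0, 12.0), seed=1
        )
        ratings, _, _ = generate_cohort(cfg)
        # drop one rater's column to go below the minimum of 3
        df = ratings.to_frame()
        df = df[df["participant_id"] != "P001"]
        rs = RatingSet.from_frame(df)
        with pytest.raises(StructuralError):
            build_rating_matrix(rs, rs.videos[0], "valence")

    def test_truncated_series_names_participant(self, small_cohort):
        ratings, _, _ = small_cohort
        df = ratings.to_frame()
        vid = ratings.videos[0]
        drop = (df["participant_id"] == "P003") & (df["video_id"] == vid) & (
            df["t_s"] > 5.0
        )
        with pytest.raises(StructuralError, match="P003"):
            RatingSet.from_frame(df[~drop])


class TestComputeConsensus:
    def test_identical_raters_rank_one(self, rng):
        u = rng.standard_normal(300)
        M = np.tile(u[:, None], (1, 5))
        cons = compute_consensus(M)
        uz = (u - u.mean()) / u.std()
        r = np.corrcoef(cons.scores, uz)[0, 1]
        assert r > 1 - 1e-12
        assert cons.explained_variance_fraction == pytest.approx(1.0)
        assert np.allclose(cons.loadings, cons.loadings.iloc[0])

    def test_sign_tie_broken_toward_first_rater(self, rng):
        u = rng.standard_normal(400)
        M = np.column_stack([u, u, -u, -u])
        cons = compute_consensus(M, ["a", "b", "c", "d"])
        assert cons.loadings["a"] >= 0
        assert np.corrcoef(cons.scores, u)[0, 1] > 0

    def test_matches_eigendecomposition_oracle(self, rng):
        M = rng.standard_normal((200, 6))
        cons = compute_consensus(M)
        scores, evf = eigen_oracle(M)
        assert np.max(np.abs(cons.scores - scores)) < 1e-8
        assert cons.explained_variance_fraction == pytest.approx(evf, abs=1e-10)

    def test_zero_variance_column_dropped(self, rng):
        M = rng.standard_normal((100, 4))
        M[:, 2] = 0.7
        cons = compute_consensus(M, ["a", "b", "c", "d"])
        assert cons.dropped == ["c"]
        assert list(cons.loadings.index) == ["a", "b", "d"]

    def test_all_constant_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_consensus(np.full((50, 4), 0.3))


class TestScoreParticipant:
    def test_identity_and_antisymmetry(self, rng):
        c = rng.standard_normal(100)
        assert score_participant(c, c) == pytest.approx(1.0)
        assert score_participant(-c, c) == pytest.approx(-1.0)

    def test_noise_attenuation_closed_form(self, rng):
        # trajectory = consensus + white noise with sigma = 1 gives
        # theoretical r = (1 + sigma^2)^(-1/2) = 1/sqrt(2)
        n = 200_000
        c = rng.standard_normal(n)
        x = c + rng.standard_normal(n)
        assert score_participant(x, c) == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_flat_rater_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            score_participant(np.zeros(50), np.arange(50.0))


class TestFisherPooling:
    def test_idempotent_on_equal_values(self):
        assert pool_fisher_z([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_mean(self):
        # atanh(0.8) = ln 3, so tanh(ln(3)/2) = (3-1)/(3+1) = 0.5
        assert pool_fisher_z([0.0, 0.8]) == pytest.approx(0.5, abs=1e-12)

    def test_perfect_correlation_is_clipped_not_infinite(self):
        out = pool_fisher_z([1.0])
        assert np.isfinite(out) and out > 0.999999

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            pool_fisher_z([])


class TestScoreStudy:
    def test_flat_rater_yields_missing_cell_not_zero(self, small_cohort):
        ratings, _, _ = small_cohort
        rs = RatingSet.from_frame(ratings.to_frame())
        vid = rs.videos[0]
        block = rs.block(vid)
        j = block.participants.index("P002")
        block.values["valence"][:, j] = 0.1
        acc = score_study(rs)
        sub = acc.cells.query(
            "participant_id == 'P002' and dimension == 'valence'"
        )
        assert vid not in set(sub["video_id"])
        assert len(sub) == len(rs.videos) - 1
        assert any(
            m["participant_id"] == "P002" and m["video_id"] == vid
            for m in acc.missing
        )
        # pooled accuracy still defined from the remaining videos
        pooled = acc.pooled_series("valence")
        assert np.isfinite(pooled["P002"])

    def test_affine_rater_maps_leave_accuracy_invariant(self, small_cohort, rng):
        ratings, _, _ = small_cohort
        base = score_study(ratings)
        rs = RatingSet.from_frame(ratings.to_frame())
        for vid in rs.videos:
            block = rs.block(vid)
            p = len(block.participants)
            gains = rng.uniform(0.5, 2.0, size=p)
            offsets = rng.uniform(-0.5, 0.5, size=p)
            for dim in ("valence", "arousal"):
                block.values[dim] = block.values[dim] * gains + offsets
        transformed = score_study(rs)
        merged = base.cells.merge(
            transformed.cells, on=["participant_id", "video_id", "dimension"]
        )
        assert np.max(np.abs(merged["r_x"] - merged["r_y"])) < 1e-9

    def test_graded_competencies_recovered(self):
        cfg = SyntheticConfig(
            n_participants=50, n_videos=8, duration_range_s=(30.0, 50.0),
            noise_sd=0.1, seed=41,
        )
        ratings, _, truth = generate_cohort(cfg)
        acc = score_study(ratings)
        from scipy import stats

        pooled = acc.pooled_series("valence")
        comp = truth["profiles"].set_index("participant_id")["competency"]
        rho = stats.spearmanr(pooled, comp.reindex(pooled.index)).statistic
        assert rho > 0.9

    def test_phantom_consensus_rater_is_benign(self, rng):
        # appending the consensus itself as an extra rater barely moves
        # anyone's accuracy at n = 50
        M = rng.standard_normal((400, 1)) + 0.8 * rng.standard_normal((400, 50))
        cons = compute_consensus(M)
        r_before = np.array([score_participant(M[:, j], cons.scores)
                             for j in range(50)])
        M2 = np.column_stack([M, cons.scores])
        cons2 = compute_consensus(M2)
        r_after = np.array([score_participant(M2[:, j], cons2.scores)
                            for j in range(50)])
        assert np.all(np.sign(r_after) == np.sign(r_before))
        assert np.max(r_after - r_before) < 0.01

    def test_leave_in_vs_leave_out_gap_is_small(self):
        cfg = SyntheticConfig(
            n_participants=30, n_videos=5, duration_range_s=(30.0, 40.0), seed=43
        )
        ratings, _, _ = generate_cohort(cfg)
        leave_in = score_study(ratings, loo_consensus=False)
        leave_out = score_study(ratings, loo_consensus=True)
        merged = leave_in.cells.merge(
            leave_out.cells, on=["participant_id", "video_id", "dimension"]
        )
        assert np.max(np.abs(merged["r_x"] - merged["r_y"])) < 0.05
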