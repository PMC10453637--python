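"""Score tables, the surrogate scorer, frame sampling, and bootstrap summaries."""

import numpy as np
import pytest

from metastab.errors import ComparabilityError, CoverageError, ScoreTableFormatError
from metastab.stability import (
    ResidueScoreTable,
    compare_variants,
    local_energy_summary,
    read_score_table,
    sample_state_frames,
    surrogate_score_frame,
    write_score_table,
)
from metastab.states import fit_kmeans, Projection
from metastab.synthetic_data import simulate_score_table
from metastab.traj_io import ResidueSelection

from conftest import atom, toy_trajectory


def _table(scores, positions=(1, 2), units="arbitrary"):
    scores = np.asarray(scores, dtype=float)
    return ResidueScoreTable(
        frame_ids=tuple(range(scores.shape[0])),
        residue_positions=tuple(positions),
        scores=scores,
        units=units,
    )


class TestScoreTableIO:
    def test_parse_shape(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("frame\t10\t11\n0\t0.5\t1.5\n1\t0.25\t-1.0\n2\t0\t0\n")
        table = read_score_table(p)
        assert table.scores.shape == (3, 2)
        assert table.residue_positions == (10, 11)

    def test_round_trip(self, tmp_path, rng):
        table = _table(rng.normal(size=(5, 2)))
        p = tmp_path / "t.tsv"
        write_score_table(table, p)
        back = read_score_table(p)
        assert back.residue_positions == table.residue_positions
        assert np.array_equal(back.scores, table.scores)

    def test_ragged_row_reports_row_number(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("frame\t1\t2\n0\t0.5\n")
        with pytest.raises(ScoreTableFormatError, match="row 2"):
            read_score_table(p)

    def test_non_numeric_cell(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("frame\t1\n0\tabc\n")
        with pytest.raises(ScoreTableFormatError, match="row 2"):
            read_score_table(p)

    def test_duplicate_frame_id(self):
        with pytest.raises(ScoreTableFormatError, match="duplicated"):
            ResidueScoreTable(
                frame_ids=(0, 0), residue_positions=(1,), scores=np.zeros((2, 1))
            )


class TestSurrogateScorer:
    def test_isolated_residue_scores_zero(self):
        atoms = [atom(resid=1), atom(resid=2)]
        traj = toy_trajectory([[(0, 0, 0), (50, 0, 0)]], atoms)
        scores = surrogate_score_frame(traj, 0)
        assert scores == {1: 0.0, 2: 0.0}

    def test_contact_at_sigma_gives_well_depth(self):
        # single C-C pair at exactly sigma = 3.4 A: pair term is -epsilon = -0.05
        atoms = [atom(resid=1), atom(resid=2)]
        traj = toy_trajectory([[(0, 0, 0), (3.4, 0, 0)]], atoms)
        scores = surrogate_score_frame(traj, 0)
        assert scores[1] == pytest.approx(-0.05, abs=1e-12)
        assert scores[2] == pytest.approx(-0.05, abs=1e-12)

    def test_clash_capped_at_ten(self):
        atoms = [atom(resid=1), atom(resid=2)]
        traj = toy_trajectory([[(0, 0, 0), (2.0, 0, 0)]], atoms)
        scores = surrogate_score_frame(traj, 0)
        # raw 12-6 value 0.05*(582.62 - 48.28) ~ 26.7, capped
        assert scores[1] == pytest.approx(10.0)

    def test_backbone_hbond_credited_to_both_partners(self):
        def pair_scores(sep):
            atoms = [
                atom(name="N", element="N", resid=1),
                atom(name="O", element="O", resid=1 + sep),
            ]
            traj = toy_trajectory([[(0, 0, 0), (2.9, 0, 0)]], atoms)
            return surrogate_score_frame(traj, 0)

        bonded = pair_scores(3)  # separation 3 >= 2: hydrogen bond counts
        unbonded = pair_scores(1)  # separation 1: same packing, no bond
        assert bonded[1] == pytest.approx(unbonded[1] - 0.5, abs=1e-12)
        assert bonded[4] == pytest.approx(bonded[1])  # symmetric credit

    def test_adjacent_residues_no_hbond(self):
        atoms = [
            atom(name="N", element="N", resid=1),
            atom(name="O", element="O", resid=2),
        ]
        traj = toy_trajectory([[(0, 0, 0), (20.0, 0, 0)]], atoms)
        scores = surrogate_score_frame(traj, 0)
        assert scores == {1: 0.0, 2: 0.0}

    def test_unknown_element_rejected(self):
        atoms = [atom(element="Fe", resid=1), atom(resid=2)]
        traj = toy_trajectory([[(0, 0, 0), (3, 0, 0)]], atoms)
        with pytest.raises(KeyError, match="radius"):
            surrogate_score_frame(traj, 0)

    def test_engineered_clash_raises_neighborhood_energy(self, rng):
        """Two-conformation toy: the clashed conformation scores less favorably."""
        worse = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            atoms = [atom(resid=1), atom(resid=2), atom(resid=3)]
            good = np.array([(0, 0, 0), (3.6, 0, 0), (7.2, 0, 0)])
            bad = good.copy()
            bad[1, 0] = 2.2  # clash with residue 1
            frames = np.stack([good + r.normal(scale=0.01, size=good.shape),
                               bad + r.normal(scale=0.01, size=good.shape)])
            traj = toy_trajectory(frames, atoms)
            a = sum(surrogate_score_frame(traj, 0).values())
            b = sum(surrogate_score_frame(traj, 1).values())
            worse += b > a
        assert worse == 10


class TestSampleStateFrames:
    def _model(self, labels):
        labels = np.asarray(labels)
        k = labels.max() + 1
        counts = np.bincount(labels, minlength=k)
        from metastab.states import StateModel

        return StateModel(
            k=int(k),
            centroids=np.zeros((k, 2)),
            labels=labels,
            inertia=0.0,
            occupancies=counts / labels.size,
            seed=0,
        )

    def test_stride_takes_every_fifth(self):
        model = self._model(np.zeros(1000, dtype=int))
        frames = sample_state_frames(model, 0, n=200)
        assert np.array_equal(frames, np.arange(0, 1000, 5))

    def test_shortfall_returns_all_with_warning(self):
        model = self._model(np.zeros(150, dtype=int))
        with pytest.warns(UserWarning, match="150"):
            frames = sample_state_frames(model, 0, n=200)
        assert frames.size == 150

    def test_random_policy_deterministic(self):
        model = self._model(np.zeros(1000, dtype=int))
        a = sample_state_frames(model, 0, n=200, seed=3, policy="random")
        b = sample_state_frames(model, 0, n=200, seed=3, policy="random")
        assert np.array_equal(a, b)
        assert np.unique(a).size == 200

    def test_bad_n(self):
        model = self._model(np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            sample_state_frames(model, 0, n=0)


class TestLocalEnergySummary:
    def test_constant_scores_collapse_ci(self):
        table = _table(np.tile([0.1, 0.2], (5, 1)))
        nb = ResidueSelection((1, 2), focal=1)
        s = local_energy_summary(table, range(5), nb, n_boot=100, seed=0)
        assert s.per_frame_sums == pytest.approx([0.3] * 5)
        assert (s.mean, s.ci_low, s.ci_high) == pytest.approx((0.3, 0.3, 0.3))

    def test_missing_position_is_coverage_error(self):
        table = _table(np.zeros((3, 2)))
        nb = ResidueSelection((1, 2, 9), focal=1)
        with pytest.raises(CoverageError):
            local_energy_summary(table, range(3), nb)

    def test_normal_ci_half_width_matches_clt(self):
        r = np.random.default_rng(8)
        table = _table(r.normal(0, 1, size=(200, 1)), positions=(1,))
        nb = ResidueSelection((1,), focal=1)
        s = local_energy_summary(table, range(200), nb, n_boot=1000, seed=2)
        half_width = (s.ci_high - s.ci_low) / 2
        assert half_width == pytest.approx(1.96 / np.sqrt(200), abs=0.03)

    def test_linearity_under_scaling(self, rng):
        scores = rng.normal(size=(50, 2))
        nb = ResidueSelection((1, 2), focal=1)
        s1 = local_energy_summary(_table(scores), range(50), nb, n_boot=500, seed=4)
        s3 = local_energy_summary(_table(3.0 * scores), range(50), nb, n_boot=500, seed=4)
        assert s3.mean == pytest.approx(3 * s1.mean, rel=1e-12)
        assert s3.ci_low == pytest.approx(3 * s1.ci_low, rel=1e-9)
        assert s3.ci_high == pytest.approx(3 * s1.ci_high, rel=1e-9)


class TestCompareVariants:
    def _planted_pair(self, seed=0):
        nb = ResidueSelection((1, 2, 3), focal=2)
        tables, _ = simulate_score_table(
            200, nb, {"A": 0.32, "B": 1.35}, noise_sigma=0.1, seed=seed
        )
        a = local_energy_summary(tables["A"], range(200), nb, n_boot=1000, seed=seed)
        b = local_energy_summary(tables["B"], range(200), nb, n_boot=1000, seed=seed)
        return a, b

    def test_self_comparison_spans_zero(self):
        a, _ = self._planted_pair()
        report = compare_variants(a, a)
        assert report["mean_difference"] == 0.0
        assert report["difference_ci"][0] <= 0.0 <= report["difference_ci"][1]
        assert report["individual_cis_overlap"]

    def test_planted_contrast_recovered(self):
        a, b = self._planted_pair(seed=5)
        report = compare_variants(a, b)
        assert report["mean_difference"] == pytest.approx(1.03, abs=0.05)
        assert not report["individual_cis_overlap"]
        assert report["difference_excludes_zero"]

    def test_mismatched_neighborhoods_rejected(self):
        nb1 = ResidueSelection((1, 2), focal=1)
        nb2 = ResidueSelection((1, 2, 3), focal=1)
        s1 = local_energy_summary(_table(np.ones((4, 2))), range(4), nb1, n_boot=10)
        s2 = local_energy_summary(
            _table(np.ones((4, 3)), positions=(1, 2, 3)), range(4), nb2, n_boot=10
        )
        with pytest.raises(ComparabilityError):
            compare_variants(s1, s2)

    def test_mismatched_units_rejected(self):
        nb = ResidueSelection((1, 2), focal=1)
        s1 = local_energy_summary(_table(np.ones((4, 2)), units="REU"), range(4), nb, n_boot=10)
        s2 = local_energy_summary(
            _table(np.ones((4, 2)), units="surrogate"), range(4), nb, n_boot=10
        )
        with pytest.raises(ComparabilityError):
            compare_variants(s1, s2)
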