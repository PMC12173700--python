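"""Data model, I/O round-trips and quality-control transformations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connodiff.connectomes import (
    DMRI,
    RSFMRI,
    UNITS_COUNT,
    UNITS_R,
    UNITS_Z,
    Atlas,
    Connectome,
    Parcel,
    SubjectRecord,
    apply_dmri_threshold,
    apply_rsfmri_threshold,
    default_atlas,
    fisher_z_transform,
    motion_exclude,
    n_node_pairs,
    read_connectome,
    read_matrix,
    symmetrize,
    upper_vector,
    vector_to_matrix,
    write_connectome,
    write_matrix,
)


def _count_connectome(values, sid="s1"):
    return Connectome(subject_id=sid, modality=DMRI, values=np.asarray(values, float), units=UNITS_COUNT)


def _r_connectome(values, sid="s1"):
    return Connectome(subject_id=sid, modality=RSFMRI, values=np.asarray(values, float), units=UNITS_R)


class TestAtlas:
    def test_node_ids_must_be_contiguous(self):
        with pytest.raises(ValueError):
            Atlas((Parcel(1, "L"), Parcel(3, "R")))

    def test_hemisphere_validated(self):
        with pytest.raises(ValueError):
            Parcel(1, "X")

    def test_tsv_round_trip(self, tmp_path):
        atlas = default_atlas(20)
        atlas.to_tsv(tmp_path / "atlas.tsv")
        back = Atlas.from_tsv(tmp_path / "atlas.tsv")
        assert back == atlas
        assert back.n_pairs == 190


class TestMatrixIO:
    def test_zero_tsv(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_matrix(p, np.zeros((3, 3)))
        assert np.array_equal(read_matrix(p), np.zeros((3, 3)))

    def test_matrix_market_sparse_entries(self, tmp_path):
        p = tmp_path / "m.mtx"
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 5.0
        write_matrix(p, m)
        assert np.array_equal(read_matrix(p), m)

    @pytest.mark.parametrize("fmt,ext", [("dense-tsv", "tsv"), ("matrix-market", "mtx")])
    def test_round_trip_exact(self, tmp_path, rng, fmt, ext):
        m = rng.standard_normal((10, 10))
        p = tmp_path / f"m.{ext}"
        write_matrix(p, m, format=fmt)
        assert np.array_equal(read_matrix(p, format=fmt), m)

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        np.savetxt(p, np.zeros((2, 3)), delimiter="\t")
        with pytest.raises(ValueError, match="square"):
            read_matrix(p)

    def test_dimension_mismatch_vs_atlas(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_matrix(p, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="expected 5"):
            read_matrix(p, n_expected=5)

    def test_connectome_sidecar_round_trip(self, tmp_path, rng):
        m = np.abs(rng.standard_normal((6, 6)))
        m = symmetrize(m)
        c = _count_connectome(m, sid="sub-42")
        write_connectome(tmp_path / "c.tsv", c)
        back = read_connectome(tmp_path / "c.tsv")
        assert back.subject_id == "sub-42"
        assert back.units == UNITS_COUNT
        assert np.array_equal(back.values, c.values)


class TestSymmetrize:
    def test_already_symmetric_unchanged_except_diagonal(self, rng):
        m = rng.random((5, 5))
        m = m + m.T
        out = symmetrize(m, "mean")
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(out[off], m[off])
        assert np.all(np.diag(out) == 0)

    def test_mean_of_directions(self):
        m = np.zeros((3, 3))
        m[0, 1], m[1, 0] = 4.0, 6.0
        out = symmetrize(m, "mean")
        assert out[0, 1] == out[1, 0] == 5.0

    def test_matches_formula(self, rng):
        m = rng.standard_normal((8, 8))
        expected = (m + m.T) / 2
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(symmetrize(m, "mean"), expected)

    @pytest.mark.parametrize("method", ["min", "max"])
    def test_min_max(self, method):
        m = np.array([[0.0, 4.0], [6.0, 0.0]])
        v = symmetrize(m, method)[0, 1]
        assert v == (4.0 if method == "min" else 6.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            symmetrize(np.zeros((2, 3)))


class TestThresholds:
    def test_count_threshold_keeps_at_boundary(self):
        c = _count_connectome(symmetrize(np.full((3, 3), 9.0)))
        c.values[0, 1] = c.values[1, 0] = 10.0
        out = apply_dmri_threshold(c)
        assert out.values[0, 1] == 10.0  # "thresholded at 10" keeps 10
        assert out.values[0, 2] == 0.0  # 9 is removed

    def test_all_zero_stays_zero(self):
        out = apply_dmri_threshold(_count_connectome(np.zeros((4, 4))))
        assert not out.values.any()

    def test_wrong_units_rejected(self):
        with pytest.raises(ValueError):
            apply_dmri_threshold(_r_connectome(np.zeros((3, 3))))
        with pytest.raises(ValueError):
            apply_rsfmri_threshold(_count_connectome(np.zeros((3, 3))))

    def test_correlation_threshold_strict(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.05  # exactly at the cut: removed
        m[0, 2] = m[2, 0] = -0.06  # above in magnitude: kept with sign
        out = apply_rsfmri_threshold(_r_connectome(m))
        assert out.values[0, 1] == 0.0
        assert out.values[0, 2] == -0.06

    def test_subthreshold_matrix_zeroed(self):
        m = symmetrize(np.full((4, 4), 0.04) * np.sign(np.random.default_rng(0).standard_normal((4, 4))))
        out = apply_rsfmri_threshold(_r_connectome(np.clip(m, -0.04, 0.04)))
        assert not out.values.any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_shrinking(self, seed):
        rng = np.random.default_rng(seed)
        counts = _count_connectome(symmetrize(rng.integers(0, 30, (6, 6)).astype(float)))
        once = apply_dmri_threshold(counts)
        twice = apply_dmri_threshold(once)
        assert np.array_equal(once.values, twice.values)
        assert np.all(np.abs(once.values) <= np.abs(counts.values))
        rs = _r_connectome(symmetrize(rng.uniform(-0.9, 0.9, (6, 6))))
        once_r = apply_rsfmri_threshold(rs)
        assert np.array_equal(once_r.values, apply_rsfmri_threshold(once_r).values)
        assert np.all(np.abs(once_r.values) <= np.abs(rs.values))


class TestFisherZ:
    def test_closed_form(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.5
        m[0, 2] = m[2, 0] = -0.5
        out = fisher_z_transform(_r_connectome(m))
        assert out.units == UNITS_Z
        assert out.values[0, 1] == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        assert out.values[0, 2] == pytest.approx(-0.5 * np.log(3.0), abs=1e-12)
        assert out.values[1, 2] == 0.0  # zeros stay zero

    def test_monotone_and_odd_on_grid(self):
        r = np.linspace(-0.95, 0.95, 39)
        n = r.size + 1
        m = np.zeros((n, n))
        m[0, 1:] = r
        m[1:, 0] = r
        z = fisher_z_transform(_r_connectome(m)).values[0, 1:]
        assert np.all(np.diff(z) > 0)
        m_neg = np.zeros((n, n))
        m_neg[0, 1:] = -r
        m_neg[1:, 0] = -r
        z_neg = fisher_z_transform(_r_connectome(m_neg)).values[0, 1:]
        assert np.allclose(z_neg, -z)

    def test_r_of_one_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(ValueError):
            fisher_z_transform(_r_connectome(m))


def _subject(sid, motion, group="A"):
    return SubjectRecord(subject_id=sid, group_label=group, motion_summary={DMRI: motion})


class TestMotionExclude:
    def test_identical_motion_nobody_excluded(self):
        subs = [_subject(f"s{i}", 0.2) for i in range(10)]
        kept, excluded = motion_exclude(subs, DMRI)
        assert len(kept) == 10 and not excluded

    def test_single_outlier_excluded(self):
        # {0.1 x 9, 1.0}: mean 0.19, sample SD 0.2846, cutoff 0.4746
        subs = [_subject(f"s{i}", 0.1) for i in range(9)] + [_subject("mover", 1.0)]
        kept, excluded = motion_exclude(subs, DMRI)
        assert [s.subject_id for s in excluded] == ["mover"]
        assert len(kept) == 9

    def test_one_sided_rule_ignores_low_movers(self):
        subs = [_subject(f"s{i}", 0.5) for i in range(9)] + [_subject("still", 0.001)]
        kept, excluded = motion_exclude(subs, DMRI, sided="upper")
        assert not excluded
        _, excluded_both = motion_exclude(subs, DMRI, sided="both")
        assert [s.subject_id for s in excluded_both] == ["still"]

    def test_partition_is_exact(self, rng):
        subs = [_subject(f"s{i}", float(v)) for i, v in enumerate(rng.random(25))]
        kept, excluded = motion_exclude(subs, DMRI)
        assert sorted(s.subject_id for s in kept + excluded) == sorted(s.subject_id for s in subs)
        assert not {s.subject_id for s in kept} & {s.subject_id for s in excluded}

    def test_per_group_reference(self):
        subs = [_subject(f"a{i}", 0.1, "A") for i in range(5)] + [
            _subject(f"b{i}", 5.0, "B") for i in range(4)
        ] + [_subject("b_mover", 9.0, "B")]
        kept, excluded = motion_exclude(subs, DMRI, pooled=False)
        assert [s.subject_id for s in excluded] == ["b_mover"]

    def test_missing_summary_rejected(self):
        subs = [_subject("s0", 0.1), SubjectRecord(subject_id="s1", group_label="A")]
        with pytest.raises(ValueError):
            motion_exclude(subs, DMRI)


class TestPairCounting:
    @pytest.mark.parametrize("n,expected", [(333, 55278), (2, 1), (10, 45)])
    def test_values(self, n, expected):
        assert n_node_pairs(n) == expected

    def test_ten_matches_enumeration(self):
        pairs = {(i, j) for i in range(10) for j in range(i + 1, 10)}
        assert n_node_pairs(10) == len(pairs)

    def test_too_small(self):
        with pytest.raises(ValueError):
            n_node_pairs(1)


class TestEdgeVectorisation:
    def test_upper_vector_round_trip(self, rng):
        m = symmetrize(rng.standard_normal((7, 7)))
        assert np.allclose(vector_to_matrix(upper_vector(m), 7), m)
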