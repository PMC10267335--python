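"""Contact-occupancy statistics: worked examples and oracle properties."""

import numpy as np
import pytest
import biotite.structure as struc

from theratype.trajectory import (
    AtomSelector,
    ContactMetricSpec,
    DistanceSeries,
    LAMBDA_METRIC,
    SIGMA_METRIC,
    contact_fraction,
    distance_series_from_models,
    pooled_contact_fraction,
    read_distance_csv,
    summarize_distances,
)
from theratype.synthetic import gen_distance_series


def _two_atom_stack(coords_per_model):
    """Stack of models each holding residue-551 N and an ATP PG atom."""
    n_models = len(coords_per_model)
    atoms = struc.AtomArray(2)
    atoms.atom_name = np.array(["N", "PG"])
    atoms.res_name = np.array(["GLY", "ATP"])
    atoms.res_id = np.array([551, 9001])
    atoms.chain_id = np.array(["A", "A"])
    atoms.element = np.array(["N", "P"])
    stack = struc.stack([atoms] * n_models)
    stack.coord = np.array(coords_per_model, dtype=float)
    return stack


def _series(distances, metric=SIGMA_METRIC, rep="r1"):
    return DistanceSeries(
        metric=metric,
        replicate_id=rep,
        times=np.arange(len(distances), dtype=float),
        distances=np.asarray(distances, dtype=float),
    )


class TestDistanceFromModels:
    def test_three_four_five_triangle(self):
        stack = _two_atom_stack([[[0, 0, 0], [3, 4, 0]]])
        series = distance_series_from_models(stack, LAMBDA_METRIC)
        assert series.distances == pytest.approx([5.0])

    def test_coincident_atoms_zero_distance(self):
        stack = _two_atom_stack([[[1, 1, 1], [1, 1, 1]]] * 2)
        series = distance_series_from_models(stack, LAMBDA_METRIC)
        assert series.distances == pytest.approx([0.0, 0.0])

    def test_stepping_partner_atom(self):
        coords = [[[0, 0, 0], [0, 0, z]] for z in range(1, 6)]
        series = distance_series_from_models(_two_atom_stack(coords), LAMBDA_METRIC)
        assert series.distances == pytest.approx([1, 2, 3, 4, 5])

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(4, 2, 3))
        shifted = coords + np.array([10.0, -3.0, 7.5])
        d0 = distance_series_from_models(_two_atom_stack(coords), LAMBDA_METRIC)
        d1 = distance_series_from_models(_two_atom_stack(shifted), LAMBDA_METRIC)
        assert d0.distances == pytest.approx(d1.distances)

    def test_missing_atom_names_frame_and_selector(self):
        stack = _two_atom_stack([[[0, 0, 0], [1, 0, 0]]])
        bad = ContactMetricSpec(
            name="x",
            atom_a=AtomSelector(res_id=999, atom_name="N"),
            atom_b=AtomSelector(atom_name="PG"),
            threshold=5.0,
        )
        with pytest.raises(ValueError, match="model 0.*res_id=999"):
            distance_series_from_models(stack, bad)

    def test_time_count_mismatch(self):
        stack = _two_atom_stack([[[0, 0, 0], [1, 0, 0]]] * 3)
        with pytest.raises(ValueError, match="frame times"):
            distance_series_from_models(stack, LAMBDA_METRIC, frame_times=[0.0, 1.0])

    def test_pdb_file_round_trip(self, tmp_path):
        import biotite.structure.io.pdb as pdb

        stack = _two_atom_stack([[[0, 0, 0], [3, 4, 0]], [[0, 0, 0], [0, 0, 2]]])
        f = pdb.PDBFile()
        f.set_structure(stack)
        path = tmp_path / "models.pdb"
        f.write(str(path))
        series = distance_series_from_models(path, LAMBDA_METRIC)
        assert series.distances == pytest.approx([5.0, 2.0], abs=1e-3)


class TestContactFraction:
    def test_all_below(self):
        assert contact_fraction(_series([4.0, 4.5, 4.9, 4.2]), 5.0) == 1.0

    def test_half_below(self):
        assert contact_fraction(_series([4, 6, 4, 6]), 5.0) == 0.5

    def test_tie_at_threshold_counts_as_no_contact(self):
        assert contact_fraction(_series([5.0, 4.0]), 5.0) == 0.5

    def test_matches_brute_force_count_on_random_series(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n = int(rng.integers(1, 200))
            d = rng.uniform(0, 15, size=n)
            thr = float(rng.uniform(0.1, 15))
            expected = sum(1 for x in d if x < thr) / n
            assert contact_fraction(_series(d), thr) == pytest.approx(expected)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        s = _series(rng.uniform(0, 12, size=300))
        fracs = [contact_fraction(s, t) for t in np.linspace(0.5, 14, 30)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_two_state_generator_occupancy_recovery(self):
        # binomial-SD bound requires per-frame-independent state draws
        # (switch_rate=1) and state means well clear of the threshold
        p, n = 0.57, 10_000
        series, _ = gen_distance_series(
            seed=99, occupancy=p, contact_mean=4.0, contact_sd=0.3,
            disrupted_mean=10.7, disrupted_sd=0.9, n_frames=n, switch_rate=1.0,
        )
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert contact_fraction(series, 7.0) == pytest.approx(p, abs=tol)


class TestPooling:
    def test_all_in_contact(self):
        series = [_series([3.0] * 10, rep=f"r{i}") for i in range(3)]
        assert pooled_contact_fraction(series, 7.0) == 1.0

    def test_equal_length_equal_weight(self):
        series = [_series([1.0] * 50), _series([9.0] * 50)]
        assert pooled_contact_fraction(series, 5.0) == 0.5

    def test_frame_weighted_not_mean_of_fractions(self):
        series = [_series([1.0] * 100), _series([9.0] * 300)]
        assert pooled_contact_fraction(series, 5.0) == pytest.approx(0.25)

    def test_identical_replicates_equal_single(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0, 12, 80)
        single = contact_fraction(_series(d), 7.0)
        pooled = pooled_contact_fraction([_series(d, rep=f"r{i}") for i in range(4)], 7.0)
        assert pooled == pytest.approx(single)

    def test_mixed_metrics_rejected(self):
        with pytest.raises(ValueError, match="mixed metrics"):
            pooled_contact_fraction(
                [_series([1.0], metric=SIGMA_METRIC), _series([1.0], metric=LAMBDA_METRIC)]
            )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_contact_fraction([])


class TestSummarize:
    def test_constant_series(self):
        s = summarize_distances([_series([5.0] * 20)])
        assert s.mean_distance == 5.0
        assert s.sd_distance == 0.0
        assert s.n_frames_total == 20

    def test_two_point_sample_sd(self):
        s = summarize_distances([_series([3.0, 5.0])])
        assert s.mean_distance == pytest.approx(4.0)
        assert s.sd_distance == pytest.approx(np.sqrt(2), abs=0.005)

    def test_recovers_configured_distance_distribution(self):
        series, _ = gen_distance_series(
            seed=11, occupancy=1.0, contact_mean=6.6, contact_sd=0.2, n_frames=10_000
        )
        s = summarize_distances([series])
        assert s.mean_distance == pytest.approx(6.6, abs=0.05)
        assert s.sd_distance == pytest.approx(0.2, abs=0.05)


def test_distance_csv_round_trip(tmp_path):
    import pandas as pd

    rows = []
    for rep in ("r1", "r2"):
        for t, d in enumerate([3.0, 8.0, 4.0]):
            rows.append(
                {"time_ns": t, "distance_angstrom": d, "replicate_id": rep,
                 "metric": "sigma"}
            )
    path = tmp_path / "d.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    series = read_distance_csv(path, SIGMA_METRIC)
    assert len(series) == 2
    assert pooled_contact_fraction(series, 7.0) == pytest.approx(4 / 6)
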