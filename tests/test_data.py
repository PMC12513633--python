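"""Containers, file round-trips, splitting, seed plumbing."""

import numpy as np
import pytest

from endnsde.data import (ExtrinsicParamGrid, GridEntry, RunConfig,
                          TrajectoryEnsemble, read_ensemble, read_grid,
                          split_grid, substream, write_ensemble, write_grid)


class TestEnsembleInvariants:
    def test_rejects_decreasing_times(self, rng):
        with pytest.raises(ValueError, match="strictly increasing"):
            TrajectoryEnsemble(times=[0.0, 0.5, 0.5],
                               values=rng.normal(size=(2, 3, 1)), omega=[0.1])

    def test_rejects_nan_with_index(self, rng):
        values = rng.normal(size=(2, 3, 2))
        values[1, 2, 0] = np.nan
        with pytest.raises(ValueError, match="trajectory 1, time index 2, component 0"):
            TrajectoryEnsemble(times=[0, 1, 2], values=values, omega=[0.1])

    def test_rejects_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            TrajectoryEnsemble(times=[0, 1], values=rng.normal(size=(2, 3, 1)),
                               omega=[0.1])


class TestRoundTrip:
    @pytest.mark.parametrize("fmt,suffix", [("columnar-text", ".csv"),
                                            ("hierarchical-binary", ".h5")])
    def test_write_read_identity(self, small_ensemble, tmp_path, fmt, suffix):
        path = write_ensemble(small_ensemble, tmp_path / f"ens{suffix}", fmt)
        back = read_ensemble(path)
        assert back.allclose(small_ensemble)
        assert back.state_labels == small_ensemble.state_labels
        assert back.param_labels == small_ensemble.param_labels

    def test_simulated_ensemble_round_trip(self, tmp_path):
        from endnsde import circadian
        ens = circadian.simulate(circadian.CircadianParams(sigma0=0.2, c=0.4),
                                 (0, 1), np.linspace(0, 1, 11), 50, seed=3)
        back = read_ensemble(write_ensemble(ens, tmp_path / "c.csv", "columnar-text"))
        assert back.allclose(ens)
        assert back.n_traj == 50

    def test_nan_rejected_on_write(self, small_ensemble, tmp_path):
        bad = TrajectoryEnsemble.__new__(TrajectoryEnsemble)
        bad.__dict__.update(small_ensemble.__dict__)
        bad.values = small_ensemble.values.copy()
        bad.values[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            write_ensemble(bad, tmp_path / "bad.csv", "columnar-text")

    def test_shuffled_rows_give_same_ensemble(self, small_ensemble, tmp_path, rng):
        """Columnar text is order-invariant: rows may arrive shuffled."""
        path = write_ensemble(small_ensemble, tmp_path / "e.csv", "columnar-text")
        lines = path.read_text().strip().split("\n")
        header, cols, rows = lines[0], lines[1], lines[2:]
        rng.shuffle(rows)
        shuffled = tmp_path / "shuffled.csv"
        shuffled.write_text("\n".join([header, cols] + rows) + "\n")
        assert read_ensemble(shuffled).allclose(small_ensemble)

    def test_ragged_grid_rejected(self, small_ensemble, tmp_path):
        path = write_ensemble(small_ensemble, tmp_path / "e.csv", "columnar-text")
        lines = path.read_text().strip().split("\n")
        bad = tmp_path / "ragged.csv"
        bad.write_text("\n".join(lines[:-1]) + "\n")  # drop one row
        with pytest.raises(ValueError):
            read_ensemble(bad)

    def test_grid_round_trip(self, small_ensemble, tmp_path):
        other = TrajectoryEnsemble(times=small_ensemble.times,
                                   values=small_ensemble.values + 1.0,
                                   omega=[0.3, 0.4])
        grid = ExtrinsicParamGrid(entries=[
            GridEntry(small_ensemble.omega, small_ensemble, "train"),
            GridEntry(other.omega, other, "test")],
            metadata={"system": "toy"})
        back = read_grid(write_grid(grid, tmp_path / "grid.h5"))
        assert len(back.entries) == 2
        assert back.metadata["system"] == "toy"
        assert back.entries[1].split == "test"
        assert back.entries[0].ensemble.allclose(small_ensemble)


class TestSplitGrid:
    def _grid(self, rng, n_omegas=4, n_traj=10):
        entries = []
        for k in range(n_omegas):
            ens = TrajectoryEnsemble(times=[0.0, 1.0],
                                     values=rng.normal(size=(n_traj, 2, 1)),
                                     omega=[float(k)])
            entries.append(GridEntry(ens.omega, ens, "train"))
        return ExtrinsicParamGrid(entries=entries)

    def test_partition_and_heldout(self, rng):
        grid = self._grid(rng)
        out = split_grid(grid, heldout_omegas=[(3.0,)], within_fraction=0.5, seed=9)
        held = [e for e in out.entries if e.split == "heldout"]
        assert len(held) == 1 and held[0].omega_key == (3.0,)
        for key in [(0.0,), (1.0,), (2.0,)]:
            tr = [e for e in out.entries if e.omega_key == key and e.split == "train"]
            te = [e for e in out.entries if e.omega_key == key and e.split == "test"]
            assert tr[0].ensemble.n_traj == 5 and te[0].ensemble.n_traj == 5
            # partition: every original trajectory appears exactly once
            combined = np.concatenate([tr[0].ensemble.values, te[0].ensemble.values])
            orig = next(e for e in grid.entries if e.omega_key == key).ensemble.values
            assert (np.sort(combined.ravel()) == np.sort(orig.ravel())).all()

    def test_deterministic_per_seed(self, rng):
        grid = self._grid(rng)
        a = split_grid(grid, [], 0.5, seed=1)
        b = split_grid(grid, [], 0.5, seed=1)
        c = split_grid(grid, [], 0.5, seed=2)
        for ea, eb in zip(a.entries, b.entries):
            assert np.array_equal(ea.ensemble.values, eb.ensemble.values)
        assert any(not np.array_equal(ea.ensemble.values, ec.ensemble.values)
                   for ea, ec in zip(a.entries, c.entries))

    def test_within_fraction_one_all_train(self, rng):
        grid = self._grid(rng)
        out = split_grid(grid, [], 1.0, seed=0)
        assert all(e.split == "train" for e in out.entries)
        assert out.n_traj_total == grid.n_traj_total

    def test_missing_heldout_errors(self, rng):
        with pytest.raises(ValueError, match="not present"):
            split_grid(self._grid(rng), [(99.0,)], 0.5, seed=0)


def test_substream_stable_and_distinct():
    assert substream(5, "sim") == substream(5, "sim")
    assert substream(5, "sim") != substream(5, "train")
    assert substream(5, "sim") != substream(6, "sim")
    assert 0 <= substream(12345, "anything") < 2**31


def test_runconfig_round_trip():
    cfg = RunConfig(seed=3, dt=0.01, horizon=2.0, imax=7, hidden=(16, 8),
                    latent_mask=(4, 9), extra={"note": "x"})
    back = RunConfig.from_dict(cfg.to_dict())
    assert back.seed == 3 and back.hidden == (16, 8)
    assert back.latent_mask == (4, 9)
    with pytest.raises(ValueError):
        RunConfig(dt=-1.0)
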