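"""I/O round-trips, schema enforcement and configuration validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rcpdecode as rd
from rcpdecode.expression import CellQuantification
from rcpdecode.simio import (
    AcquisitionLayout,
    Codebook,
    RunConfig,
    SPOT_COLUMNS,
    read_expression,
    read_spot_table,
    read_tile_stack,
    tile_filename,
    write_expression,
    write_spot_table,
    write_tileset,
)


class TestAcquisitionLayout:
    def test_geometry_of_default_grid(self):
        lay = AcquisitionLayout(grid_rows=2, grid_cols=3, tile_height_px=100,
                                tile_width_px=200)
        assert lay.overlap_py == 10 and lay.overlap_px == 20
        assert lay.canvas_shape == (100 + 90, 200 + 2 * 180)
        assert lay.nominal_offset(lay.tile_index(1, 2)) == (90, 360)
        assert lay.signal_channels == (1, 2, 3, 4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(overlap_fraction=0.5),
            dict(overlap_fraction=-0.1),
            dict(grid_rows=0),
            dict(nuclear_channel=9),
            dict(z_steps=0),
            dict(grid_cols=4, tile_width_px=8, overlap_fraction=0.01),  # <1 px overlap
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionLayout(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        lay = AcquisitionLayout(grid_rows=2, grid_cols=2, n_rounds=3, z_steps=5)
        lay.to_yaml(tmp_path / "layout.yaml")
        assert AcquisitionLayout.from_yaml(tmp_path / "layout.yaml") == lay


class TestTileStacks:
    def test_simulated_tileset_round_trips_bit_identically(self, tmp_path):
        lay = AcquisitionLayout(grid_rows=2, grid_cols=2, tile_height_px=64,
                                tile_width_px=64, n_rounds=2, z_steps=3)
        sim = rd.simulate.SimulationConfig(layout=lay, n_cells=4, seed=5)
        ts, _ = rd.simulate.simulate_experiment(
            sim, rd.simulate.default_codebook(lay, 4)
        )
        write_tileset(ts, tmp_path)
        back = read_tile_stack(tmp_path, lay)
        assert set(back.stacks) == set(ts.stacks)
        assert len(back.stacks) == 4 * 2 * 5
        for key in ts.stacks:
            assert back.stacks[key].shape == (3, 64, 64)
            np.testing.assert_array_equal(back.stacks[key], ts.stacks[key])

    def test_empty_directory_reports_first_missing_file(self, tmp_path):
        lay = AcquisitionLayout(tile_height_px=32, tile_width_px=32)
        with pytest.raises(FileNotFoundError, match=tile_filename(0, 0, 0)):
            read_tile_stack(tmp_path, lay)

    def test_shape_mismatch_names_offending_index(self, tmp_path):
        import tifffile

        lay = AcquisitionLayout(tile_height_px=32, tile_width_px=32, z_steps=1,
                                channel_names=("DAPI", "Cy3"))
        for c in range(2):
            tifffile.imwrite(tmp_path / tile_filename(0, 0, c),
                             np.zeros((16, 32), dtype=np.uint16))
        with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
            read_tile_stack(tmp_path, lay)

    def test_extra_files_rejected(self, tmp_path):
        import tifffile

        lay = AcquisitionLayout(tile_height_px=8, tile_width_px=8, z_steps=1,
                                channel_names=("DAPI", "Cy3"))
        for c in range(2):
            tifffile.imwrite(tmp_path / tile_filename(0, 0, c),
                             np.zeros((8, 8), dtype=np.uint16))
        tifffile.imwrite(tmp_path / "t009_r0_c0.tif",
                         np.zeros((8, 8), dtype=np.uint16))
        with pytest.raises(ValueError, match="t009_r0_c0.tif"):
            read_tile_stack(tmp_path, lay)

    def test_8bit_input_upcast_without_rescaling(self, tmp_path):
        import tifffile

        lay = AcquisitionLayout(tile_height_px=8, tile_width_px=8, z_steps=1,
                                channel_names=("DAPI", "Cy3"))
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        tifffile.imwrite(tmp_path / tile_filename(0, 0, 0), img)
        tifffile.imwrite(tmp_path / tile_filename(0, 0, 1), img)
        ts = read_tile_stack(tmp_path, lay)
        assert ts.stacks[(0, 0, 0)].dtype == np.uint16
        np.testing.assert_array_equal(ts.stacks[(0, 0, 0)][0], img)


class TestSpotTables:
    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "spots.csv"
        write_spot_table(pd.DataFrame(columns=list(SPOT_COLUMNS)), path)
        assert path.read_text().strip() == ",".join(SPOT_COLUMNS)
        assert len(read_spot_table(path)) == 0

    def test_three_spot_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "round": [0, 0, 1],
                "channel": [1, 2, 1],
                "y": [1.5, 2.25, 3.125],
                "x": [4.0, 5.5, 6.0],
                "intensity": [100.0, 200.0, 300.0],
                "area": [5, 6, 7],
            }
        )
        path = tmp_path / "spots.csv"
        write_spot_table(df, path)
        assert len(path.read_text().strip().splitlines()) == 4
        back = read_spot_table(path)
        for col in ("round", "channel", "y", "x", "intensity", "area"):
            np.testing.assert_array_equal(back[col].to_numpy(), df[col].to_numpy())
        assert (back["gene"] == "").all() and (back["cell_id"] == -1).all()

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_random_tables_round_trip_losslessly(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        n = 10_000
        df = pd.DataFrame(
            {
                "spot_id": np.arange(n),
                "round": rng.integers(0, 5, n),
                "channel": rng.integers(1, 5, n),
                "y": rng.uniform(0, 4096, n),
                "x": rng.uniform(0, 4096, n),
                "intensity": rng.exponential(1000, n),
                "area": rng.integers(1, 100, n),
                "quality": rng.exponential(1.0, n),
                "gene": rng.choice(["Mbp", "Cd24a", "unassigned", ""], n),
                "cell_id": rng.integers(-1, 50, n),
                "Q": rng.normal(0, 1, n),
            }
        )
        path = tmp_path_factory.mktemp("rt") / "spots.csv"
        write_spot_table(df, path)
        back = read_spot_table(path)
        for col in SPOT_COLUMNS:
            np.testing.assert_array_equal(
                back[col].to_numpy(), df[col].to_numpy(), err_msg=col
            )

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError, match="header"):
            read_spot_table(path)


class TestCodebook:
    def test_duplicate_assignments_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Codebook("sequential", {"a": (0, 1), "b": (0, 1)})

    def test_combinatorial_length_constraints(self):
        with pytest.raises(ValueError, match="same length"):
            Codebook("combinatorial", {"a": (1, 2), "b": (1, 2, 3)})
        with pytest.raises(ValueError, match="n_cycles"):
            Codebook("combinatorial", {"a": (1,), "b": (2,)})

    def test_nuclear_channel_not_allowed(self):
        lay = AcquisitionLayout()
        cb = Codebook("sequential", {"a": (0, 0)})  # channel 0 is DAPI
        with pytest.raises(ValueError, match="nuclear"):
            cb.validate_against(lay)

    def test_yaml_round_trip_and_tags(self, tmp_path):
        cb = Codebook(
            "combinatorial",
            {"Mbp": (1, 3), "Cd24a": (2, 4)},
            gene_tags={"Mbp": "A" * 20, "Cd24a": "C" * 20},
        )
        cb.to_yaml(tmp_path / "cb.yaml")
        back = Codebook.from_yaml(tmp_path / "cb.yaml")
        assert back.entries == cb.entries and back.gene_tags == cb.gene_tags
        assert back.n_cycles == 2
        assert back.lookup()[(1, 3)] == "Mbp"

    def test_bad_tag_length_rejected(self):
        with pytest.raises(ValueError, match="20 characters"):
            Codebook("sequential", {"a": (0, 1)}, gene_tags={"a": "short"})


class TestRunConfig:
    def test_unknown_keys_all_reported(self):
        with pytest.raises(ValueError) as err:
            RunConfig.from_dict({"k": 0.1, "bogus_one": 1, "bogus_two": 2})
        assert "bogus_one" in str(err.value) and "bogus_two" in str(err.value)

    def test_yaml_round_trip_and_per_channel_thresholds(self, tmp_path):
        cfg = RunConfig(detect_threshold=[100.0, 200.0, 300.0, 400.0], k=0.5)
        cfg.to_yaml(tmp_path / "run.yaml")
        back = RunConfig.from_yaml(tmp_path / "run.yaml")
        assert back == cfg
        assert back.threshold_for(2) == 300.0
        assert RunConfig(detect_threshold=7.0).threshold_for(3) == 7.0


class TestExpressionIO:
    def _quant(self, matrix, ids=None):
        matrix = np.asarray(matrix)
        ids = np.arange(1, matrix.shape[0] + 1) if ids is None else ids
        meta = pd.DataFrame(
            {
                "centroid_y": np.zeros(matrix.shape[0]),
                "centroid_x": np.zeros(matrix.shape[0]),
                "area_px": np.full(matrix.shape[0], 10),
            }
        )
        genes = [f"g{i}" for i in range(matrix.shape[1])]
        return CellQuantification(matrix=matrix, cell_ids=ids, genes=genes,
                                  cell_meta=meta)

    def test_empty_matrix_is_valid_mtx(self, tmp_path):
        quant = self._quant(np.zeros((0, 3), dtype=np.int64), ids=np.array([], int))
        write_expression(quant, tmp_path)
        mat, ids, genes, _ = read_expression(tmp_path)
        assert mat.shape == (0, 3) and len(ids) == 0 and genes == ["g0", "g1", "g2"]

    def test_two_by_two_matrix_has_two_nonzeros(self, tmp_path):
        write_expression(self._quant([[1, 0], [0, 3]]), tmp_path)
        header = (tmp_path / "matrix.mtx").read_text().splitlines()
        sizes = [l for l in header if not l.startswith("%")][0]
        assert sizes.split() == ["2", "2", "2"]
        mat, ids, genes, meta = read_expression(tmp_path)
        np.testing.assert_array_equal(mat, [[1, 0], [0, 3]])
        assert list(meta.columns) == ["centroid_y", "centroid_x", "area_px"]

    def test_pipeline_matrix_total_equals_assigned_spots(self, seg_run, tmp_path):
        write_expression(seg_run.quant, tmp_path)
        mat, _, _, _ = read_expression(tmp_path)
        n_counted = int(
            (
                (seg_run.assigned["cell_id"] > 0)
                & (seg_run.assigned["gene"] != "unassigned")
            ).sum()
        )
        assert int(mat.sum()) == n_counted
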