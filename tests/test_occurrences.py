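import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon, box

from nichetrunc.grids import GridGeometry, GridStack
from nichetrunc.occurrences import (
    FilterConfig,
    OccurrenceSet,
    SpeciesProfile,
    adjust_temperatures,
    apply_occurrence_filters,
    define_study_area,
    extract_covariates,
    polygons_to_cell_centres,
    thin_occurrences,
)

GEOM = GridGeometry(n_rows=20, n_cols=20, cell_size=5.0)


def _occ(rows):
    return OccurrenceSet(pd.DataFrame.from_records(rows))


class TestPolygonsToCells:
    def test_square_covering_2x2_block(self):
        # cells (rows 18-19, cols 0-1) span x in [0,10], y in [0,10]
        poly = box(0.0, 0.0, 10.0, 10.0)
        occ = polygons_to_cell_centres({"sp": poly}, GEOM)
        assert len(occ) == 4
        assert set(occ.df["x"]) == {2.5, 7.5}
        assert set(occ.df["y"]) == {2.5, 7.5}
        assert set(occ.df["period"]) == {"current"}

    def test_sliver_between_centres_yields_nothing(self):
        poly = box(3.0, 0.0, 4.0, 100.0)  # misses every centre x = 2.5, 7.5, ...
        with pytest.warns(UserWarning, match="no cell centre"):
            occ = polygons_to_cell_centres({"sp": poly}, GEOM)
        assert len(occ) == 0

    def test_matches_exhaustive_point_in_polygon(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(10, 90, size=(8, 2))
        blob = Polygon(pts).convex_hull.buffer(6.0)
        occ = polygons_to_cell_centres({"sp": blob}, GEOM)
        got = set(zip(occ.df["x"], occ.df["y"]))
        xs, ys = GEOM.cell_centres()
        expected = {
            (x, y)
            for x, y in zip(xs.ravel(), ys.ravel())
            if blob.contains(Point(x, y))
        }
        assert got == expected


class TestFilters:
    profiles = {"R. bieti": SpeciesProfile("R. bieti", 3000.0, 4700.0)}

    def _record(self, **kw):
        base = dict(
            species="R. bieti", x=1.0, y=1.0, period="current",
            ELEV=3500.0, TREECOV=80.0, POPDENS=10.0, HII=5.0,
        )
        base.update(kw)
        return base

    @pytest.mark.parametrize(
        "override, kept",
        [
            ({}, True),
            ({"ELEV": 2900.0}, False),  # below the species' 3000 m floor
            ({"ELEV": 3000.0}, True),
            ({"TREECOV": 49.0}, False),
            ({"TREECOV": 50.0}, True),   # "below 50%" is strict
            ({"HII": 21.0}, False),
            ({"HII": 20.0}, True),       # "above 20" is strict
            ({"POPDENS": 100.0}, True),  # "above 100" is strict
            ({"POPDENS": 100.5}, False),
        ],
    )
    def test_boundary_semantics(self, override, kept):
        occ = _occ([self._record(**override)])
        out = apply_occurrence_filters(occ, None, self.profiles, FilterConfig())
        assert len(out) == (1 if kept else 0)

    def test_historical_records_bypass_filters(self):
        occ = _occ([self._record(period="historical", species="genus",
                                 TREECOV=0.0, HII=64.0, ELEV=100.0)])
        out = apply_occurrence_filters(occ, None, self.profiles, FilterConfig())
        assert len(out) == 1

    def test_unknown_species_raises_with_name(self):
        occ = _occ([self._record(species="R. mysterius")])
        with pytest.raises(KeyError, match="R. mysterius"):
            apply_occurrence_filters(occ, None, self.profiles, FilterConfig())

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        occ = _occ(
            [
                self._record(
                    ELEV=rng.uniform(2000, 5000),
                    TREECOV=rng.uniform(0, 100),
                    HII=rng.uniform(0, 64),
                    POPDENS=rng.uniform(0, 300),
                )
                for _ in range(40)
            ]
        )
        once = apply_occurrence_filters(occ, None, self.profiles, FilterConfig())
        twice = apply_occurrence_filters(once, None, self.profiles, FilterConfig())
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestThinning:
    def test_coincident_points_target_one(self):
        occ = _occ(
            [dict(species="g", x=0.0, y=0.0, period="current")] * 2
        )
        out = thin_occurrences(occ, target_n=1, seed=0)
        assert len(out) == 1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(14)
        occ = _occ(
            [
                dict(species="g", x=float(x), y=float(y), period="current")
                for x, y in rng.uniform(0, 50, size=(30, 2))
            ]
        )
        a = thin_occurrences(occ, target_n=10, seed=5)
        b = thin_occurrences(occ, target_n=10, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_removals_come_from_the_cluster(self):
        rng = np.random.default_rng(15)
        cluster = rng.normal(0.0, 2.0, size=(50, 2))
        isolated = np.array([[200.0, 0], [0, 200.0], [-200.0, 0], [0, -200.0], [200.0, 200.0]])
        occ = _occ(
            [
                dict(species="g", x=float(x), y=float(y), period="current")
                for x, y in np.vstack([cluster, isolated])
            ]
        )
        out = thin_occurrences(occ, target_n=20, seed=0)
        kept = set(zip(out.df["x"], out.df["y"]))
        for x, y in isolated:
            assert (x, y) in kept

    def test_min_dist_enforced(self):
        rng = np.random.default_rng(16)
        occ = _occ(
            [
                dict(species="g", x=float(x), y=float(y), period="current")
                for x, y in rng.uniform(0, 30, size=(25, 2))
            ]
        )
        out = thin_occurrences(occ, min_dist=8.0, seed=0)
        pts = out.df[["x", "y"]].to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0

    def test_identity_cases(self):
        occ = _occ(
            [dict(species="g", x=float(i), y=0.0, period="current") for i in range(5)]
        )
        assert len(thin_occurrences(occ, target_n=5, seed=0)) == 5
        assert len(thin_occurrences(occ, min_dist=0.0, seed=0)) == 5

    def test_errors(self):
        occ = _occ([dict(species="g", x=0.0, y=0.0, period="current")])
        with pytest.raises(ValueError):
            thin_occurrences(occ, target_n=2, seed=0)
        with pytest.raises(ValueError):
            thin_occurrences(occ, min_dist=1.0, target_n=1, seed=0)


class TestStudyArea:
    def test_single_point_buffer(self):
        occ = _occ([dict(species="g", x=0.0, y=0.0, period="current")])
        assert define_study_area(None, occ, 500.0) == (-500.0, -500.0, 500.0, 500.0)

    def test_zero_buffer_is_bounding_box(self):
        occ = _occ(
            [
                dict(species="g", x=1.0, y=2.0, period="current"),
                dict(species="g", x=7.0, y=-3.0, period="historical"),
            ]
        )
        assert define_study_area(None, occ, 0.0) == (1.0, -3.0, 7.0, 2.0)

    def test_two_points_with_buffer(self):
        occ = _occ(
            [
                dict(species="g", x=0.0, y=0.0, period="current"),
                dict(species="g", x=100.0, y=0.0, period="current"),
            ]
        )
        assert define_study_area(None, occ, 500.0) == (-500.0, -500.0, 600.0, 500.0)

    def test_margin_property(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(-100, 100, size=(20, 2))
        occ = _occ(
            [dict(species="g", x=float(x), y=float(y), period="current") for x, y in pts]
        )
        xmin, ymin, xmax, ymax = define_study_area(None, occ, 50.0)
        assert (pts[:, 0] - xmin >= 50).all() and (xmax - pts[:, 0] >= 50).all()
        assert (pts[:, 1] - ymin >= 50).all() and (ymax - pts[:, 1] >= 50).all()

    def test_polygon_and_empty(self):
        poly = box(0, 0, 10, 10)
        assert define_study_area([poly], None, 5.0) == (-5.0, -5.0, 15.0, 15.0)
        with pytest.raises(ValueError):
            define_study_area(None, None, 5.0)


class TestExtraction:
    def _stack(self):
        geom = GridGeometry(n_rows=4, n_cols=4, cell_size=5.0)
        layer = np.arange(16, dtype=float).reshape(4, 4)
        layer[0, 0] = np.nan
        return GridStack(geom, {"V": layer})

    def test_centre_lookup(self):
        stack = self._stack()
        occ = _occ([dict(species="g", x=7.5, y=2.5, period="current")])
        out = extract_covariates(occ, stack)
        # x=7.5 -> col 1; y=2.5 -> bottom row 3
        assert out.df["V"].iloc[0] == stack["V"][3, 1]
        assert bool(out.df["valid"].iloc[0])

    def test_nodata_cell_flagged_excluded(self):
        stack = self._stack()
        occ = _occ([dict(species="g", x=2.5, y=17.5, period="current")])  # cell (0,0)
        out = extract_covariates(occ, stack)
        assert not out.df["valid"].iloc[0]
        assert len(out.modelling_records()) == 0

    def test_outside_grid_raises(self):
        stack = self._stack()
        occ = _occ([dict(species="g", x=999.0, y=0.0, period="current")])
        with pytest.raises(ValueError, match="outside the grid"):
            extract_covariates(occ, stack)

    def test_batch_equals_single_lookups(self):
        stack = self._stack()
        rng = np.random.default_rng(18)
        pts = rng.uniform(0.1, 19.9, size=(10, 2))
        occ = _occ(
            [dict(species="g", x=float(x), y=float(y), period="current") for x, y in pts]
        )
        batch = extract_covariates(occ, stack)
        for i, (x, y) in enumerate(pts):
            single = extract_covariates(
                _occ([dict(species="g", x=float(x), y=float(y), period="current")]), stack
            )
            assert batch.df["V"].iloc[i] == pytest.approx(
                single.df["V"].iloc[0], nan_ok=True
            )


class TestTemperatureAdjustment:
    def test_historical_reduced_current_unchanged(self):
        occ = _occ(
            [
                dict(species="g", x=0.0, y=0.0, period="historical",
                     MTCQ=5.0, PANN=1000.0, AMT=12.0),
                dict(species="g", x=0.0, y=0.0, period="current",
                     MTCQ=5.0, PANN=1000.0, AMT=12.0),
            ]
        )
        out = adjust_temperatures(occ, 0.7)
        hist = out.df[out.df["period"] == "historical"].iloc[0]
        cur = out.df[out.df["period"] == "current"].iloc[0]
        assert hist["MTCQ"] == pytest.approx(4.3)
        assert hist["AMT"] == pytest.approx(11.3)
        assert hist["PANN"] == 1000.0  # precipitation untouched
        assert cur["MTCQ"] == 5.0

    def test_zero_delta_is_identity(self):
        occ = _occ(
            [dict(species="g", x=0.0, y=0.0, period="historical", MTCQ=5.0)]
        )
        out = adjust_temperatures(occ, 0.0)
        pd.testing.assert_frame_equal(out.df, occ.df)

    def test_negative_delta_rejected(self):
        occ = _occ(
            [dict(species="g", x=0.0, y=0.0, period="historical", MTCQ=5.0)]
        )
        with pytest.raises(ValueError):
            adjust_temperatures(occ, -1.0)
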