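"""Ground-truth generator: packing validity, determinism, distribution
recovery, phenotype contrast, table round-trips, rasterization."""

import math

import numpy as np
import pandas as pd
import pytest

from nervestereo import (
    DistributionError,
    DistributionSpec,
    PackingError,
    RenderError,
    control_params,
    generate_section,
    regenerated_params,
    render_section,
    section_to_table,
    table_to_section,
)
from nervestereo.synthetic import FiberPhenotypeParams

from conftest import tiny_phenotype


class TestDistributionSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(DistributionError):
            DistributionSpec("weibull", {"shape": 1.0})

    def test_wrong_params_rejected(self):
        with pytest.raises(DistributionError):
            DistributionSpec("normal", {"mean": 1.0})

    def test_truncation_respected(self, rng):
        spec = DistributionSpec("normal", {"mean": 0.65, "sd": 0.05}, low=0.4, high=0.85)
        x = spec.draw(rng, 5000)
        assert np.all((x > 0.4) & (x < 0.85))

    def test_lognormal_mean_closed_form(self, rng):
        spec = DistributionSpec("lognormal", {"median": 3.5, "sigma_log": 0.35})
        x = spec.draw(rng, 200_000)
        assert spec.mean() == pytest.approx(3.5 * math.exp(0.35**2 / 2))
        assert x.mean() == pytest.approx(spec.mean(), rel=0.01)


class TestGenerateSection:
    def test_degenerate_distributions_force_geometry(self):
        # d = 2 um, g = 0.6 everywhere -> every D = 2/0.6
        section = generate_section(tiny_phenotype(10), nerve_radius=100.0, seed=3)
        assert section.n_fibers == 10
        assert np.allclose(section.d, 2.0)
        assert np.allclose(section.D, 2.0 / 0.6)
        section.validate()

    def test_fiber_larger_than_nerve_is_packing_error(self):
        params = tiny_phenotype(1, d=180.0, g=0.6)  # D = 300 um
        with pytest.raises(PackingError):
            generate_section(params, nerve_radius=100.0, seed=0)

    def test_overfull_population_is_packing_error(self):
        # the default 1200-fiber control population exceeds the packing
        # limit in a 120 um nerve
        with pytest.raises(PackingError):
            generate_section(control_params(1200), nerve_radius=120.0, seed=0)

    def test_determinism_bitwise(self):
        params = control_params(120)
        a = section_to_table(generate_section(params, nerve_radius=60.0, seed=42))
        b = section_to_table(generate_section(params, nerve_radius=60.0, seed=42))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    @pytest.mark.parametrize("seed", range(25))
    def test_invariants_across_seeds(self, seed):
        section = generate_section(control_params(150), nerve_radius=60.0, seed=seed)
        section.validate()  # raises on overlap / boundary / id violations
        assert section.n_fibers == 150

    def test_distribution_recovery_three_standard_errors(self):
        # pure lognormal axon-diameter population, no sub-resolution tail
        params = FiberPhenotypeParams(
            group_label="control",
            axon_diameter_dist=DistributionSpec(
                "lognormal", {"median": 3.5, "sigma_log": 0.35}, low=0.0
            ),
            g_ratio_dist=DistributionSpec(
                "normal", {"mean": 0.65, "sd": 0.05}, low=0.4, high=0.85
            ),
            target_fiber_count=500,
        )
        section = generate_section(params, nerve_radius=120.0, seed=1)
        expected = 3.5 * math.exp(0.35**2 / 2)
        se = section.d.std(ddof=1) / math.sqrt(section.n_fibers)
        assert abs(section.d.mean() - expected) < 3 * se
        g = section.d / section.D
        assert abs(g.mean() - 0.65) < 3 * g.std(ddof=1) / math.sqrt(g.size)

    @pytest.mark.parametrize("seed", range(20))
    def test_regenerated_sizes_below_control(self, seed):
        ctrl = generate_section(control_params(300), nerve_radius=90.0, seed=seed)
        regen = generate_section(
            regenerated_params(300), nerve_radius=90.0, seed=seed + 1000
        )
        assert regen.d.mean() < ctrl.d.mean()
        assert regen.D.mean() < ctrl.D.mean()
        myelin = lambda s: ((s.D - s.d) / 2.0).mean()
        assert myelin(regen) < myelin(ctrl)


class TestFiberTable:
    def test_round_trip_identity(self, small_section):
        table = section_to_table(small_section)
        assert len(table) == small_section.n_fibers
        back = table_to_section(
            table,
            section_id=small_section.section_id,
            nerve_radius=small_section.nerve_radius,
        )
        assert np.array_equal(back.fiber_id, small_section.fiber_id)
        assert np.array_equal(back.x, small_section.x)
        assert np.array_equal(back.d, small_section.d)
        assert np.array_equal(back.D, small_section.D)

    def test_empty_section_gives_header_only_table(self):
        section = generate_section(tiny_phenotype(0), nerve_radius=50.0, seed=0)
        table = section_to_table(section)
        assert len(table) == 0
        assert list(table.columns) == [
            "fiber_id", "x_um", "y_um", "axon_diameter_um", "fiber_diameter_um",
        ]

    def test_degenerate_D_column_value(self):
        section = generate_section(tiny_phenotype(5), nerve_radius=50.0, seed=1)
        table = section_to_table(section)
        assert table["fiber_diameter_um"].to_numpy() == pytest.approx(
            np.full(5, 2.0 / 0.6)
        )


class TestRender:
    def test_single_fiber_annulus_radii(self):
        # d=2, D=4 at center, pixel 0.1 -> annulus outer ~20 px, inner ~10 px
        section = table_to_section(
            pd.DataFrame(
                {
                    "fiber_id": [0],
                    "x_um": [0.0],
                    "y_um": [0.0],
                    "axon_diameter_um": [2.0],
                    "fiber_diameter_um": [4.0],
                }
            ),
            nerve_radius=10.0,
        )
        img = render_section(section, pixel_size=0.1)
        n = img.shape[0]
        center = (n - 1) / 2.0
        myelin_px = np.argwhere(img == 50)
        radii = np.hypot(myelin_px[:, 0] - center, myelin_px[:, 1] - center)
        assert radii.max() == pytest.approx(20.0, abs=1.5)
        assert radii.min() == pytest.approx(10.0, abs=1.5)

    def test_empty_section_uniform_outside_nerve(self):
        section = generate_section(tiny_phenotype(0), nerve_radius=20.0, seed=0)
        img = render_section(section, pixel_size=0.5)
        assert set(np.unique(img)) == {220, 245}  # endoneurium + background only

    def test_pixel_budget_enforced(self, small_section):
        with pytest.raises(RenderError):
            render_section(small_section, pixel_size=0.001)

    def test_rendered_fibers_never_touch(self):
        # disk disjointness must survive rasterization at fine pixel size
        section = generate_section(control_params(200), nerve_radius=70.0, seed=5)
        half = section.nerve_radius + 1.0
        px = 0.1
        n = int(np.ceil(2 * half / px))
        xs = -half + (np.arange(n) + 0.5) * px
        cover = np.zeros((n, n), dtype=np.int16)
        for cx, cy, D in zip(section.x, section.y, section.D):
            mask = (xs[None, :] - cx) ** 2 + (xs[:, None] - cy) ** 2 <= (D / 2) ** 2
            cover += mask
        assert cover.max() <= 1
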