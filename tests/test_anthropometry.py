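"""Geometry: part sizing, body assembly, heights, silhouettes."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from partitherm.anthropometry import (
    BodyPartSpec,
    DEFAULT_PART_SPECS,
    assemble_body,
    body_silhouette_area,
    dubois_area,
    part_heights,
    prolate_spheroid_area,
    silhouette_area,
    silhouette_correction,
    size_part,
    stature,
    validate_part_specs,
)


class TestSizePart:
    def test_cylinder_closed_form(self):
        # V = pi * 0.05^2 * 0.2 = 1.5708e-3 m^3 -> mass 1.5708 kg at 1000 kg/m^3
        g = size_part(1.5708, 1000.0, "cylinder", 2.0)
        assert g.diameter / 2 == pytest.approx(0.05, rel=1e-4)
        assert g.length == pytest.approx(0.20, rel=1e-4)
        # lateral + both ends
        assert g.area_total == pytest.approx(0.07854, rel=1e-3)

    def test_spheroid_sphere_limit(self):
        g = size_part(5.0, 1050.0, "prolate_spheroid", 1.0)
        b = g.diameter / 2
        assert g.area_total == pytest.approx(4 * math.pi * b * b, rel=1e-9)

    @pytest.mark.parametrize("shape_b", [1.0, 1.3, 1.6, 2.5, 4.0])
    def test_spheroid_area_matches_quadrature(self, shape_b):
        """Closed-form spheroid area vs numerical surface-of-revolution integral."""
        g = size_part(5.0, 1050.0, "prolate_spheroid", shape_b)
        b, a = g.diameter / 2, g.length / 2

        # surface of revolution of x(z) = b*sqrt(1-(z/a)^2) about the z axis
        def integrand(z):
            x = b * math.sqrt(max(1 - (z / a) ** 2, 0.0))
            dxdz = -b * z / (a * a * max(x / b, 1e-300)) / b if x > 0 else 0.0
            dxdz = -(b * z) / (a * a * math.sqrt(max(1 - (z / a) ** 2, 1e-300)))
            return 2 * math.pi * x * math.sqrt(1 + dxdz * dxdz)

        oracle, _ = quad(integrand, -a * (1 - 1e-12), a * (1 - 1e-12), limit=200)
        assert g.area_total == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(mass=-1.0, density=1000.0, shape_class="cylinder", shape_b=2.0),
        dict(mass=1.0, density=0.0, shape_class="cylinder", shape_b=2.0),
        dict(mass=1.0, density=1000.0, shape_class="cylinder", shape_b=-2.0),
    ])
    def test_rejects_nonpositive_inputs(self, bad):
        with pytest.raises(ValueError):
            size_part(**bad)

    def test_volume_exact(self):
        g = size_part(12.0, 1050.0, "cylinder", 5.0)
        assert g.volume == pytest.approx(12.0 / 1050.0, rel=1e-12)


class TestAssembleBody:
    def test_single_part_identity(self):
        spec = (BodyPartSpec("trunk", "cylinder", 1.0, 1.0, 2.0),)
        parts = assemble_body(70.0, 1.8, 1.75, spec)
        assert len(parts) == 1
        assert parts[0].area_joined == 0.0
        assert parts[0].area_skin == pytest.approx(1.8, rel=1e-3)

    def test_default_configuration_closes_area(self):
        parts = assemble_body(70.0, 1.83, 1.75)
        total = sum(p.count * p.area_skin for p in parts)
        assert total == pytest.approx(1.83, rel=1e-3)

    def test_default_configuration_hits_stature(self):
        parts = assemble_body(70.0, dubois_area(70.0, 1.75), 1.75)
        assert stature(parts) == pytest.approx(1.75, rel=0.02)

    def test_mass_partition_is_linear(self):
        p1 = assemble_body(70.0, 1.83, 1.75)
        p2 = assemble_body(140.0, 1.83, 1.75)
        for a, b in zip(p1, p2):
            assert b.volume == pytest.approx(2 * a.volume, rel=1e-12)

    def test_mass_conserved_exactly(self):
        parts = assemble_body(70.0, 1.83, 1.75)
        assert sum(p.count * p.mass for p in parts) == pytest.approx(70.0, abs=1e-9)

    @given(
        raw=st.lists(st.floats(0.3, 3.0), min_size=4, max_size=4),
        area_raw=st.lists(st.floats(0.3, 3.0), min_size=4, max_size=4),
    )
    def test_area_closure_over_random_proportions(self, raw, area_raw):
        """Count-weighted exposed skin area closes on the specified total for
        any valid proportion set."""
        counts = [1, 1, 2, 2]
        m = [r / sum(c * x for c, x in zip(counts, raw)) for r in raw]
        a = [r / sum(c * x for c, x in zip(counts, area_raw)) for r in area_raw]
        specs = tuple(
            BodyPartSpec(pid, shape, m[i], a[i], b, count=counts[i])
            for i, (pid, shape, b) in enumerate([
                ("head", "prolate_spheroid", 1.6), ("trunk", "cylinder", 2.1),
                ("arm", "cylinder", 8.0), ("leg", "cylinder", 6.5)])
        )
        validate_part_specs(specs)
        parts = assemble_body(60.0, 1.7, 1.7, specs)
        total = sum(p.count * p.area_skin for p in parts)
        assert total == pytest.approx(1.7, rel=1e-3)

    def test_infeasible_combination_raises_diagnostic(self):
        spec = (BodyPartSpec("trunk", "cylinder", 1.0, 1.0, 2.0),)
        with pytest.raises(ValueError, match="infeasible|closes"):
            assemble_body(70.0, 40.0, 1.75, spec)  # area far beyond any shape


class TestPartHeights:
    def test_leg_midpoint_is_half_length(self, default_parts):
        heights = part_heights(default_parts)
        leg = next(p for p in default_parts if p.part_id == "leg")
        assert heights["leg"] == pytest.approx(leg.length / 2)

    def test_ordering(self, default_parts):
        h = part_heights(default_parts)
        assert h["head"] > h["trunk"] > h["arm"] >= h["leg"]
        assert h["head"] < stature(default_parts)
        assert h["head"] > 0.8 * stature(default_parts)

    def test_prefix_sum_oracle(self, default_parts):
        by_id = {p.part_id: p for p in default_parts}
        h = part_heights(default_parts)
        leg, trunk, head = by_id["leg"], by_id["trunk"], by_id["head"]
        assert h["trunk"] == pytest.approx(leg.length + trunk.length / 2)
        assert h["head"] == pytest.approx(leg.length + trunk.length + head.length / 2)
        arm = by_id["arm"]
        assert h["arm"] == pytest.approx(leg.length + trunk.length - arm.length / 2)


class TestSilhouette:
    def test_vertical_cylinder_overhead_sun(self):
        g = size_part(10.0, 1000.0, "cylinder", 4.0)
        r = g.diameter / 2
        assert silhouette_area(g, 0.0) == pytest.approx(math.pi * r * r, rel=1e-12)

    def test_vertical_cylinder_horizon_sun(self):
        g = size_part(10.0, 1000.0, "cylinder", 4.0)
        assert silhouette_area(g, 90.0) == pytest.approx(
            g.length * g.diameter, rel=1e-12)

    def test_zenith_out_of_range_rejected(self, trunk_geometry):
        for z in (-1.0, 90.5):
            with pytest.raises(ValueError):
                silhouette_area(trunk_geometry, z)
            with pytest.raises(ValueError):
                silhouette_correction(z)

    @pytest.mark.parametrize("zenith", np.linspace(0, 90, 19).tolist())
    def test_silhouette_bounds(self, default_parts, zenith):
        """A projection is positive and cannot exceed half the closed surface."""
        for p in default_parts:
            a = silhouette_area(p, zenith)
            assert 0 < a <= p.area_total / 2 + 1e-12

    @pytest.mark.parametrize("zenith", [30.0, 45.0, 60.0])
    def test_correction_reduces_geometric_overestimate(self, default_parts, zenith):
        """The empirical standing-human projection is below the geometric sum
        of the primitives at mid zenith angles."""
        geo = body_silhouette_area(default_parts, zenith, corrected=False)
        cor = body_silhouette_area(default_parts, zenith, corrected=True)
        assert cor < geo

    def test_correction_clamped_positive(self):
        for z in np.linspace(0, 90, 91):
            assert 0 < silhouette_correction(float(z)) <= 1.5


def test_default_part_specs_are_valid():
    validate_part_specs(DEFAULT_PART_SPECS)
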