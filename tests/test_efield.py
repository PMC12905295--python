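import numpy as np
import pytest

from fieldpmf.constants import COULOMB_FIELD_MV_CM
from fieldpmf.efield import (
    FieldSample,
    ReactionAxis,
    axial_field,
    field_correlation,
    window_field_statistics,
)
from fieldpmf.errors import (
    DegenerateAxisError,
    InsufficientDataError,
    SingularityError,
    UndefinedCorrelationError,
)
from fieldpmf.structures_io import AtomRecord, ChargedFrame, Selection
from fieldpmf.synthetic_data import DEFAULT_AXIS, GeneratorSpec, gen_point_charges

EVERYTHING = Selection(mode="exclude")  # empty exclude-set = all atoms


def _axis_frame(extra_atoms):
    """Frame with the unit axis (tail -0.5, head +0.5 on x) plus extras."""
    atoms = [
        AtomRecord(1, "T", "AXS", 1, np.array([-0.5, 0.0, 0.0]), 0.0),
        AtomRecord(2, "H", "AXS", 2, np.array([0.5, 0.0, 0.0]), 0.0),
    ] + extra_atoms
    return ChargedFrame(atoms)


class TestAxialField:
    def test_unit_charge_one_angstrom_constant(self):
        """+1e on the axis, 1 A beyond the midpoint on the head side: the
        field at the probe points back toward the tail, so the axial
        component is -1439.96 MV/cm (the Coulomb unit-field constant)."""
        frame = _axis_frame(
            [AtomRecord(3, "Q", "CHG", 10, np.array([1.0, 0.0, 0.0]), 1.0)]
        )
        s = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        assert s.axial_component == pytest.approx(-1439.964547842567, rel=1e-12)
        # independently derived: e/(4 pi eps0 (1e-10 m)^2), V/m -> MV/cm
        import math
        e, eps0 = 1.602176634e-19, 8.8541878128e-12
        expected = e / (4 * math.pi * eps0 * (1e-10) ** 2) / 1e8
        assert COULOMB_FIELD_MV_CM == pytest.approx(expected, rel=1e-12)

    def test_perpendicular_charge_has_zero_axial_component(self):
        frame = _axis_frame(
            [AtomRecord(3, "Q", "CHG", 10, np.array([0.0, 2.5, -1.0]), 0.7)]
        )
        s = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        assert abs(s.axial_component) < 1e-9
        assert np.linalg.norm(s.field_vector) > 0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorised Coulomb sum equals the generator's independent
        double-loop oracle to 1e-10 relative on random 50-charge frames."""
        frame, record = gen_point_charges(GeneratorSpec(seed=seed, n_charges=50))
        s = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        np.testing.assert_allclose(s.field_vector, record.field_vector, rtol=1e-10)
        assert s.axial_component == pytest.approx(record.axial_component, rel=1e-10)

    def test_axial_component_is_projection(self):
        frame, _ = gen_point_charges(GeneratorSpec(seed=1, n_charges=20))
        s = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        assert s.axial_component == pytest.approx(s.field_vector[0], rel=1e-9)

    def test_superposition_over_disjoint_environments(self):
        frame, _ = gen_point_charges(GeneratorSpec(seed=2, n_charges=30))
        ids = [a.residue_id for a in frame.atoms if a.residue_name == "CHG"]
        half_a, half_b = set(ids[:15]), set(ids[15:])
        s_all = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        s_a = axial_field(frame, DEFAULT_AXIS, Selection(half_a, "include"))
        s_b = axial_field(frame, DEFAULT_AXIS, Selection(half_b, "include"))
        np.testing.assert_allclose(
            s_a.field_vector + s_b.field_vector, s_all.field_vector, rtol=1e-12
        )
        assert s_a.axial_component + s_b.axial_component == pytest.approx(
            s_all.axial_component, rel=1e-12
        )

    def test_charge_scaling_is_linear(self):
        frame, _ = gen_point_charges(GeneratorSpec(seed=3, n_charges=10))
        scaled = ChargedFrame(
            [
                AtomRecord(a.serial, a.atom_name, a.residue_name, a.residue_id,
                           a.position.copy(),
                           a.charge * 2.5 if a.residue_name == "CHG" else a.charge)
                for a in frame.atoms
            ]
        )
        s1 = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        s2 = axial_field(scaled, DEFAULT_AXIS, EVERYTHING)
        np.testing.assert_allclose(s2.field_vector, 2.5 * s1.field_vector, rtol=1e-12)

    def test_axis_reversal_negates_projection(self):
        frame, _ = gen_point_charges(GeneratorSpec(seed=4, n_charges=25))
        fwd = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        rev = axial_field(frame, DEFAULT_AXIS.reversed(), EVERYTHING)
        assert rev.axial_component == pytest.approx(-fwd.axial_component, rel=1e-12)
        assert np.linalg.norm(rev.field_vector) == pytest.approx(
            np.linalg.norm(fwd.field_vector), rel=1e-12
        )

    def test_axis_atoms_always_excluded(self):
        # give the axis atoms huge charges: the field must not change
        frame = _axis_frame(
            [AtomRecord(3, "Q", "CHG", 10, np.array([2.0, 1.0, 0.0]), 0.5)]
        )
        charged_axis = ChargedFrame(
            [
                AtomRecord(1, "T", "AXS", 1, np.array([-0.5, 0.0, 0.0]), 9.0),
                AtomRecord(2, "H", "AXS", 2, np.array([0.5, 0.0, 0.0]), -9.0),
                AtomRecord(3, "Q", "CHG", 10, np.array([2.0, 1.0, 0.0]), 0.5),
            ]
        )
        s1 = axial_field(frame, DEFAULT_AXIS, EVERYTHING)
        s2 = axial_field(charged_axis, DEFAULT_AXIS, EVERYTHING)
        np.testing.assert_allclose(s2.field_vector, s1.field_vector, rtol=1e-12)

    def test_charge_on_probe_is_singular(self):
        frame = _axis_frame(
            [AtomRecord(3, "Q", "CHG", 10, np.array([1e-9, 0.0, 0.0]), 1.0)]
        )
        with pytest.raises(SingularityError):
            axial_field(frame, DEFAULT_AXIS, EVERYTHING)

    def test_coincident_axis_atoms_rejected(self):
        with pytest.raises(DegenerateAxisError):
            ReactionAxis((1, "T"), (1, "T"))


class TestWindowStatistics:
    def _samples(self, values):
        return [FieldSample(0.001 * i, np.zeros(3), v) for i, v in enumerate(values)]

    def test_discards_leading_half(self):
        st = window_field_statistics(self._samples([-40, -40, -30, -30]), 0.5)
        assert st.mean == -30 and st.std == 0 and st.n_samples == 2

    def test_constant_series_any_fraction(self):
        for frac in (0.0, 0.3, 0.6):
            st = window_field_statistics(self._samples([-37.1] * 20), frac)
            assert st.mean == pytest.approx(-37.1) and st.std == 0

    def test_recovers_gaussian_mean_within_sampling_bound(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(-37.1, 11.1, size=10_000)
        st = window_field_statistics(self._samples(vals), 0.5)
        assert st.n_samples == 5000
        assert abs(st.mean - (-37.1)) < 3 * 11.1 / np.sqrt(5000)
        assert st.std == pytest.approx(11.1, rel=0.1)

    def test_too_few_retained_samples(self):
        with pytest.raises(InsufficientDataError):
            window_field_statistics(self._samples([1.0, 2.0]), 0.6)


class TestFieldCorrelation:
    def test_identical_series_correlate_perfectly(self):
        s = [1.0, -2.0, 3.0, 0.5]
        m = field_correlation({"a": s, "b": list(s)})
        assert m.loc["a", "b"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_negated_series_anticorrelate(self):
        s = np.array([1.0, -2.0, 3.0, 0.5])
        m = field_correlation({"a": s, "b": -s})
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(7)
        m = field_correlation({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        assert abs(m.loc["a", "b"]) < 0.1
        assert np.all(m.to_numpy() <= 1.0) and np.all(m.to_numpy() >= -1.0)

    def test_constant_series_rejected_by_name(self):
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            field_correlation({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
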