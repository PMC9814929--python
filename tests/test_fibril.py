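"""Ideal strand geometry, lattice construction and alignment classification."""

import numpy as np
import pytest

from oligofib.fibril import (
    ConstructionError,
    ContactSet,
    LatticeSpec,
    StrandGeometry,
    build_fibril_lattice,
    build_ideal_strand,
    classify_alignment,
    intermolecular_contacts,
)


def _ca(coords, names):
    return coords[names == "CA"]


class TestIdealStrand:
    def test_consecutive_ca_distances_are_trans_standard(self, ideal_strand):
        coords, _, names = ideal_strand
        ca = _ca(coords, names)
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all((d > 3.7) & (d < 3.9))

    def test_heptapeptide_ca1_ca6_span_matches_beta_strand_window(self, ideal_strand):
        coords, _, names = ideal_strand
        ca = _ca(coords, names)
        span = np.linalg.norm(ca[5] - ca[0])
        assert 15.0 <= span <= 18.0

    def test_fully_extended_dihedrals_maximize_end_to_end(self):
        spans = {}
        for phi, psi in ((-139.0, 135.0), (-120.0, 120.0), (180.0, 180.0), (-60.0, -45.0)):
            coords, _, names = build_ideal_strand(StrandGeometry(7, phi=phi, psi=psi))
            ca = _ca(coords, names)
            spans[(phi, psi)] = np.linalg.norm(ca[-1] - ca[0])
        assert spans[(180.0, 180.0)] == max(spans.values())

    def test_strand_is_centered_and_chain_runs_along_y(self, ideal_strand):
        coords, _, names = ideal_strand
        bb = np.isin(names, ("N", "CA", "C", "O"))
        assert np.allclose(coords[bb].mean(axis=0), 0.0, atol=1e-9)
        ca = _ca(coords, names)
        direction = ca[-1] - ca[0]
        assert abs(direction[1]) > 0.95 * np.linalg.norm(direction)

    def test_too_short_strand_rejected(self):
        with pytest.raises(ValueError):
            StrandGeometry(residue_count=1)


class TestLattice:
    def test_default_lattice_has_36_strands(self, default_lattice):
        assert default_lattice.n_strands == 36
        assert len(np.unique(default_lattice.strand_ids)) == 36

    def test_strand_origins_are_integer_multiples_of_spacing(self, default_lattice):
        cents, _, sheets = default_lattice.strand_centroids()
        sheet0 = cents[sheets == 0]
        d = np.linalg.norm(sheet0[:, None] - sheet0[None, :], axis=-1)
        multiples = d / default_lattice.spec.intra_sheet_spacing
        assert np.allclose(multiples, np.round(multiples), atol=1e-6)

    def test_sheets_are_exact_translates_at_the_inter_sheet_spacing(self, default_lattice):
        cents, _, sheets = default_lattice.strand_centroids()
        offset = cents[sheets == 1] - cents[sheets == 0]
        np.testing.assert_allclose(offset, [[0.0, 0.0, 10.0]] * 18, atol=1e-9)

    def test_zero_twist_keeps_strand_axes_parallel(self, default_lattice):
        lat = default_lattice
        axes = []
        for s in (0, 2, 20):
            ca = lat.coords[(lat.strand_ids == s) & (lat.atom_names == "CA")]
            v = ca[-1] - ca[0]
            axes.append(v / np.linalg.norm(v))
        assert abs(np.dot(axes[0], axes[1])) > 1 - 1e-9
        assert abs(np.dot(axes[0], axes[2])) > 1 - 1e-9

    def test_interdigitation_shifts_alternate_sheets_by_half_spacing(self):
        lat = build_fibril_lattice(LatticeSpec(interdigitated=True))
        cents, _, sheets = lat.strand_centroids()
        offset = cents[sheets == 1][0] - cents[sheets == 0][0]
        assert offset[0] == pytest.approx(2.5, abs=1e-9)

    def test_twist_rotates_successive_strands_about_fibril_axis(self):
        lat = build_fibril_lattice(LatticeSpec(twist_per_strand=-2.0, antiparallel=False))
        ca0 = lat.coords[(lat.strand_ids == 0) & (lat.atom_names == "CA")]
        ca3 = lat.coords[(lat.strand_ids == 3) & (lat.atom_names == "CA")]
        ca3 = ca3 - np.array([15.0, 0.0, 0.0])  # undo the lattice translation
        angle = np.deg2rad(-6.0)
        rot = np.array(
            [
                [1, 0, 0],
                [0, np.cos(angle), -np.sin(angle)],
                [0, np.sin(angle), np.cos(angle)],
            ]
        )
        np.testing.assert_allclose(ca3, ca0 @ rot.T, atol=1e-9)

    def test_clashing_spacing_raises(self):
        with pytest.raises(ConstructionError):
            build_fibril_lattice(LatticeSpec(intra_sheet_spacing=1.0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LatticeSpec(n_strands=1)
        with pytest.raises(ValueError):
            LatticeSpec(intra_sheet_spacing=-5.0)
        with pytest.raises(ValueError):
            LatticeSpec(n_strands=36, n_sheets=5)


class TestAlignmentClassification:
    def test_antiparallel_contact_pattern_maps_terminal_residues_crosswise(self, default_lattice):
        contacts = intermolecular_contacts(default_lattice)
        cross = [
            c
            for c in contacts.contacts
            if {c[1], c[3]} & {1, 2} and {c[1], c[3]} & {6, 7}
        ]
        assert len(cross) > 0
        assert classify_alignment(contacts) == "antiparallel"

    def test_parallel_lattice_contact_pattern_is_in_register(self):
        lat = build_fibril_lattice(LatticeSpec(antiparallel=False))
        contacts = intermolecular_contacts(lat)
        assert classify_alignment(contacts) == "parallel"
        # parallel neighbours put residue i against residue i
        in_register = [c for c in contacts.contacts if c[1] == c[3]]
        assert len(in_register) > 0

    @pytest.mark.parametrize("twist", [0.0, -1.0, -2.0, -3.0, 1.5, 3.0])
    def test_classification_correct_for_all_tested_twists(self, twist):
        for antiparallel, expected in ((True, "antiparallel"), (False, "parallel")):
            lat = build_fibril_lattice(
                LatticeSpec(antiparallel=antiparallel, twist_per_strand=twist)
            )
            assert classify_alignment(intermolecular_contacts(lat)) == expected

    def test_dimer_is_sufficient_for_classification(self):
        for antiparallel, expected in ((True, "antiparallel"), (False, "parallel")):
            lat = build_fibril_lattice(
                LatticeSpec(n_strands=2, n_sheets=1, antiparallel=antiparallel)
            )
            assert classify_alignment(intermolecular_contacts(lat)) == expected

    def test_empty_contact_set_is_indeterminate(self):
        with pytest.warns(UserWarning):
            assert classify_alignment(ContactSet(contacts=())) == "indeterminate"

    def test_contact_set_rejects_intramolecular_records(self):
        with pytest.raises(ValueError):
            ContactSet(contacts=((0, 1, 0, 6, 4.8),))
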