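"""Chemical-shift perturbation, exchange classes and spatial epitope patches."""

import numpy as np
import pytest

from nmrens.csp_epitope import (
    TitrationSeries,
    classify_exchange,
    combined_csp,
    epitope_patches,
    titration_report,
)
from nmrens.io_formats import PeakRecord
from nmrens.synthetic import TitrationSpec, make_titration

from conftest import brute_force_components, model_from_coords


def _peak(res, h=8.0, n=115.0, inten=1e5, chain="A"):
    return PeakRecord(chain, res, "ALA", h, n, inten)


class TestCombinedCsp:
    def test_identical_lists_zero_csp_unit_ratio(self):
        ref = [_peak(r) for r in range(1, 6)]
        recs = combined_csp(ref, ref)
        assert all(r.delta_combined == pytest.approx(0.0) for r in recs)
        assert all(r.intensity_ratio == pytest.approx(1.0) for r in recs)

    def test_hand_arithmetic(self):
        ref = [_peak(1, h=8.00, n=115.0)]
        tit = [_peak(1, h=8.03, n=115.2)]
        rec = combined_csp(ref, tit, alpha=0.14)[0]
        assert rec.delta_combined == pytest.approx(
            np.sqrt(0.03 ** 2 + (0.14 * 0.2) ** 2), rel=1e-9
        )
        assert rec.delta_combined == pytest.approx(0.0410, abs=5e-4)

    def test_symmetric_in_list_order(self):
        rng = np.random.default_rng(0)
        ref = [_peak(r, h=rng.uniform(7, 10), n=rng.uniform(105, 130))
               for r in range(1, 11)]
        tit = [_peak(r.res_seq, h=r.shift_H + rng.normal(0, 0.05),
                     n=r.shift_N + rng.normal(0, 0.3)) for r in ref]
        fwd = combined_csp(ref, tit)
        rev = combined_csp(tit, ref)
        for a, b in zip(fwd, rev):
            assert a.delta_combined == pytest.approx(b.delta_combined, rel=1e-12)

    def test_vanished_peak_gets_zero_ratio(self):
        ref = [_peak(1), _peak(2)]
        tit = [_peak(1)]
        recs = combined_csp(ref, tit)
        assert recs[1].delta_combined is None
        assert recs[1].intensity_ratio == 0.0

    def test_disjoint_lists_rejected(self):
        with pytest.raises(ValueError):
            combined_csp([_peak(1)], [_peak(2)])


class TestClassify:
    def test_zero_ratio_is_disappeared(self):
        recs = combined_csp([_peak(1), _peak(2)], [_peak(1)])
        out = classify_exchange(recs, csp_threshold=0.05)
        assert out[1].exchange_class == "disappeared"

    def test_attenuation_precedence_over_shift(self):
        ref = [_peak(r) for r in range(1, 6)]
        tit = [_peak(1, h=8.5, inten=0.3e5)] + [_peak(r) for r in range(2, 6)]
        out = classify_exchange(combined_csp(ref, tit), csp_threshold=0.05)
        assert out[0].exchange_class == "attenuated"  # despite the huge shift

    def test_shift_above_threshold(self):
        ref = [_peak(r) for r in range(1, 6)]
        tit = [_peak(1, h=8.2)] + [_peak(r) for r in range(2, 6)]
        out = classify_exchange(combined_csp(ref, tit), csp_threshold=0.1)
        assert out[0].exchange_class == "shifted"
        assert all(r.exchange_class == "unaffected" for r in out[1:])

    def test_classification_is_a_partition(self):
        series, _ = make_titration(TitrationSpec(seed=1))
        recs = classify_exchange(
            combined_csp(series.peak_lists[0], series.peak_lists[-1]))
        assert all(r.exchange_class is not None for r in recs)

    def test_generator_classes_recovered_exactly_at_zero_noise(self):
        spec = TitrationSpec(seed=2)
        series, truth = make_titration(spec)
        recs = classify_exchange(
            combined_csp(series.peak_lists[0], series.peak_lists[-1]))
        got = {c: {r.res_seq for r in recs if r.exchange_class == c}
               for c in ("disappeared", "attenuated", "shifted")}
        assert got["disappeared"] == set(spec.disappeared)
        assert got["attenuated"] == set(spec.attenuated)
        assert got["shifted"] == set(spec.shifted)


class TestEpitopePatches:
    def test_two_close_residues_one_patch(self):
        m = model_from_coords(
            {("A", 1, "CA"): (0, 0, 0), ("A", 5, "CA"): (4, 0, 0)}
        )
        emap = epitope_patches(m, [1, 5], contact_cutoff=8.0)
        assert len(emap.patches) == 1
        assert emap.patches[0]["residues"] == {("A", 1), ("A", 5)}
        assert not emap.unassigned

    def test_far_residues_all_unassigned(self):
        m = model_from_coords(
            {("A", 1, "CA"): (0, 0, 0), ("A", 5, "CA"): (50, 0, 0),
             ("A", 9, "CA"): (0, 50, 0)}
        )
        emap = epitope_patches(m, [1, 5, 9], contact_cutoff=8.0)
        assert emap.patches == []
        assert emap.unassigned == {("A", 1), ("A", 5), ("A", 9)}

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(3)
        coords = {("A", r, "CA"): rng.uniform(0, 30, 3) for r in range(1, 21)}
        m = model_from_coords(coords)
        cutoff = 9.0
        emap = epitope_patches(m, list(range(1, 21)), contact_cutoff=cutoff)
        pairs = sorted(coords)
        edges = [
            ((a[0], a[1]), (b[0], b[1]))
            for i, a in enumerate(pairs)
            for b in pairs[i + 1:]
            if np.linalg.norm(np.array(coords[a]) - np.array(coords[b])) <= cutoff
        ]
        expected = [
            g for g in brute_force_components(
                [(c, r) for c, r, _ in pairs], edges)
            if len(g) >= 2
        ]
        got = sorted(map(sorted, emap.patch_residue_sets))
        assert got == sorted(map(sorted, expected))

    def test_heavy_atom_mode_uses_minimum_distance(self):
        m = model_from_coords(
            {("A", 1, "CA"): (0, 0, 0), ("A", 1, "CB"): (4, 0, 0),
             ("A", 9, "CA"): (10, 0, 0), ("A", 9, "CB"): (8, 0, 0)}
        )
        # CA-CA distance is 10 > 5, but CB-CB is 4 <= 5
        emap = epitope_patches(m, [1, 9], contact_cutoff=5.0, mode="heavy")
        assert len(emap.patches) == 1

    def test_affected_residue_absent_rejected(self):
        m = model_from_coords({("A", 1, "CA"): (0, 0, 0)})
        with pytest.raises(ValueError):
            epitope_patches(m, [99])


class TestTitrationReport:
    def test_flat_series_has_empty_epitope(self):
        ref = [_peak(r) for r in range(1, 8)]
        series = TitrationSeries([0.0, 1.0], [ref, list(ref)])
        coords = {("A", r, "CA"): (3.8 * r, 0.0, 0.0) for r in range(1, 8)}
        rep = titration_report(series, model_from_coords(coords),
                               csp_threshold=0.05)
        assert rep.epitope is None
        assert rep.class_members["unaffected"] == list(range(1, 8))

    def test_monotone_shift_growth_across_points(self):
        spec = TitrationSpec(seed=5)
        series, _ = make_titration(spec)
        rep = titration_report(series, None)
        mid, final = rep.per_point[0], rep.per_point[1]
        for r in spec.shifted:
            d_mid = float(mid.loc[mid.res_seq == r, "delta_combined"].iloc[0])
            d_fin = float(final.loc[final.res_seq == r, "delta_combined"].iloc[0])
            assert d_fin >= d_mid

    def test_prior_epitope_split(self):
        spec = TitrationSpec(seed=6)
        series, _ = make_titration(spec)
        prior = {18, 23, 26, 39, 40, 49, 52, 93, 96, 99, 100, 101}
        rep = titration_report(series, None, prior_epitope=prior)
        affected = set().union(
            spec.disappeared, spec.attenuated, spec.shifted)
        assert rep.known_epitope_residues == affected & prior
        assert rep.new_epitope_residues == affected - prior

    def test_unknown_residue_in_point_rejected(self):
        ref = [_peak(1)]
        bad = [_peak(1), _peak(2)]
        with pytest.raises(ValueError):
            titration_report(TitrationSeries([0.0, 1.0], [ref, bad]), None)
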