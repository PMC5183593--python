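"""Helix classification from hydrogen-bond geometry and bundle fractions."""

import numpy as np
import pytest

from nmrens.helicity import (
    HelixCriteria,
    classify_residue_helix,
    helical_fraction,
    nterm_hbond_report,
)
from nmrens.io_formats import Ensemble
from nmrens.synthetic import (
    ALPHA_DIHEDRALS,
    BETA_DIHEDRALS,
    EnsembleSpec,
    build_peptide,
    make_dimer_ensemble,
)


class TestClassifier:
    @pytest.mark.parametrize(
        "fixture,expected",
        [("ideal_alpha", "alpha"), ("ideal_three_ten", "three_ten"),
         ("ideal_extended", "none")],
    )
    def test_interior_residues_of_canonical_geometries(self, request, fixture, expected):
        model = request.getfixturevalue(fixture)
        for res in range(3, 8):  # interior: ends excluded
            assert classify_residue_helix(model, "A", res) == expected

    def test_alpha_precedence_when_both_bonds_present(self, ideal_alpha):
        # on the ideal alpha helix the heavy-atom i+3 distance also passes
        # the O...N cutoff; the label must still be alpha
        crit = HelixCriteria(use_hydrogen="never")
        assert classify_residue_helix(ideal_alpha, "A", 4, crit) == "alpha"

    def test_chain_too_short_raises(self, ideal_alpha):
        with pytest.raises(ValueError, match="too short"):
            classify_residue_helix(ideal_alpha, "A", 11)

    def test_loosening_cutoff_never_removes_helicity(self, ideal_alpha,
                                                     ideal_three_ten,
                                                     ideal_extended):
        rank = {"none": 0, "three_ten": 1, "alpha": 1}
        for model in (ideal_alpha, ideal_three_ten, ideal_extended):
            for res in range(3, 8):
                tight = classify_residue_helix(
                    model, "A", res, HelixCriteria(o_n_cutoff=3.0, o_h_cutoff=2.2))
                loose = classify_residue_helix(
                    model, "A", res, HelixCriteria(o_n_cutoff=4.5, o_h_cutoff=3.5))
                assert rank[loose] >= rank[tight]

    def test_dihedral_gate_blocks_nonhelical_backbone(self, ideal_extended):
        # even with absurdly loose distance cutoffs the gate keeps an
        # extended chain unlabelled
        crit = HelixCriteria(o_n_cutoff=50.0, o_h_cutoff=50.0, dihedral_gate=True)
        assert classify_residue_helix(ideal_extended, "A", 5, crit) == "none"


class TestHelicalFraction:
    def test_all_helical_and_all_extended(self, ideal_alpha, ideal_extended):
        span = (3, 7)
        ens_h = Ensemble([ideal_alpha])
        prof = helical_fraction(ens_h, "A", span)
        assert all(v == 1.0 for v in prof.fraction_helical.values())
        assert prof.segment_fraction == 1.0

        ens_e = Ensemble([ideal_extended])
        prof_e = helical_fraction(ens_e, "A", span)
        assert all(v == 0.0 for v in prof_e.fraction_helical.values())
        assert prof_e.segment_fraction == 0.0

    def test_labels_partition_every_residue(self, ideal_alpha):
        prof = helical_fraction(Ensemble([ideal_alpha]), "A", (3, 7))
        for r in range(3, 8):
            assert prof.fraction_alpha[r] + prof.fraction_310[r] <= 1.0 + 1e-12
            assert (1, "A", r) in prof.labels

    def test_half_helical_bundle_recovers_segment_fraction(self):
        spec = EnsembleSpec(n_models=20, helix_fraction=0.5,
                            sigma_core=0.0, sigma_loop=0.0, seed=0)
        ens, truth = make_dimer_ensemble(spec)
        prof = helical_fraction(ens, "A", spec.helix_segment)
        assert prof.segment_fraction == pytest.approx(0.5)
        assert len(truth.helical_models) == 10
        for r in range(spec.helix_segment[0], spec.helix_segment[1] + 1):
            assert prof.fraction_helical[r] == pytest.approx(0.5)

    def test_propensity_recovered_within_binomial_ci(self):
        # deterministic model choice means the fraction is exact, which is
        # trivially inside any binomial CI of p at n = 200
        p = 0.35
        spec = EnsembleSpec(n_models=200, helix_fraction=p,
                            sigma_core=0.0, sigma_loop=0.0, chain_length=30,
                            core_ranges=((15, 20),), loop_ranges=((22, 25),),
                            seed=1)
        ens, _ = make_dimer_ensemble(spec)
        prof = helical_fraction(ens, "A", spec.helix_segment)
        half_width = 1.96 * np.sqrt(p * (1 - p) / 200)
        for r in range(spec.helix_segment[0], spec.helix_segment[1] + 1):
            assert abs(prof.fraction_helical[r] - p) <= half_width


class TestHbondReport:
    def test_single_ideal_helix_narrow_i4_distances(self):
        model = build_peptide([ALPHA_DIHEDRALS] * 14)
        df, summary = nterm_hbond_report(
            Ensemble([model]), "A", (2, 9), use_hydrogen="never")
        i4 = df[df.offset == 4]["distance"]
        assert i4.max() - i4.min() < 0.2
        assert 2.8 <= i4.mean() <= 3.2

    def test_bundle_extremes_cover_generated_range(self):
        spec = EnsembleSpec(n_models=20, helix_fraction=0.5,
                            sigma_core=0.0, sigma_loop=0.0, seed=2)
        ens, _ = make_dimer_ensemble(spec)
        lo, hi = spec.helix_segment
        df, summary = nterm_hbond_report(ens, "A", (lo, hi))
        # helical models contribute short H-bond distances, extended models
        # long ones: the reported extremes must bracket both regimes
        assert summary["min"] < 2.7
        assert summary["max"] > 6.0
        assert summary["min"] == pytest.approx(df["distance"].min())
        assert summary["max"] == pytest.approx(df["distance"].max())

    def test_mean_per_pair_keys(self):
        model = build_peptide([ALPHA_DIHEDRALS] * 14)
        _, summary = nterm_hbond_report(Ensemble([model]), "A", (2, 5))
        assert (2, 3) in summary["mean_per_pair"]
        assert (5, 4) in summary["mean_per_pair"]
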