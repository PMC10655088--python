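import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from picontact import EDAComponents, EDARecord, classify, summarize, ternary_coordinates
from picontact.ternary import UndefinedPointError, points_to_dataframe
from picontact.synthetic import sample_mixed_suite


def comp(elec=0.0, pauli=0.0, disp=0.0, pol=0.0, ct=0.0, **kw):
    return EDAComponents(elec=elec, pauli=pauli, disp=disp, pol=pol, ct=ct, **kw)


def record(elec=0.0, pauli=0.0, disp=0.0, pol=0.0, ct=0.0, charges=(0, 0),
           is_pi=True, dimer_id="r", pair_type="SCSC", subclass="aromatic-aromatic"):
    return EDARecord(
        dimer_id=dimer_id, pair_type=pair_type, subclass=subclass,
        charges=charges, components_gas=comp(elec, pauli, disp, pol, ct),
        is_pi_contact=is_pi,
    )


class TestTernaryCoordinates:
    def test_balanced_example(self):
        p = ternary_coordinates(comp(elec=0.0, pauli=20.0, disp=-10.0, pol=-10.0))
        assert (p.r_disp, p.r_orb, p.r_signed) == (-0.25, -0.25, 0.5)

    def test_pure_dispersion_vertex(self):
        p = ternary_coordinates(comp(disp=-1.0))
        assert (p.r_disp, p.r_orb, p.r_signed) == (-1.0, 0.0, 0.0)

    def test_variant_sign_flip(self):
        """Subtracting Pauli out can flip the signed vertex."""
        c = comp(elec=-20.0, pauli=35.0, disp=-10.0, pol=-3.0, ct=-2.0)
        p_frz = ternary_coordinates(c, "frz")
        p_elst = ternary_coordinates(c, "elst")
        # frz = +15 (repulsive), elst = -20 (attractive)
        assert p_frz.r_signed == pytest.approx(15.0 / (10 + 5 + 15))
        assert p_elst.r_signed == pytest.approx(-20.0 / (10 + 5 + 20))
        assert p_frz.r_signed > 0 > p_elst.r_signed

    def test_solvation_enters_both_variants(self):
        c = comp(elec=-10.0, pauli=20.0, disp=-5.0, pol=-1.0, ct=-1.0,
                 solv_correction=-4.0, environment="pcm", epsilon=78.39)
        p_frz = ternary_coordinates(c, "frz")
        p_elst = ternary_coordinates(c, "elst")
        assert p_frz.r_signed == pytest.approx(6.0 / (5 + 2 + 6))
        assert p_elst.r_signed == pytest.approx(-14.0 / (5 + 2 + 14))

    def test_zero_denominator(self):
        with pytest.raises(UndefinedPointError):
            ternary_coordinates(comp())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        elec=st.floats(-300, 300), pauli=st.floats(0, 300),
        disp=st.floats(-300, 0), pol=st.floats(-100, 0),
        ct=st.floats(-100, 0), variant=st.sampled_from(["frz", "elst"]),
        scale=st.floats(0.01, 100.0),
    )
    def test_normalization_and_scale_invariance(
        self, elec, pauli, disp, pol, ct, variant, scale
    ):
        """|r_disp| + |r_orb| + |r_signed| = 1; ratios ignore overall scale."""
        assume(abs(disp) + abs(pol + ct) + abs(elec) > 1e-6)
        assume(abs(elec + pauli) > 1e-6)
        c = comp(elec, pauli, disp, pol, ct)
        p = ternary_coordinates(c, variant)
        assert abs(p.r_disp) + abs(p.r_orb) + abs(p.r_signed) == pytest.approx(
            1.0, abs=1e-9
        )
        assert p.r_disp <= 0 and p.r_orb <= 0
        scaled = ternary_coordinates(
            comp(elec * scale, pauli * scale, disp * scale, pol * scale, ct * scale),
            variant,
        )
        assert scaled.r_disp == pytest.approx(p.r_disp, abs=1e-9)
        assert scaled.r_orb == pytest.approx(p.r_orb, abs=1e-9)
        assert scaled.r_signed == pytest.approx(p.r_signed, abs=1e-9)


class TestReferenceAnchors:
    def test_benzene_dimer_like(self):
        """Dispersion-dominant, attractive electrostatics, repulsive frozen."""
        c = comp(elec=-8.0, pauli=16.0, disp=-20.0, pol=-2.0, ct=-1.0)
        p_frz = ternary_coordinates(c, "frz")
        p_elst = ternary_coordinates(c, "elst")
        assert abs(p_frz.r_disp) > max(abs(p_frz.r_orb), abs(p_frz.r_signed))
        assert p_frz.r_signed > 0  # frozen repulsive
        assert p_elst.r_signed < 0  # electrostatics attractive

    def test_ionic_salt_like(self):
        """An NaCl-like record sits at the electrostatics vertex."""
        c = comp(elec=-500.0, pauli=30.0, disp=-5.0, pol=-15.0, ct=-10.0)
        p = ternary_coordinates(c, "elst")
        assert abs(p.r_signed) > 0.85
        assert p.r_signed < 0


class TestClassify:
    def test_ion_ion(self):
        lbl = classify(record(elec=-400.0, pauli=20.0, disp=-5.0,
                              charges=(1, -1)))
        assert lbl.label == "ion_ion"
        assert lbl.evidence["both_charged"]

    def test_ion_pi_regardless_of_balance(self):
        assert classify(record(elec=-40.0, pauli=20.0, disp=-15.0, pol=-12.0,
                               charges=(1, 0))).label == "ion_pi"
        assert classify(record(elec=5.0, pauli=2.0, disp=-1.0,
                               charges=(0, -1))).label == "ion_pi"

    def test_hunter_sanders(self):
        lbl = classify(record(elec=5.0, pauli=20.0, disp=-24.0))
        assert lbl.label == "hunter_sanders"

    def test_vdw_cfh(self):
        lbl = classify(record(elec=-20.0, pauli=35.0, disp=-30.0))
        assert lbl.label == "vdw_cfh"
        assert not lbl.evidence["elec_repulsive"]
        assert lbl.evidence["frz_repulsive"]

    def test_indeterminate_attractive_frozen(self):
        assert classify(record(elec=-30.0, pauli=10.0, disp=-5.0)).label == (
            "indeterminate"
        )

    def test_non_contact_neutral_repulsive_elec_is_not_hs(self):
        assert classify(record(elec=5.0, pauli=20.0, disp=-24.0,
                               is_pi=False)).label == "indeterminate"

    def test_every_record_gets_exactly_one_label(self):
        suite = sample_mixed_suite(40, seed=5)
        labels = [classify(r).label for r in suite]
        assert all(isinstance(l, str) for l in labels)
        reversed_labels = [classify(r).label for r in reversed(suite)]
        assert labels == list(reversed(reversed_labels))

    def test_missing_charges(self):
        rec = record()
        rec.charges = (0,)
        with pytest.raises(ValueError):
            classify(rec)


class TestPCMScreening:
    def test_ion_pi_orbital_weight_drops_in_solvent(self):
        """Dielectric screening quenches the orbital share of ion-pi pairs."""
        from picontact.synthetic import EDAGenSpec, sample_eda

        records = sample_eda(
            EDAGenSpec(class_label="ion_pi", environment="pcm", n=100, seed=11)
        )
        for r in records:
            gas = ternary_coordinates(r.components_gas, "frz")
            pcm = ternary_coordinates(r.components_pcm, "frz")
            assert abs(pcm.r_orb) < abs(gas.r_orb)


class TestSummarize:
    def test_zero_hs_fraction(self):
        records = [
            record(elec=-10.0, pauli=20.0, disp=-15.0, is_pi=(i < 4),
                   dimer_id=f"r{i}")
            for i in range(10)
        ]
        report = summarize(records)
        assert report.n_records == 10
        assert report.n_pi_contacts == 4
        assert report.hs_fraction_pct == 0

    def test_matches_generator_ground_truth(self):
        suite = sample_mixed_suite(30, seed=2)
        report = summarize(suite)
        truth = {}
        for r in suite:
            lbl = r.extra["true_label"]
            truth[lbl] = truth.get(lbl, 0) + 1
        for lbl, n in truth.items():
            assert report.label_counts[lbl] == n
        assert report.n_records == len(suite)
        assert sum(report.counts_by_pair_type.values()) == len(suite)
        assert sum(report.counts_by_subclass.values()) == len(suite)

    def test_energy_extrema_match_direct_scan(self):
        from picontact.eda import total_interaction

        suite = sample_mixed_suite(25, seed=8)
        report = summarize(suite)
        totals = [total_interaction(r.components_gas) for r in suite]
        lo, hi = report.energy_range_by_pair_type["SCSC"]
        assert lo == pytest.approx(min(totals))
        assert hi == pytest.approx(max(totals))
        assert lo <= hi

    def test_hs_fraction_pooled_over_contacts(self):
        records = [
            record(elec=5.0, pauli=10.0, disp=-20.0, dimer_id="hs1"),
            record(elec=5.0, pauli=10.0, disp=-20.0, dimer_id="hs2"),
            record(elec=-5.0, pauli=10.0, disp=-20.0, dimer_id="cfh1"),
            record(elec=-5.0, pauli=10.0, disp=-20.0, dimer_id="cfh2"),
            record(elec=-5.0, pauli=10.0, disp=-20.0, dimer_id="cfh3"),
            record(elec=-5.0, pauli=10.0, disp=-20.0, dimer_id="off",
                   is_pi=False),
        ]
        report = summarize(records)
        # 2 HS of 5 pi contacts -> 40%
        assert report.hs_fraction_pct == 40

    def test_orphan_contacts_rejected(self):
        class FakeContact:
            dimer_id = "ghost"
            group_a = "x"
            group_b = "y"

        with pytest.raises(ValueError, match="ghost"):
            summarize([record()], [FakeContact()])


def test_points_dataframe_covers_variants_and_environments():
    suite = sample_mixed_suite(10, seed=4)
    df = points_to_dataframe(suite, variants=("frz", "elst"),
                             environments=("gas", "pcm"))
    assert set(df["variant"]) == {"frz", "elst"}
    assert set(df["environment"]) == {"gas", "pcm"}
    assert len(df) == len(suite) * 4
    norms = df[["r_disp", "r_orb", "r_signed"]].abs().sum(axis=1)
    assert np.allclose(norms, 1.0, atol=1e-9)
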