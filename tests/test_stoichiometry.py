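"""Dilution planning, reaction mixes, and equimolar pooling arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblyline.config import RunConfig
from assemblyline.design import PcrSpec
from assemblyline.stoichiometry import (
    DilutionError,
    MixError,
    build_dpn1_mix,
    build_pcr_mix,
    equimolar_volumes,
    plan_primer_dilution,
    plan_template_dilution,
)

PLACEMENTS = {
    "master_mix": (1, "A1"), "water": (1, "B1"),
    "cutsmart_buffer": (1, "C1"), "dpn1": (1, "D1"),
    "f1": (2, "A1"), "r1": (2, "B1"), "t1": (2, "C1"),
}
RXN = PcrSpec(id=1, template_name="t1", fwd_oligo="f1", rev_oligo="r1",
              product_length=1500, ta_opt=60.0)


class TestPrimerDilution:
    def test_defaults_give_2p5_uM_working(self):
        d = plan_primer_dilution()
        assert d.result.conc_value == pytest.approx(2.5)
        assert d.source_volume_ul == pytest.approx(0.5)
        assert d.diluent_volume_ul == pytest.approx(19.5)

    def test_add_volume_2_halves_working_conc(self):
        d = plan_primer_dilution(add_volume=2.0)
        assert d.result.conc_value == pytest.approx(1.25)

    def test_weak_stock_rejected(self):
        with pytest.raises(DilutionError):
            plan_primer_dilution(stock_conc=2.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        stock=st.floats(5.0, 500.0),
        final=st.floats(0.02, 0.5),
        rxn=st.floats(10.0, 100.0),
        add=st.floats(0.5, 5.0),
    )
    def test_c1v1_equals_c2v2(self, stock, final, rxn, add):
        """Amount conservation through the dilution, <= 1e-9 relative."""
        working = final * rxn / add
        if stock <= working:
            return
        d = plan_primer_dilution(stock_conc=stock, final_conc=final,
                                 rxn_volume=rxn, add_volume=add)
        amount_in = d.source.conc_value * d.source_volume_ul
        amount_out = d.result.conc_value * (d.source_volume_ul + d.diluent_volume_ul)
        assert amount_out == pytest.approx(amount_in, rel=1e-9)
        # the planned addition delivers exactly the target final concentration
        assert d.result.conc_value * d.add_volume_ul / rxn == pytest.approx(final, rel=1e-9)


class TestTemplateDilution:
    def test_50_ng_ul_stock(self):
        d = plan_template_dilution(stock_conc=50.0)
        assert d.result.conc_value == pytest.approx(0.5)
        assert d.source_volume_ul == pytest.approx(0.2)
        assert d.diluent_volume_ul == pytest.approx(19.8)

    def test_stock_at_working_conc_passes_through(self):
        d = plan_template_dilution(stock_conc=0.5)
        assert d.is_passthrough
        assert d.add_volume_ul == pytest.approx(1.0)

    def test_too_dilute_stock_rejected(self):
        # 0.5 ng at 0.1 ng/µL needs 5 µL, above the 2.5 µL (10 %) cap
        with pytest.raises(DilutionError, match="too dilute"):
            plan_template_dilution(stock_conc=0.1)


class TestPcrMix:
    def test_default_mix_sums_to_25(self):
        steps = build_pcr_mix(RXN, RunConfig(), PLACEMENTS, (7, "A1"))
        assert len(steps) == 5
        assert sum(s.volume_ul for s in steps) == pytest.approx(25.0)
        by_name = {s.source_name: s.volume_ul for s in steps}
        assert by_name["master_mix"] == pytest.approx(12.5)
        assert by_name["water"] == pytest.approx(9.5)

    def test_final_primer_concentration(self):
        cfg = RunConfig()
        steps = build_pcr_mix(RXN, cfg, PLACEMENTS, (7, "A1"))
        fwd = next(s for s in steps if s.source_name == "f1")
        moles = cfg.primer_working_conc_um * fwd.volume_ul  # pmol
        assert moles / cfg.rxn_volume_ul == pytest.approx(0.1)

    def test_50_ul_scaling(self):
        cfg = RunConfig(rxn_volume_ul=50.0)
        steps = build_pcr_mix(RXN, cfg, PLACEMENTS, (7, "A1"))
        by_name = {s.source_name: s.volume_ul for s in steps}
        assert by_name["f1"] == pytest.approx(2.0)
        assert by_name["water"] == pytest.approx(19.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(factor=st.sampled_from([0.5, 1.0, 2.0, 3.0, 4.0]))
    def test_scaling_linearity(self, factor):
        """Doubling the reaction volume doubles every component exactly."""
        base = {
            s.source_name: s.volume_ul
            for s in build_pcr_mix(RXN, RunConfig(), PLACEMENTS, (7, "A1"))
        }
        scaled = {
            s.source_name: s.volume_ul
            for s in build_pcr_mix(
                RXN, RunConfig(rxn_volume_ul=25.0 * factor), PLACEMENTS, (7, "A1")
            )
        }
        for name, v in base.items():
            assert scaled[name] == pytest.approx(v * factor, rel=1e-12)

    def test_overfull_mix_rejected(self):
        with pytest.raises(MixError, match="overfull"):
            build_pcr_mix(RXN, RunConfig(rxn_volume_ul=25.0, primer_add_volume_ul=10.0),
                          PLACEMENTS, (7, "A1"))


class TestDpn1Mix:
    def test_printed_additions(self):
        steps = build_dpn1_mix(PLACEMENTS, (7, "A1"))
        by_name = {s.source_name: s.volume_ul for s in steps}
        assert by_name == {"water": 19.0, "cutsmart_buffer": 5.0, "dpn1": 1.0}
        assert sum(by_name.values()) + 25.0 == pytest.approx(50.0)

    def test_half_volume_scales_proportionally(self):
        steps = build_dpn1_mix(PLACEMENTS, (7, "A1"), rxn_volume=12.5)
        vols = [s.volume_ul for s in steps]
        assert vols == pytest.approx([9.5, 2.5, 0.5])


class TestEquimolar:
    def test_proportional_volumes(self):
        volumes, predil = equimolar_volumes([(1, 1000), (2, 2000), (3, 4000)])
        assert volumes == pytest.approx({1: 1.0, 2: 2.0, 3: 4.0})
        assert predil == {}

    def test_equal_lengths_all_ref_volume(self):
        volumes, _ = equimolar_volumes([(1, 1500), (2, 1500), (3, 1500)])
        assert set(volumes.values()) == {4.0}

    def test_short_fragment_prediluted(self):
        volumes, predil = equimolar_volumes([(1, 500), (2, 4000)])
        assert volumes[1] == pytest.approx(1.0)
        assert predil[1] == pytest.approx(2.0)
        assert 2 not in predil

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lengths=st.lists(st.integers(100, 10000), min_size=2, max_size=8),
        conc=st.floats(1.0, 50.0),
    )
    def test_moles_equal_under_equal_yield(self, lengths, conc):
        """With equal mass concentration, delivered moles are equal across
        fragments to <= 1e-9 relative, predilution included."""
        frags = list(enumerate(lengths))
        volumes, predil = equimolar_volumes(frags)
        moles = []
        for fid, length in frags:
            c = conc / predil.get(fid, 1.0)   # predilution cuts concentration
            moles.append(c * volumes[fid] / length)
        ref = moles[0]
        for m in moles[1:]:
            assert m == pytest.approx(ref, rel=1e-9)
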