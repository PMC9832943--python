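"""End-to-end run builders: structure, ordering, flags, reproducibility."""

import dataclasses
from pathlib import Path

import pytest

from assemblyline.config import RunConfig
from assemblyline.design import Strategy, parse_design
from assemblyline.fixtures import FixtureSpec, chromoprotein_like_fixture, generate_bundle
from assemblyline.stoichiometry import TransferStep
from assemblyline.workflows import (
    Message,
    Pause,
    StrategyError,
    Thermocycle,
    build_aqua_workflow,
    build_goldengate_workflow,
    build_onepot_iva_workflow,
    build_pcr_workflow,
    emit_artifacts,
)


def _transfers_into(rb, dest):
    return [s for s in rb.transfers if s.dest == dest]


class TestPcrWorkflow:
    def test_each_pcr_well_gets_five_components(self, config):
        bundle = generate_bundle(
            FixtureSpec(n_assemblies=1, fragments_per_assembly=5, seed=9)
        )
        rb = build_pcr_workflow(bundle, config)
        first_pause = next(s.ordinal for s in rb.steps if isinstance(s, Pause))
        for rid in range(1, 6):
            dest = rb.layout.placements[f"pcr_{rid}"]
            mix = [s for s in _transfers_into(rb, dest) if s.ordinal < first_pause]
            assert len(mix) == 5

    def test_pause_precedes_external_amplification(self, small_bundle, config):
        rb = build_pcr_workflow(small_bundle, config)
        for i, step in enumerate(rb.steps):
            if isinstance(step, Thermocycle) and step.location == "external":
                assert isinstance(rb.steps[i - 1], Pause)
                break
        else:
            pytest.fail("no external thermocycle step found")

    def test_dpn1_flag_disables_digestion(self, small_bundle):
        rb = build_pcr_workflow(small_bundle, RunConfig(dpn1_enabled=False))
        assert not any(
            isinstance(s, Thermocycle) and s.kind == "digestion" for s in rb.steps
        )
        assert not any(s.source_name == "dpn1" for s in rb.transfers)

    def test_ordinals_strictly_increasing(self, small_bundle, config):
        rb = build_pcr_workflow(small_bundle, config)
        ordinals = [s.ordinal for s in rb.steps]
        assert ordinals == sorted(set(ordinals))


class TestGoldenGate:
    def test_cleanup_pause_present(self, chromo_gg, config):
        bundle, _ = chromo_gg
        rb = build_goldengate_workflow(bundle, config)
        assert any(
            isinstance(s, Pause) and "clean" in s.message.lower() for s in rb.steps
        )

    def test_assembly_wells_structure(self, chromo_gg, config):
        """4 assembly wells, each: 4 fragment volumes + 3 reagents + water."""
        bundle, _ = chromo_gg
        rb = build_goldengate_workflow(bundle, config)
        pools = [k for k in rb.layout.placements if k.startswith("pool_")]
        assert len(pools) == 4
        for pool in pools:
            dest = rb.layout.placements[pool]
            steps = _transfers_into(rb, dest)
            assert len(steps) == 8
            names = [s.source_name for s in steps]
            assert names[-4:] == ["ligase_buffer", "typeIIs_enzyme", "ligase", "water"]
            assert sum(s.volume_ul for s in steps) == pytest.approx(20.0)

    def test_destination_plasmid_mode_skips_backbone_pcrs(self, chromo_gg):
        bundle, _ = chromo_gg
        cfg = RunConfig(destination_backbone_pieces=(2, 5, 6))
        rb = build_goldengate_workflow(bundle, cfg)
        # only the 4 color-piece PCRs are planned
        assert sorted(rb.plan.assignments) == [1, 3, 4, 7]
        assert "pcr_2" not in rb.layout.placements
        dest = rb.layout.placements["pool_construct_1"]
        names = [s.source_name for s in _transfers_into(rb, dest)]
        assert "destination_plasmid" in names

    def test_external_cycling_flag(self, chromo_gg):
        bundle, _ = chromo_gg
        rb = build_goldengate_workflow(bundle, RunConfig(gg_external_cycling=True))
        gg = [s for s in rb.steps if isinstance(s, Thermocycle) and s.kind == "assembly"]
        assert gg[0].location == "external"
        assert isinstance(rb.steps[gg[0].ordinal - 1], Pause)


class TestOnepotIva:
    def test_two_fragment_constructs_one_well_each(self, config):
        bundle = generate_bundle(
            FixtureSpec(n_assemblies=2, fragments_per_assembly=2, seed=5,
                        strategy=Strategy.IVA_ONEPOT)
        )
        rb = build_onepot_iva_workflow(bundle, config)
        for i in (1, 2):
            dest = rb.layout.placements[f"pcr_{i}"]
            names = [s.source_name for s in _transfers_into(rb, dest)]
            assert sum(1 for n in names if n.startswith("oligo_")) == 4
        assert isinstance(rb.steps[-1], Message)

    def test_more_than_two_fragments_refused(self, chromo_gg, config):
        bundle, _ = chromo_gg
        bundle = dataclasses.replace(bundle, strategy=Strategy.IVA_ONEPOT)
        with pytest.raises(StrategyError, match="one-pot"):
            build_onepot_iva_workflow(bundle, config)

    def test_override_emits_warning(self, chromo_gg):
        bundle, _ = chromo_gg
        rb = build_onepot_iva_workflow(bundle, RunConfig(onepot_override=True))
        assert any(
            isinstance(s, Message) and "WARNING" in s.text for s in rb.steps
        )


class TestAqua:
    def test_no_enzymes_no_assembly_cycle(self, chromo_aqua, config):
        bundle, _ = chromo_aqua
        rb = build_aqua_workflow(bundle, config)
        pools = [k for k in rb.layout.placements if k.startswith("pool_")]
        assert len(pools) == 4
        assert not any(
            s.source_name in ("ligase", "typeIIs_enzyme", "ligase_buffer")
            for s in rb.transfers
        )
        assert not any(
            isinstance(s, Thermocycle) and s.kind == "assembly" for s in rb.steps
        )
        assert isinstance(rb.steps[-1], Message)

    def test_pool_volumes_proportional_to_length(self, chromo_aqua, config):
        bundle, manifest = chromo_aqua
        rb = build_aqua_workflow(bundle, config)
        lengths = {p["id"]: p["length"] for p in manifest["pieces"]}
        combo = bundle.combinations[0]
        dest = rb.layout.placements[f"pool_{combo.construct_name}"]
        vols = {s.source_name: s.volume_ul for s in _transfers_into(rb, dest)}
        max_len = max(lengths[pid] for pid in combo.piece_ids)
        for pid in combo.piece_ids:
            expected = 4.0 * lengths[pid] / max_len
            assert vols[f"pcr_{pid}"] == pytest.approx(expected)

    def test_pcr_prefix_identical_to_goldengate(self, tmp_path, config):
        """Same design, two strategies: identical steps up to the digestion."""
        p_gg, _ = chromoprotein_like_fixture(tmp_path / "g", Strategy.GOLDEN_GATE)
        p_aq, _ = chromoprotein_like_fixture(tmp_path / "a", Strategy.AQUA)
        rb_gg = build_goldengate_workflow(parse_design(p_gg, Strategy.GOLDEN_GATE), config)
        rb_aq = build_aqua_workflow(parse_design(p_aq, Strategy.AQUA), config)
        end = rb_gg.stage_boundaries[list(rb_gg.stage_boundaries)[-2]]
        for s_gg, s_aq in zip(rb_gg.steps, rb_aq.steps):
            if s_gg.ordinal > end:
                break
            assert type(s_gg) is type(s_aq)
            if isinstance(s_gg, TransferStep):
                assert (s_gg.source, s_gg.dest, s_gg.volume_ul) == (
                    s_aq.source, s_aq.dest, s_aq.volume_ul
                )


class TestArtifacts:
    def test_snapshot_reproduces_byte_identical_artifacts(self, chromo_gg, tmp_path):
        bundle, _ = chromo_gg
        rb1 = build_goldengate_workflow(bundle, RunConfig(pcr_cycles=36))
        emit_artifacts(rb1, tmp_path / "run1")
        cfg2 = RunConfig.from_dict(rb1.config_snapshot)
        rb2 = build_goldengate_workflow(bundle, cfg2)
        emit_artifacts(rb2, tmp_path / "run2")
        files1 = sorted(Path(tmp_path / "run1").iterdir())
        assert len(files1) >= 9
        for f1 in files1:
            f2 = tmp_path / "run2" / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_expected_artifact_set(self, chromo_gg, tmp_path, config):
        bundle, _ = chromo_gg
        rb = build_goldengate_workflow(bundle, config)
        artifacts = emit_artifacts(rb, tmp_path / "out")
        for name in ("oligo.csv", "pcr.csv", "assembly.csv", "combinations.csv",
                     "reagent_setup.txt", "reactions_setup.txt", "picklist.csv",
                     "runbundle.json"):
            assert name in artifacts
            assert Path(artifacts[name]).exists()

    def test_picklist_schema(self, small_bundle, tmp_path, config):
        rb = build_pcr_workflow(small_bundle, config)
        artifacts = emit_artifacts(rb, tmp_path)
        header = Path(artifacts["picklist.csv"]).read_text().splitlines()[0]
        assert header == ("ordinal,source_slot,source_well,dest_slot,dest_well,"
                          "volume_ul,mix_reps,mix_vol_ul")
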