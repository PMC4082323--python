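import json

import numpy as np
import pytest

from naspkit import composition as comp
from naspkit import divergence as dv
from naspkit import motifs
from naspkit import synthetic_data as syn
from naspkit.seqio import GeneticCode, translate


def plain_architecture(n_codons: int, seed: int = 1) -> syn.Architecture:
    return syn.make_architecture({"ALL": n_codons}, seed=seed)


class TestArchitecture:
    def test_default_tpr_blocks_span_34(self):
        arch = syn.make_architecture()
        for label in ("TPR1", "TPR2", "TPR3", "TPR4"):
            assert arch.regions.length(label) == 34

    def test_acidic_tract_de_fraction(self):
        arch = syn.make_architecture()
        start, end = arch.regions["ACIDIC"]
        tract = arch.scaffold[start - 1:end]
        de = tract.count("D") + tract.count("E")
        assert de / len(tract) >= 0.5

    def test_nnr_scaffold_contains_motif(self):
        arch = syn.make_architecture(nnr=True)
        from naspkit.seqio import Sequence
        hits = motifs.scan_nnr(Sequence("root", arch.scaffold, "protein"))
        assert len(hits) >= 1

    def test_region_map_covers_scaffold(self):
        arch = syn.make_architecture()
        covered = sum(arch.regions.length(lbl) for lbl in arch.regions.labels)
        assert covered == arch.n_codons


class TestSimulateFamily:
    def test_omega_zero_freezes_protein(self):
        params = syn.SimulationParams(seed=3, n_leaves=4, radius=0.4,
                                      omega=0.0, omega_by_region={})
        fam = syn.simulate_family(params)
        prots = {translate(s).residues for s in fam.cds}
        assert prots == {fam.architecture.scaffold}

    def test_same_seed_identical_output(self, tmp_path):
        params = syn.SimulationParams(seed=9, n_leaves=5, radius=0.3)
        fam1 = syn.simulate_family(params)
        fam2 = syn.simulate_family(params)
        assert [s.residues for s in fam1.cds] == [s.residues for s in fam2.cds]
        fam1.save(tmp_path / "a")
        fam2.save(tmp_path / "b")
        assert ((tmp_path / "a" / "family.fasta").read_bytes()
                == (tmp_path / "b" / "family.fasta").read_bytes())

    def test_no_internal_stops(self, std_code):
        params = syn.SimulationParams(seed=13, n_leaves=6, radius=0.8)
        fam = syn.simulate_family(params)
        for seq in fam.cds:
            for i in range(0, len(seq.residues) - 3, 3):
                assert not std_code.is_stop(seq.residues[i:i + 3])

    @pytest.mark.parametrize("target", [0.35, 0.5, 0.65])
    def test_gc3_matches_target(self, target):
        arch = plain_architecture(3000)
        params = syn.SimulationParams(seed=5, n_leaves=2, radius=0.3,
                                      omega=0.1, omega_by_region={},
                                      gc3_target=target)
        fam = syn.simulate_family(params, arch)
        for seq in fam.cds:
            gc3 = comp.gc_by_position(seq)[2]
            assert gc3 == pytest.approx(target, abs=0.02)

    def test_event_ratio_converges_to_omega_times_site_ratio(self, std_code):
        arch = plain_architecture(10000)
        omega = 0.2
        tot_syn = tot_non = 0
        S = N = 0.0
        for seed in (1, 2, 3):
            params = syn.SimulationParams(seed=seed, n_leaves=2, radius=0.3,
                                          omega=omega, omega_by_region={},
                                          kappa=2.0)
            fam = syn.simulate_family(params, arch)
            ev = fam.region_events["ALL"]
            tot_syn += ev["syn"]
            tot_non += ev["nonsyn"]
            for seq in fam.cds:
                for i in range(0, len(seq.residues), 3):
                    s, n = dv.ng_site_counts(seq.residues[i:i + 3], 1.0, std_code)
                    S += s
                    N += n
        assert tot_non / tot_syn == pytest.approx(omega * N / S, rel=0.10)

    def test_ps_pn_consistency_under_neutral_evolution(self):
        # omega = 1, kappa = 1, low divergence: the counting method should
        # recover pN/pS near 1 on its own simulated data
        arch = plain_architecture(10000)
        params = syn.SimulationParams(seed=1, n_leaves=2, radius=0.05,
                                      omega=1.0, omega_by_region={}, kappa=1.0)
        fam = syn.simulate_family(params, arch)
        ps, pn = dv.ps_pn(fam.alignment, 0.5, n_boot=100, seed=1)
        assert 0.8 <= pn.value / ps.value <= 1.2

    def test_newick_tree_input(self):
        params = syn.SimulationParams(
            seed=2, tree="((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        fam = syn.simulate_family(params, plain_architecture(200))
        assert sorted(fam.cds.ids) == ["A", "B", "C", "D"]

    def test_branch_length_required(self):
        params = syn.SimulationParams(seed=2, tree="((A:0.1,B),C:0.1);")
        with pytest.raises(ValueError, match="length"):
            syn.simulate_family(params, plain_architecture(100))

    def test_truth_file_round_trip(self, tmp_path):
        params = syn.SimulationParams(seed=21, n_leaves=4, radius=0.2)
        fam = syn.simulate_family(params)
        fam.save(tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["seed"] == 21
        assert truth["n_leaves"] == 4
        total_events = sum(v["syn"] + v["nonsyn"]
                           for v in truth["region_events"].values())
        assert total_events == sum(v["syn"] + v["nonsyn"]
                                   for v in fam.region_events.values())


class TestMutationBiasMode:
    def test_amino_acid_classes_track_gc(self):
        # neutral expectation: GAPW rises and FYMINK falls with genomic GC
        arch = plain_architecture(400, seed=2)
        gvals = {f"L{i:02d}": g
                 for i, g in enumerate(np.linspace(0.3, 0.7, 30), start=1)}
        params = syn.SimulationParams(seed=42, n_leaves=30, radius=2.5,
                                      omega=1.0, omega_by_region={},
                                      gc3_target=gvals, mode="mutation-bias")
        fam = syn.simulate_family(params, arch)
        from naspkit import neutrality as neu
        reports = [comp.composition_report(s) for s in fam.cds]
        rows = {r.label: r for r in neu.neutrality_correlations(reports)}
        assert rows["GC4f vs GAPW"].r_s > 0
        assert rows["GC4f vs GAPW"].p_value < 0.05
        assert rows["GC4f vs FYMINK"].r_s < 0
        assert rows["GC4f vs FYMINK"].p_value < 0.05


class TestDuplication:
    def test_bookkeeping_ids(self):
        params = syn.SimulationParams(seed=4, n_leaves=4, radius=0.1)
        fam = syn.simulate_duplication(params, divergence_boost=2.0)
        assert len(fam.cds) == 8
        assert sorted(fam.paralog_of.values()) == ["1"] * 4 + ["2"] * 4
        assert all(i.endswith(("_1", "_2")) for i in fam.cds.ids)

    def test_paralog_clustering_recovered_by_nj(self):
        from naspkit import trees
        params = syn.SimulationParams(seed=9, n_leaves=4, radius=0.08,
                                      omega=0.2, omega_by_region={})
        fam = syn.simulate_duplication(params, divergence_boost=3.0)
        dm = trees.DistanceMatrix.from_alignment(fam.alignment, "aa")
        tree = trees.nj(dm)
        paralog1 = [i for i in fam.cds.ids if i.endswith("_1")]
        assert trees.same_split(tree, paralog1)

    def test_paralog_gc3_contrast(self):
        arch = syn.make_architecture(
            {"NTERM": 20, "TPR1": 34, "TPR2": 34, "ACIDIC": 20,
             "TPR3": 34, "TPR4": 34, "CTERM": 824},  # 1000 codons total
            nnr=True, seed=3)
        params = syn.SimulationParams(seed=9, n_leaves=4, radius=0.08,
                                      omega=0.2, omega_by_region={})
        fam = syn.simulate_duplication(params, arch, divergence_boost=3.0,
                                       gc3_paralogs=(0.71, 0.49))
        gc1 = np.mean([comp.gc_by_position(s)[2]
                       for s in fam.cds if s.id.endswith("_1")])
        gc2 = np.mean([comp.gc_by_position(s)[2]
                       for s in fam.cds if s.id.endswith("_2")])
        assert gc1 - gc2 >= 0.15

    def test_nnr_only_in_paralog_two(self):
        params = syn.SimulationParams(seed=9, n_leaves=4, radius=0.08,
                                      omega=0.2, omega_by_region={})
        arch = syn.make_architecture(nnr=True, seed=3)
        fam = syn.simulate_duplication(params, arch, divergence_boost=3.0)
        for seq in fam.cds:
            hits = motifs.scan_nnr(translate(seq))
            if seq.id.endswith("_2"):
                assert len(hits) >= 1
            else:
                assert len(hits) == 0

    def test_unknown_duplication_node_rejected(self):
        params = syn.SimulationParams(seed=4, n_leaves=4, radius=0.1)
        with pytest.raises(ValueError, match="not found"):
            syn.simulate_duplication(params, duplication="nonexistent")


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "weird"},
            {"kappa": 0.0},
            {"gc3_target": 1.5},
            {"omega": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.SimulationParams(seed=1, **kwargs)
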