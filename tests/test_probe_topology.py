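"""Probe reduction statistics and consensus topology calls."""

import numpy as np
import pytest

from memtrap.io_formats import IntensityTable, read_pdb
from memtrap.probe_topology import (
    consensus_topology,
    map_to_structure,
    reduction_profile,
)
from memtrap.synthetic_data import (
    HIAPP_SEQUENCE,
    MEMBRANE_SET,
    SOLVENT_SET,
    ProbeSpec,
    SimSpec,
    gen_membrane_complex,
    gen_probe_tables,
)
from tests.conftest import bead_model


def itab(entries, label="none"):
    return IntensityTable(entries=entries, probe_label=label)


class TestReductionProfile:
    def test_arithmetic_and_above_average(self):
        ref = itab({1: 100.0, 2: 100.0, 3: 100.0})
        probe = itab({1: 10.0, 2: 90.0, 3: 80.0}, label="ND")
        prof = reduction_profile(ref, probe)
        assert prof.reductions == pytest.approx({1: 0.9, 2: 0.1, 3: 0.2})
        assert prof.mean_reduction == pytest.approx(0.4)
        assert prof.above_average == {1}

    def test_null_probe(self):
        ref = itab({i: 50.0 for i in range(1, 11)})
        prof = reduction_profile(ref, itab(ref.entries, label="Gd"))
        assert all(r == 0.0 for r in prof.reductions.values())
        assert prof.above_average == set()

    def test_scale_invariance(self):
        ref = itab({1: 10.0, 2: 20.0, 3: 40.0})
        probe = itab({1: 5.0, 2: 18.0, 3: 10.0}, label="DSA")
        p1 = reduction_profile(ref, probe)
        c = 7.3
        p2 = reduction_profile(
            itab({k: c * v for k, v in ref.entries.items()}),
            itab({k: c * v for k, v in probe.entries.items()}, label="DSA"),
        )
        assert p2.reductions == pytest.approx(p1.reductions)

    def test_above_average_never_everything(self):
        rng = np.random.default_rng(5)
        ref = itab({i: 100.0 for i in range(1, 30)})
        probe = itab({i: float(rng.uniform(10, 90)) for i in range(1, 30)},
                     label="ND")
        prof = reduction_profile(ref, probe)
        assert len(prof.above_average) < len(prof.reductions)

    def test_disjoint_tables_rejected(self):
        with pytest.raises(ValueError, match="share no residues"):
            reduction_profile(itab({1: 1.0}), itab({2: 1.0}, label="ND"))

    def test_one_sided_residues_excluded_with_warning(self):
        ref = itab({1: 100.0, 2: 100.0, 3: 100.0})
        probe = itab({1: 50.0, 2: 50.0, 4: 1.0}, label="ND")
        with pytest.warns(UserWarning, match=r"\[3, 4\]"):
            prof = reduction_profile(ref, probe)
        assert set(prof.reductions) == {1, 2}

    def test_zero_reference_excluded(self):
        ref = itab({1: 0.0, 2: 100.0, 3: 100.0})
        probe = itab({1: 0.0, 2: 40.0, 3: 90.0}, label="Gd")
        with pytest.warns(UserWarning, match="zero reference"):
            prof = reduction_profile(ref, probe)
        assert set(prof.reductions) == {2, 3}

    def test_strong_negative_reduction_flagged(self):
        ref = itab({1: 100.0, 2: 100.0})
        probe = itab({1: 140.0, 2: 50.0}, label="ND")
        prof = reduction_profile(ref, probe)
        assert prof.flagged_negative == {1}

    def test_median_mad_rule_resists_outliers(self):
        # two fully broadened residues drag the mean but not the median
        ref = itab({i: 100.0 for i in range(1, 21)})
        entries = {i: 95.0 for i in range(1, 21)}
        entries[1] = entries[2] = 1.0
        entries[3] = 90.0   # modestly broadened, hidden by the inflated mean
        prof_mean = reduction_profile(ref, itab(entries, label="ND"))
        prof_rob = reduction_profile(ref, itab(entries, label="ND"),
                                     threshold_rule="median_mad")
        assert 3 not in prof_mean.above_average
        assert 3 in prof_rob.above_average


class TestConsensusTopology:
    def test_hiapp_fixture_exact_sets(self, sim_spec):
        iref, ind, igd, idsa, truth = gen_probe_tables(sim_spec)
        call = consensus_topology(
            reduction_profile(iref, ind),
            reduction_profile(iref, igd),
            reduction_profile(iref, idsa),
            HIAPP_SEQUENCE,
        )
        assert call.residues("membrane") == set(MEMBRANE_SET)
        assert call.residues("solvent") == set(SOLVENT_SET)
        assert call.residues("ambiguous") == set()

    def test_conflicting_evidence_is_ambiguous(self):
        seq = "AAA"
        ref = itab({1: 100.0, 2: 100.0, 3: 100.0})
        nd = reduction_profile(ref, itab({1: 10.0, 2: 100.0, 3: 100.0},
                                         label="ND"))
        gd = reduction_profile(ref, itab({1: 10.0, 2: 100.0, 3: 100.0},
                                         label="Gd"))
        dsa = reduction_profile(ref, itab({1: 100.0, 2: 100.0, 3: 100.0},
                                          label="DSA"))
        call = consensus_topology(nd, gd, dsa, seq)
        assert call.labels[1] == "ambiguous"

    def test_no_flags_means_unclassified(self):
        seq = "AAAA"
        ref = itab({i: 100.0 for i in range(1, 5)})
        same = lambda lab: reduction_profile(ref, itab(ref.entries, label=lab))
        call = consensus_topology(same("ND"), same("Gd"), same("DSA"), seq)
        assert all(lab == "unclassified" for lab in call.labels.values())

    def test_wrong_probe_order_rejected(self):
        ref = itab({1: 100.0})
        nd = reduction_profile(ref, itab({1: 50.0}, label="ND"))
        gd = reduction_profile(ref, itab({1: 50.0}, label="Gd"))
        dsa = reduction_profile(ref, itab({1: 50.0}, label="DSA"))
        with pytest.raises(ValueError, match="expected probe"):
            consensus_topology(gd, nd, dsa, "A")

    def test_permutation_equivariance(self):
        """Permuting residue identities in the inputs permutes the labels."""
        spec = SimSpec(seed=42)
        iref, ind, igd, idsa, _ = gen_probe_tables(spec)
        call = consensus_topology(
            reduction_profile(iref, ind), reduction_profile(iref, igd),
            reduction_profile(iref, idsa), HIAPP_SEQUENCE,
        )
        rng = np.random.default_rng(0)
        perm = {a: b for a, b in zip(range(1, 38),
                                     rng.permutation(np.arange(1, 38)))}
        seq_p = "".join(HIAPP_SEQUENCE[next(k for k, v in perm.items()
                                            if v == i) - 1]
                        for i in range(1, 38))

        def permute(tab):
            return itab({int(perm[k]): v for k, v in tab.entries.items()},
                        label=tab.probe_label)

        call_p = consensus_topology(
            reduction_profile(permute(iref), permute(ind)),
            reduction_profile(permute(iref), permute(igd)),
            reduction_profile(permute(iref), permute(idsa)),
            seq_p,
        )
        for ri in range(1, 38):
            assert call_p.labels[int(perm[ri])] == call.labels[ri]

    def test_monte_carlo_recovery(self):
        """100 random topologies at 5% intensity noise: residue-level
        label accuracy >= 90%."""
        rng = np.random.default_rng(314)
        hits = total = 0
        for _ in range(100):
            residues = np.arange(1, 38)
            rng.shuffle(residues)
            n_mem = int(rng.integers(4, 10))
            n_sol = int(rng.integers(6, 14))
            mem = frozenset(int(r) for r in residues[:n_mem])
            sol = frozenset(int(r) for r in residues[n_mem:n_mem + n_sol])
            spec = SimSpec(
                seed=int(rng.integers(0, 2**31)),
                probes=ProbeSpec(membrane=mem, solvent=sol),
            )
            iref, ind, igd, idsa, truth = gen_probe_tables(spec)
            call = consensus_topology(
                reduction_profile(iref, ind), reduction_profile(iref, igd),
                reduction_profile(iref, idsa), HIAPP_SEQUENCE,
            )
            for ri in range(1, 38):
                total += 1
                hits += call.labels[ri] == truth[ri]
        assert hits / total >= 0.90


class TestMapToStructure:
    def test_bfactor_encoding(self, tmp_path):
        from memtrap.probe_topology import TopologyCall
        model = bead_model([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        call = TopologyCall(
            labels={1: "membrane", 2: "solvent", 3: "unclassified"},
            evidence={i: {"ND": False, "Gd": False, "DSA": False}
                      for i in (1, 2, 3)},
        )
        out = tmp_path / "mapped.pdb"
        map_to_structure(call, model, out, tmp_path / "legend.tsv")
        back = read_pdb(out, group_rules={"A": "peptide"},
                        radius_set="martini-cg")
        # b-factors land in columns 61-66 of the written records
        bvals = [float(line[60:66]) for line in out.read_text().splitlines()
                 if line.startswith("ATOM")]
        assert bvals == [1.0, 2.0, 0.0]
        assert back.natoms == 3

    def test_empty_call_all_zero(self, tmp_path):
        from memtrap.probe_topology import TopologyCall
        model = bead_model([[0, 0, 0], [1, 0, 0]])
        call = TopologyCall(labels={}, evidence={})
        out = tmp_path / "m.pdb"
        map_to_structure(call, model, out)
        bvals = [float(line[60:66]) for line in out.read_text().splitlines()
                 if line.startswith("ATOM")]
        assert bvals == [0.0, 0.0]

    def test_missing_residue_warns_not_fatal(self, tmp_path, sim_spec):
        alone, _, _ = gen_membrane_complex(sim_spec)
        # structure covers 1..37; label a residue it lacks
        from memtrap.probe_topology import TopologyCall
        labels = {i: "unclassified" for i in range(1, 38)}
        labels[38] = "membrane"
        call = TopologyCall(labels=labels, evidence={})
        with pytest.warns(UserWarning, match="38"):
            missing = map_to_structure(call, alone, tmp_path / "m.pdb")
        assert missing == [38]
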