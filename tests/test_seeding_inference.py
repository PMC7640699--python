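import subprocess
import textwrap

import numpy as np
import pytest

from metpair.ccf_clonality import CloneCluster
from metpair.io_formats import MutationRecord
from metpair.seeding_inference import (
    build_parsimony_tree,
    call_seeding_mode,
    can_be_siblings,
    check_pigeonhole,
    partition_mutations,
)


def mut(pos, sample, alt=20, depth=100):
    return MutationRecord(chrom="1", pos=pos, ref="C", alt="A",
                          sample_id=sample, t_depth=depth, t_alt=alt,
                          n_depth=50, n_alt=0)


class TestPartition:
    def test_kept_in_both_is_shared(self):
        part = partition_mutations([mut(1, "P")], [mut(1, "M")])
        assert part.shared == {("1", 1, "C", "A")}
        assert not part.primary_only and not part.metastasis_only

    def test_absent_in_other_is_private(self):
        part = partition_mutations(
            [mut(1, "P")], [], all_primary=[mut(1, "P")],
            all_metastasis=[mut(1, "M", alt=0, depth=200)])
        assert part.primary_only == {("1", 1, "C", "A")}

    def test_rescue_by_low_alt_reads(self):
        low = mut(1, "M", alt=3, depth=200)  # fails 5% VAF, rescues presence
        part = partition_mutations([mut(1, "P")], [], [mut(1, "P")], [low])
        assert part.shared == {("1", 1, "C", "A")}
        part_off = partition_mutations([mut(1, "P")], [], [mut(1, "P")],
                                       [low], rescue=False)
        assert part_off.primary_only == {("1", 1, "C", "A")}

    def test_partition_is_disjoint_and_covers_union(self, mono_patient,
                                                    fit_patient):
        bundle, truth = mono_patient
        _, _, kept_p, kept_m = fit_patient(bundle)
        part = partition_mutations(
            kept_p, kept_m, bundle.mutations_of(bundle.primary_id),
            bundle.mutations_of(bundle.metastasis_id))
        assert not part.shared & part.primary_only
        assert not part.shared & part.metastasis_only
        assert not part.primary_only & part.metastasis_only
        assert part.union >= {m.key for m in kept_p} | {m.key for m in kept_m}

    def test_shared_fraction_tracks_truth(self, mono_patient, fit_patient):
        bundle, truth = mono_patient
        _, _, kept_p, kept_m = fit_patient(bundle)
        part = partition_mutations(
            kept_p, kept_m, bundle.mutations_of(bundle.primary_id),
            bundle.mutations_of(bundle.metastasis_id))
        assert part.shared_fraction == pytest.approx(truth.trunk_fraction,
                                                     abs=0.05)


class TestPigeonhole:
    def test_examples(self):
        assert can_be_siblings(0.6, 0.3, 1.0)
        assert not can_be_siblings(0.6, 0.7, 1.0)       # 1.3 > 1.05
        assert can_be_siblings(0.5, 0.55, 1.0)          # 1.05 <= 1.05

    def test_check_reports_violating_pair(self):
        clusters = [
            CloneCluster(0, {"P": 1.0}, tuple(range(40)), 40),
            CloneCluster(1, {"P": 0.6}, tuple(range(30)), 30),
            CloneCluster(2, {"P": 0.7}, tuple(range(20)), 20),
        ]
        violations = check_pigeonhole(clusters, "P")
        assert len(violations) == 1
        assert violations[0][:2] == (1, 2)

    def test_consistent_architecture_clean(self):
        clusters = [
            CloneCluster(0, {"P": 1.0}, tuple(range(40)), 40),
            CloneCluster(1, {"P": 0.5}, tuple(range(30)), 30),
            CloneCluster(2, {"P": 0.3}, tuple(range(20)), 20),
        ]
        assert check_pigeonhole(clusters, "P") == []


def cl(cid, p, m, size=40):
    return CloneCluster(cid, {"M": m, "P": p}, tuple(range(size)), size)


class TestSeedingMode:
    def test_monoclonal(self):
        call = call_seeding_mode([cl(0, 1, 1), cl(1, 0.4, 0), cl(2, 0, 0.7)],
                                 "P", "M")
        assert call.mode == "monoclonal"
        assert call.founding_cluster_id == 0
        assert call.shared_cluster_ids == (0,)
        assert call.private_cluster_ids_by_sample == {"P": (1,), "M": (2,)}

    def test_polyclonal_shared_subclone(self):
        call = call_seeding_mode([cl(0, 1, 1), cl(1, 0.4, 0.3)], "P", "M")
        assert call.mode == "polyclonal"
        assert set(call.shared_cluster_ids) == {0, 1}

    def test_no_shared_cluster_is_error(self):
        with pytest.raises(ValueError, match="common ancestry"):
            call_seeding_mode([cl(0, 1, 0.0), cl(1, 0, 0.9)], "P", "M")

    def test_threshold_controls_sharing(self):
        clusters = [cl(0, 1, 1), cl(1, 0.4, 0.04)]
        assert call_seeding_mode(clusters, "P", "M").mode == "monoclonal"
        assert call_seeding_mode(clusters, "P", "M",
                                 min_shared_ccf=0.03).mode == "polyclonal"

    def test_simulated_pair_modes(self, mono_patient, poly_patient,
                                  fit_patient):
        for (bundle, truth) in (mono_patient, poly_patient):
            _, res, _, _ = fit_patient(bundle)
            call = call_seeding_mode(res.clusters, bundle.primary_id,
                                     bundle.metastasis_id)
            assert call.mode == truth.seeding_mode


class TestParsimonyTree:
    def test_hand_fitch_score(self):
        presence = np.array([[1, 1, 0],   # P
                             [1, 0, 1],   # M
                             [0, 0, 0]])  # N
        tree = build_parsimony_tree(presence, ["P", "M", "N"], outgroup="N")
        assert tree.score == 3
        assert sum(tree.branch_lengths.values()) == 3

    def test_identical_samples_zero_length_split(self):
        presence = np.array([[1, 1], [1, 1], [0, 0]])
        tree = build_parsimony_tree(presence, ["P", "M", "N"])
        # both shared mutations change once each, on the trunk
        assert tree.score == 2
        # the P and M leaves diverge by nothing
        assert "P:0" in tree.newick and "M:0" in tree.newick

    def test_single_variable_column(self):
        presence = np.array([[1], [0], [0]])
        assert build_parsimony_tree(presence, ["P", "M", "N"]).score == 1

    def test_four_taxa_recovers_split(self):
        # P1,P2 share 5 mutations; M1,M2 share 5; trunk has 3
        trunk = np.ones((4, 3), dtype=int)
        p_block = np.array([[1]*5, [1]*5, [0]*5, [0]*5])
        m_block = np.array([[0]*5, [0]*5, [1]*5, [1]*5])
        presence = np.hstack([trunk, p_block, m_block])
        presence = np.vstack([presence, np.zeros((1, 13), dtype=int)])
        tree = build_parsimony_tree(presence, ["P1", "P2", "M1", "M2", "N"],
                                    outgroup="N")
        assert tree.score == 13  # perfect split: every column changes once

    def test_too_many_samples_rejected(self):
        presence = np.zeros((9, 2), dtype=int)
        with pytest.raises(ValueError, match="8 samples"):
            build_parsimony_tree(presence, [f"S{i}" for i in range(9)])

    def test_newick_parses(self):
        import dendropy

        presence = np.array([[1, 1, 0], [1, 0, 1], [0, 0, 0]])
        tree = build_parsimony_tree(presence, ["P", "M", "N"])
        parsed = dendropy.Tree.get(data=tree.newick, schema="newick")
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert labels == {"P", "M", "N"}


class TestAgainstPhangorn:
    def test_score_matches_r_phangorn(self, tmp_path):
        """Independent oracle: phangorn's parsimony on the same matrix."""
        rng = np.random.default_rng(77)
        presence = rng.integers(0, 2, size=(5, 12))
        presence[4] = 0  # outgroup
        ours = build_parsimony_tree(presence, ["A", "B", "C", "D", "N"],
                                    outgroup="N")
        script = textwrap.dedent(f"""
            suppressMessages(library(phangorn))
            mat <- rbind({",".join(f'c({",".join(map(str, row))})'
                                   for row in presence)})
            rownames(mat) <- c("A","B","C","D","N")
            dat <- phyDat(mat, type="USER", levels=c(0,1))
            tr <- pratchet(dat, trace=0)
            cat(parsimony(tr, dat))
        """)
        r_file = tmp_path / "pars.R"
        r_file.write_text(script)
        try:
            out = subprocess.run(["Rscript", str(r_file)], check=True,
                                 capture_output=True, text=True, timeout=300)
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript unavailable")
        assert ours.score == int(float(out.stdout.strip()))
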