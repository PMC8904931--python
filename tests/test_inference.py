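"""Protein grouping and top-3 quantification: partitions, thresholds, scaling."""

import random

import pytest

from gonadpipe import (PeptideObservation, assign_peptides, build_groups,
                       enumerate_ions, normalize_and_rank, quantify_top3)
from gonadpipe.inference import (ProteinGroup, aggregate_intensities,
                                 groups_to_frame)

PEP_A = "DDDDDDDDDK"      # +2 in window
PEP_B = "EEEEEEEEEK"
PEP_C = "NNNNNNNNNK"
PEP_D = "QQQQQQQQQK"


def _group(peptides, clusters=("cl1",), gid="grp_cl1"):
    return ProteinGroup(group_id=gid, member_cluster_ids=frozenset(clusters),
                        member_entry_ids=frozenset(), peptide_set=frozenset(peptides))


class TestAssignPeptides:
    def setup_method(self):
        self.index = enumerate_ions({
            "e1": PEP_A + "K" + PEP_B,  # unique A; shared B
            "e2": "MK" + PEP_B,
        })

    def test_unique_shared_and_unassigned(self):
        obs = [PeptideObservation(PEP_A, 10.0),
               PeptideObservation(PEP_B, 5.0),
               PeptideObservation("ZZZZZZZZ", 1.0)]
        assignment, unassigned = assign_peptides(obs, self.index)
        assert assignment[PEP_A] == frozenset({"e1"})
        assert assignment[PEP_B] == frozenset({"e1", "e2"})
        assert unassigned == ["ZZZZZZZZ"]
        assert "ZZZZZZZZ" not in assignment


class TestBuildGroups:
    def test_one_shared_peptide_keeps_clusters_apart(self):
        assignment = {PEP_A: frozenset({"eA"}), PEP_B: frozenset({"eB"}),
                      PEP_C: frozenset({"eA", "eB"})}
        groups = build_groups(assignment, {"eA": "clA", "eB": "clB"})
        assert {g.member_cluster_ids for g in groups} == {
            frozenset({"clA"}), frozenset({"clB"})}

    def test_two_shared_peptides_merge(self):
        assignment = {PEP_A: frozenset({"eA", "eB"}),
                      PEP_B: frozenset({"eA", "eB"})}
        (group,) = build_groups(assignment, {"eA": "clA", "eB": "clB"})
        assert group.member_cluster_ids == frozenset({"clA", "clB"})
        assert group.peptide_set == frozenset({PEP_A, PEP_B})

    def test_transitive_consolidation(self):
        assignment = {
            PEP_A: frozenset({"eA", "eB"}), PEP_B: frozenset({"eA", "eB"}),
            PEP_C: frozenset({"eB", "eC"}), PEP_D: frozenset({"eB", "eC"}),
        }
        clusters = {"eA": "clA", "eB": "clB", "eC": "clC"}
        (group,) = build_groups(assignment, clusters)
        assert group.member_cluster_ids == frozenset({"clA", "clB", "clC"})

    def test_missing_cluster_mapping_rejected(self):
        with pytest.raises(ValueError, match="eA"):
            build_groups({PEP_A: frozenset({"eA"})}, {})

    @staticmethod
    def _random_scenario(rng):
        n_clusters = rng.randint(2, 8)
        entry_to_cluster = {f"e{i}": f"cl{i % n_clusters}" for i in range(12)}
        peptides = [f"{'ACDEFGHIKLMNPQRSTVWY'[i]}" * 8 for i in range(16)]
        assignment = {}
        for pep in peptides:
            if rng.random() < 0.8:
                k = rng.randint(1, 4)
                assignment[pep] = frozenset(rng.sample(sorted(entry_to_cluster), k))
        return assignment, entry_to_cluster

    def test_partition_order_invariance_and_monotonicity(self):
        rng = random.Random(99)
        for _ in range(100):
            assignment, entry_to_cluster = self._random_scenario(rng)
            groups = build_groups(assignment, entry_to_cluster)
            # partition over clusters with >= 1 assigned peptide
            covered = [c for g in groups for c in g.member_cluster_ids]
            assert len(covered) == len(set(covered))
            active = {entry_to_cluster[e] for entries in assignment.values()
                      for e in entries}
            assert set(covered) == active
            # order invariance
            shuffled_items = list(assignment.items())
            rng.shuffle(shuffled_items)
            again = build_groups(dict(shuffled_items), entry_to_cluster)
            assert {g.member_cluster_ids for g in again} == \
                   {g.member_cluster_ids for g in groups}
            # raising min_shared only refines the grouping
            finer = build_groups(assignment, entry_to_cluster, min_shared=3)
            for fine in finer:
                assert any(fine.member_cluster_ids <= g.member_cluster_ids
                           for g in groups)


class TestQuantifyTop3:
    def test_exactly_three(self):
        group = _group([PEP_A, PEP_B, PEP_C])
        got = quantify_top3(group, {PEP_A: 10, PEP_B: 20, PEP_C: 30})
        assert got == 20

    def test_top_three_of_five(self):
        peps = [PEP_A, PEP_B, PEP_C, PEP_D, "SSSSSSSSK"]
        group = _group(peps)
        intensities = dict(zip(peps, [1, 5, 9, 7, 3]))
        assert quantify_top3(group, intensities) == pytest.approx(7.0)

    def test_two_peptides_undefined_but_group_reported(self):
        group = _group([PEP_A, PEP_B])
        assert quantify_top3(group, {PEP_A: 10, PEP_B: 20}) is None
        frame = groups_to_frame([group])
        assert len(frame) == 1 and frame.loc[0, "n_peptides"] == 2

    def test_negative_intensity_rejected(self):
        group = _group([PEP_A, PEP_B, PEP_C])
        with pytest.raises(ValueError, match="negative"):
            quantify_top3(group, {PEP_A: -1, PEP_B: 2, PEP_C: 3})

    def test_duplicate_observations_summed_before_top3(self):
        obs = [PeptideObservation(PEP_A, 5.0), PeptideObservation(PEP_A, 7.0),
               PeptideObservation(PEP_B, 6.0), PeptideObservation(PEP_C, 1.0)]
        intensities = aggregate_intensities(obs)
        assert intensities[PEP_A] == 12.0
        group = _group([PEP_A, PEP_B, PEP_C])
        assert quantify_top3(group, intensities) == pytest.approx((12 + 6 + 1) / 3)


class TestNormalizeAndRank:
    def _three_groups(self):
        groups = [
            _group([PEP_A, PEP_B, PEP_C], clusters=("cl1",), gid="grp_cl1"),
            _group([PEP_A, PEP_B, PEP_D], clusters=("cl2",), gid="grp_cl2"),
            _group([PEP_B, PEP_C, PEP_D], clusters=("cl3",), gid="grp_cl3"),
        ]
        intensities = {PEP_A: 250, PEP_B: 25, PEP_C: 25, PEP_D: 25}
        # abundances: grp1 = grp2 = 100, grp3 = 25
        return groups, intensities

    def test_single_group_normalizes_to_one(self):
        group = _group([PEP_A, PEP_B, PEP_C])
        (ranked,) = normalize_and_rank([group], {PEP_A: 9, PEP_B: 6, PEP_C: 3})
        assert ranked.normalized_abundance == 1.0 and ranked.rank == 1

    def test_descending_ranks_and_tie_by_group_id(self):
        groups, intensities = self._three_groups()
        ranked = {g.group_id: g for g in normalize_and_rank(groups, intensities)}
        assert ranked["grp_cl1"].rank == 1  # tie with cl2, id order wins
        assert ranked["grp_cl2"].rank == 2
        assert ranked["grp_cl3"].rank == 3
        assert ranked["grp_cl3"].normalized_abundance == pytest.approx(0.25)

    def test_scale_invariance(self):
        groups, intensities = self._three_groups()
        base = normalize_and_rank(groups, intensities)
        scaled = normalize_and_rank(groups,
                                    {p: v * 10 for p, v in intensities.items()})
        for g_base, g_scaled in zip(base, scaled):
            assert g_scaled.abundance == pytest.approx(10 * g_base.abundance)
            assert g_scaled.normalized_abundance == pytest.approx(
                g_base.normalized_abundance)
            assert g_scaled.rank == g_base.rank

    def test_no_quantifiable_group_rejected(self):
        group = _group([PEP_A, PEP_B])
        with pytest.raises(ValueError):
            normalize_and_rank([group], {PEP_A: 1, PEP_B: 2})
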