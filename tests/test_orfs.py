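"""ORF calling: Met-to-stop enumeration, greedy selection, database rules."""

import random

import pytest

from gonadpipe import (OrfCall, build_protein_db, find_orfs, import_clusters,
                       select_nonoverlapping, simulate_transcriptome)
from gonadpipe.orfs import read_protein_fasta, write_protein_fasta
import pandas as pd


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestFindOrfs:
    def test_no_atg_no_calls(self):
        assert find_orfs("CCCCCCCCC") == []

    def test_minimal_30aa_orf(self):
        calls = find_orfs("ATG" + "GCT" * 29 + "TAA")
        assert len(calls) == 1
        call = calls[0]
        assert (call.frame, call.nt_start, call.nt_end) == (0, 0, 93)
        assert call.protein == "M" + "A" * 29

    def test_29aa_orf_below_threshold(self):
        assert find_orfs("ATG" + "GCT" * 28 + "TAA") == []

    def test_orf_without_stop_not_reported(self):
        assert find_orfs("ATG" + "GCT" * 40) == []

    def test_n_codons_translate_to_x_and_count(self):
        seq = "ATG" + "GCT" * 14 + "GCN" + "GCT" * 14 + "TAA"
        calls = find_orfs(seq)
        assert len(calls) == 1
        assert calls[0].protein == "M" + "A" * 14 + "X" + "A" * 14

    def test_ambiguous_stop_is_not_a_stop(self):
        # TAN could resolve to TAA/TAG but must be read as X, not stop.
        seq = "ATG" + "GCT" * 14 + "TAN" + "GCT" * 14 + "TGA"
        calls = find_orfs(seq)
        assert len(calls) == 1
        assert calls[0].protein[15] == "X"
        assert len(calls[0].protein) == 30

    def test_invalid_character_named_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_orfs("ACGZACGT")

    def test_all_frames_scanned(self):
        core = "ATG" + "GCT" * 29 + "TAA"
        for pad in ("", "C", "CC"):
            calls = find_orfs(pad + core)
            assert len(calls) == 1
            assert calls[0].frame == len(pad)

    def test_strandedness_forward_only(self, small_config):
        """The reverse complement of a transcript must not reproduce the
        forward ORFs (reads are stranded; only forward frames scanned)."""
        _, truth = simulate_transcriptome(small_config)
        for gene in truth.genes.index:
            transcript = truth.genes.loc[gene, "transcript"]
            forward = {c.protein for c in find_orfs(transcript)}
            reverse = {c.protein for c in find_orfs(revcomp(transcript))}
            assert truth.genes.loc[gene, "protein"] in forward
            assert not (forward & reverse)


def _call(start, end, frame=0, protein_length=None, read="r"):
    n = protein_length if protein_length is not None else (end - start) // 3 - 1
    return OrfCall(read_id=read, frame=frame, nt_start=start, nt_end=end,
                   protein="M" + "A" * (n - 1))


class TestSelectNonoverlapping:
    def test_single_orf_kept(self):
        call = _call(0, 123)
        assert select_nonoverlapping([call]) == [call]

    def test_longer_of_two_overlapping_kept(self):
        a = _call(0, 123, protein_length=40)
        b = _call(60, 168, protein_length=35)
        assert select_nonoverlapping([a, b]) == [a]

    def test_tie_broken_by_start_then_rejections_cascade(self):
        a = _call(0, 123, protein_length=40)
        b = _call(60, 213, protein_length=50)
        c = _call(150, 303, protein_length=50)
        assert select_nonoverlapping([a, b, c]) == [b]

    def test_mixed_reads_rejected(self):
        with pytest.raises(ValueError, match="single read"):
            select_nonoverlapping([_call(0, 123, read="r1"),
                                   _call(200, 323, read="r2")])

    def test_greedy_result_is_maximal_on_random_reads(self):
        rng = random.Random(20240901)
        for _ in range(60):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(200, 700)))
            candidates = find_orfs(seq, min_protein_length=10)
            kept = select_nonoverlapping(candidates)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert a.nt_end <= b.nt_start or b.nt_end <= a.nt_start
            for cand in candidates:
                if cand in kept:
                    continue
                overlaps = any(not (cand.nt_end <= k.nt_start
                                    or k.nt_end <= cand.nt_start)
                               for k in kept)
                assert overlaps, "rejected ORF could have been added"

    def test_synthetic_reads_yield_exactly_the_embedded_orf(self, small_config):
        reads, truth = simulate_transcriptome(small_config)
        for pool in reads.values():
            for read_id, seq in pool.items():
                selected = select_nonoverlapping(find_orfs(seq, read_id=read_id))
                assert [c.protein for c in selected] == [
                    truth.genes.loc[truth.read_origin[read_id], "protein"]]


class TestBuildProteinDb:
    @staticmethod
    def _assignment(reads):
        return import_clusters(pd.DataFrame(
            {"read_id": list(reads), "cluster_id": [c for _, c in reads.items()]}))

    def test_support_threshold_and_aggregation(self):
        reads = {"r1": "cA", "r2": "cA", "r3": "cB", "r4": "cC"}
        assignment = self._assignment(reads)
        shared = "M" + "K" * 39
        lone = "M" + "L" * 39
        calls = [
            OrfCall("r1", 0, 0, 123, shared),
            OrfCall("r2", 0, 0, 123, shared),
            OrfCall("r3", 1, 1, 124, shared),
            OrfCall("r4", 0, 0, 123, lone),
        ]
        entries = build_protein_db(calls, assignment)
        assert len(entries) == 1  # singleton translation excluded
        entry = entries[0]
        assert entry.protein == shared
        assert entry.support == 3
        assert entry.source_cluster_ids == frozenset({"cA", "cB"})

    def test_two_reads_suffice(self):
        assignment = self._assignment({"r1": "c", "r2": "c"})
        protein = "M" + "W" * 39
        calls = [OrfCall("r1", 0, 0, 123, protein),
                 OrfCall("r2", 0, 0, 123, protein)]
        (entry,) = build_protein_db(calls, assignment)
        assert entry.support == 2

    def test_unknown_read_rejected(self):
        assignment = self._assignment({"r1": "c"})
        with pytest.raises(ValueError, match="ghost"):
            build_protein_db([OrfCall("ghost", 0, 0, 123, "M" + "A" * 39)],
                             assignment)

    def test_db_size_monotone_in_min_support(self, small_config):
        from gonadpipe import call_reads, greedy_cluster
        from gonadpipe.pipeline import merge_pools
        reads, _ = simulate_transcriptome(small_config)
        merged = merge_pools(reads)
        assignment = greedy_cluster(merged)
        calls = call_reads(merged)
        sizes = [len(build_protein_db(calls, assignment, min_support=m))
                 for m in (1, 2, 5, 10**6)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0

    def test_fasta_roundtrip(self, tmp_path, small_config):
        from gonadpipe import call_reads, greedy_cluster
        from gonadpipe.pipeline import merge_pools
        reads, _ = simulate_transcriptome(small_config)
        merged = merge_pools(reads)
        entries = build_protein_db(call_reads(merged), greedy_cluster(merged))
        assert entries
        path = tmp_path / "db.fasta"
        write_protein_fasta(entries, path)
        assert read_protein_fasta(path) == entries
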