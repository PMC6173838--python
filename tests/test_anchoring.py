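"""Majority-vote anchoring: classification rule, summaries, oracle recounts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntenic import SimConfig, simulate
from syntenic.anchoring import (
    CONSERVED,
    REARRANGED,
    UNPLACED,
    AnchorCall,
    anchor_scaffolds,
    summarize,
)
from syntenic.io_formats import GeneRecord, ValidationError
from syntenic.orthologs import OrthologAssignment, best_hits

MB = 1_000_000


def _genes(scaffold, n):
    return [GeneRecord(f"{scaffold}_g{i}", scaffold, i * 1000, i * 1000 + 500)
            for i in range(n)]


def _assign(gene_ids, chroms):
    return {
        g.gene_id: OrthologAssignment(g.gene_id, c, 1000, 500.0)
        for g, c in zip(gene_ids, chroms)
    }


class TestClassificationRule:
    def test_six_of_ten_votes_is_conserved(self):
        genes = _genes("sc1", 10)
        a = _assign(genes, ["chr5"] * 6 + ["chr2"] * 4)
        (call,) = anchor_scaffolds(a, genes, {"sc1": 2 * MB}).calls
        assert call.assigned_chrom == "chr5"
        assert call.top_fraction == pytest.approx(0.6)
        assert call.klass == CONSERVED and not call.ambiguous

    def test_exactly_half_is_rearranged_and_tie_is_flagged(self):
        genes = _genes("sc1", 10)
        a = _assign(genes, ["chr1"] * 5 + ["chr2"] * 5)
        (call,) = anchor_scaffolds(a, genes, {"sc1": 2 * MB}).calls
        # 50% is not "better than 50%": rearranged, tie broken lexicographically.
        assert call.klass == REARRANGED
        assert call.assigned_chrom == "chr1" and call.ambiguous
        assert call.top_fraction == pytest.approx(0.5)

    def test_no_assignments_means_unplaced(self):
        genes = _genes("sc1", 4)
        (call,) = anchor_scaffolds({}, genes, {"sc1": 2 * MB}).calls
        assert call.klass == UNPLACED and call.assigned_chrom is None
        assert call.n_hit_genes == 0

    def test_all_genes_denominator_can_demote_to_rearranged(self):
        genes = _genes("sc1", 10)
        a = _assign(genes[:4], ["chr1"] * 4)  # 4 of 4 hits, but 4 of 10 genes
        call_hit = anchor_scaffolds(a, genes, {"sc1": 2 * MB}).calls[0]
        call_all = anchor_scaffolds(a, genes, {"sc1": 2 * MB},
                                    denominator="all_genes").calls[0]
        assert call_hit.klass == CONSERVED
        assert call_all.klass == REARRANGED

    def test_short_scaffolds_skipped_not_called(self):
        genes = _genes("sc1", 3) + _genes("sc2", 3)
        a = _assign(genes, ["chr1"] * 6)
        result = anchor_scaffolds(a, genes, {"sc1": 2 * MB, "sc2": 500_000})
        assert [c.scaffold_id for c in result.calls] == ["sc1"]
        assert result.skipped == ("sc2",)

    def test_missing_length_is_an_error(self):
        genes = _genes("sc1", 2)
        with pytest.raises(ValidationError, match="sc1"):
            anchor_scaffolds({}, genes, {})


class TestOracleRecount:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_brute_force_recount_on_simulated_data(self, seed):
        """Every call equals an independent recount straight from the hit table."""
        d = simulate(SimConfig(seed=seed, n_chrom_ref=6, genes_per_chrom=40,
                               n_translocations=3, scaffold_mean_genes=6,
                               hit_miss_rate=0.15, spurious_hit_rate=0.25,
                               paralog_tie_rate=0.1))
        assignments = best_hits(d.hit_table)
        calls = anchor_scaffolds(assignments, d.derived_annotation,
                                 d.derived_lengths, min_len_bp=0).calls
        # Oracle: per gene, max-bitscore subject (ties: aln_len, then name);
        # per scaffold, top chromosome and the strict >1/2 rule.
        per_query = {}
        for h in d.hit_table:
            per_query.setdefault(h.query_id, []).append(h)
        gene_chrom = {}
        for q, hs in per_query.items():
            top = sorted(hs, key=lambda h: (-h.bitscore, -h.aln_len, h.subject_id))[0]
            gene_chrom[q] = top.subject_id
        scaffold_of = {g.gene_id: g.seq_id for g in d.derived_annotation}
        votes = {}
        for q, c in gene_chrom.items():
            votes.setdefault(scaffold_of[q], {}).setdefault(c, 0)
            votes[scaffold_of[q]][c] += 1
        for call in calls:
            v = votes.get(call.scaffold_id, {})
            if not v:
                assert call.klass == UNPLACED
                continue
            top = max(v.values())
            assert call.assigned_chrom == min(c for c, n in v.items() if n == top)
            assert call.klass == (CONSERVED if top / sum(v.values()) > 0.5 else REARRANGED)
            assert call.n_hit_genes == sum(v.values())

    def test_hit_row_order_invariance(self):
        d = simulate(SimConfig(seed=4, n_chrom_ref=4, genes_per_chrom=20,
                               spurious_hit_rate=0.3, paralog_tie_rate=0.2))
        rng = np.random.default_rng(0)
        shuffled = [d.hit_table[int(i)] for i in rng.permutation(len(d.hit_table))]
        base = anchor_scaffolds(best_hits(d.hit_table), d.derived_annotation,
                                d.derived_lengths, min_len_bp=0)
        assert anchor_scaffolds(best_hits(shuffled), d.derived_annotation,
                                d.derived_lengths, min_len_bp=0) == base

    def test_classes_partition_all_scaffolds_above_cutoff(self, noisy_dataset):
        d = noisy_dataset
        result = anchor_scaffolds(best_hits(d.hit_table), d.derived_annotation,
                                  d.derived_lengths, min_len_bp=0)
        assert {c.scaffold_id for c in result.calls} == set(d.derived_lengths)
        assert all(c.klass in (CONSERVED, REARRANGED, UNPLACED) for c in result.calls)


def _call(klass, bp, scaffold="sc1", chrom="chr1"):
    return AnchorCall(scaffold, bp, 10, 10 if klass != UNPLACED else 0,
                      {chrom: 10} if klass != UNPLACED else {},
                      chrom if klass != UNPLACED else None,
                      1.0 if klass != UNPLACED else 0.0, klass, False)


class TestSummarize:
    def test_shares_of_417_and_298_mb(self):
        s = summarize([_call(CONSERVED, 417 * MB), _call(REARRANGED, 298 * MB, "sc2")])
        assert s.shares_pct == {CONSERVED: 58, REARRANGED: 42}
        assert s.total_bp == 715 * MB

    def test_single_class_is_100_percent(self):
        s = summarize([_call(CONSERVED, 5 * MB)])
        assert s.shares_pct[CONSERVED] == 100

    def test_unplaced_bp_counted_in_total_but_not_shares(self):
        s = summarize([_call(CONSERVED, 3 * MB), _call(REARRANGED, MB, "sc2"),
                       _call(UNPLACED, 10 * MB, "sc3")])
        assert s.total_bp == 14 * MB
        assert sum(s.shares_pct.values()) == 100

    def test_empty_calls_rejected(self):
        with pytest.raises(ValidationError, match="nothing to summarize"):
            summarize([])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.integers(1, 10**9), st.integers(1, 10**9))
    def test_shares_always_sum_to_exactly_100(self, conserved_bp, rearranged_bp):
        s = summarize([_call(CONSERVED, conserved_bp),
                       _call(REARRANGED, rearranged_bp, "sc2")])
        assert sum(s.shares_pct.values()) == 100
        exact = 100 * conserved_bp / (conserved_bp + rearranged_bp)
        assert abs(s.shares_pct[CONSERVED] - exact) < 1
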