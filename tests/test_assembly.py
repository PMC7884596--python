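"""Iterative mapper: acceptance rule, seeding, paralog-separated recovery."""

import copy
import math

import edlib
import numpy as np
import pytest

import hemasm as hm
from hemasm._seq import revcomp
from hemasm.assembly import MappingParams, accept_hit, assign_paralog, seed_map


def brute_force_hits(read: str, contig: str, params: MappingParams):
    """Independent all-offsets ungapped oracle for the acceptance rule."""
    accepted = {}
    for offset in range(-len(read) + 1, len(contig)):
        lo, hi = max(0, offset), min(len(contig), offset + len(read))
        overlap = hi - lo
        if overlap < params.min_overlap_nt:
            continue
        mismatches = sum(
            1 for i in range(lo, hi) if read[i - offset] != contig[i]
        )
        budget = min(
            math.floor(params.max_mismatch_fraction * overlap),
            math.floor((1 - params.min_overlap_identity) * overlap),
        )
        if mismatches <= budget:
            accepted[offset] = mismatches
    return accepted


class TestAcceptHit:
    params = MappingParams()

    def test_identical_overlap_accepted_with_zero_mismatches(self):
        contig = "ACGT" * 50
        hit = accept_hit(contig[:150], contig, 0, self.params)
        assert hit is not None
        assert hit.mismatches == 0
        assert hit.overlap_length == 150

    def test_overlap_below_minimum_rejected(self):
        contig = "ACGT" * 50
        # 59-nt overlap hanging off the left end, perfect identity
        read = contig[:59]
        assert accept_hit("T" * 41 + read, contig, -41, self.params) is None
        assert accept_hit("T" * 40 + contig[:60], contig, -40, self.params) is not None

    def test_two_mismatches_in_100_rejected(self):
        rng = np.random.default_rng(0)
        contig = "".join("ACGT"[i] for i in rng.integers(4, size=100))
        read = list(contig)
        read[10] = {"A": "C"}.get(read[10], "A")
        read[50] = {"A": "C"}.get(read[50], "A")
        assert accept_hit("".join(read), contig, 0, self.params) is None
        read[50] = contig[50]  # back to a single mismatch: within 1% of 100
        assert accept_hit("".join(read), contig, 0, self.params) is not None

    def test_matches_brute_force_on_random_read_set(self):
        rng = np.random.default_rng(42)
        contig = "".join("ACGT"[i] for i in rng.integers(4, size=300))
        params = MappingParams()
        for _ in range(60):
            start = int(rng.integers(0, 300 - 80))
            read = list(contig[start : start + 80])
            for _k in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(len(read)))
                read[pos] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            oracle = brute_force_hits(read, contig, params)
            for offset in range(-len(read) + 1, len(contig)):
                hit = accept_hit(read, contig, offset, params)
                if offset in oracle:
                    assert hit is not None and hit.mismatches == oracle[offset]
                else:
                    assert hit is None


class TestSeedMap:
    def test_self_reads_all_recruited_and_assemble_to_one_contig(self):
        rng = np.random.default_rng(1)
        gene = "".join("ACGT"[i] for i in rng.integers(4, size=1500))
        sim = hm.simulate_reads({"g": gene}, hm.ReadSimSpec(seed=2, coverage=60, error_rate=0.0))
        state = seed_map(sim, gene)
        assert state.recruited == {rid for rid, _s in sim.reads}
        final = hm.extend_iterate(state, sim)
        assert final.converged
        assert len(final.contigs) == 1
        # consensus is an error-free substring spanning almost all of the gene
        d = edlib.align(final.contigs[0].seq, gene, task="distance", mode="HW")
        assert d["editDistance"] == 0
        assert len(final.contigs[0].seq) >= len(gene) - 25

    def test_half_divergent_gene_recruits_nothing(self, truth_one_species):
        reference = hm.heterologous_reference(truth_one_species, 0.5, seed=3)
        sim = hm.simulate_reads(
            {"H1": truth_one_species.transcripts["H1_sp1"]},
            hm.ReadSimSpec(seed=4, coverage=10, error_rate=0.0),
        )
        state = seed_map(sim, reference)
        assert len(state.recruited) == 0

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            seed_map([], "ACGT" * 100)


class TestExtendIterate:
    def test_recovers_both_paralog_cds_error_free(self):
        truth = hm.generate_paralog_pair(hm.scaled_down_spec(seed=21, species_divergence=0.0))
        sim = hm.simulate_reads(truth, hm.ReadSimSpec(seed=22, coverage=50, error_rate=0.0))
        reference = hm.heterologous_reference(truth, 0.125, seed=23)
        state = hm.assemble(sim, reference)
        assert state.converged
        consensi = list(state.consensus().values())
        for label in ("H1_sp1", "H2_sp1"):
            cds = truth.genes[label]
            assert any(cds in c or revcomp(cds) in c for c in consensi), label

    def test_single_gene_reads_give_single_contig(self, truth_one_species):
        sim = hm.simulate_reads(
            {"H1": truth_one_species.transcripts["H1_sp1"]},
            hm.ReadSimSpec(seed=24, coverage=50, error_rate=0.0),
        )
        reference = hm.heterologous_reference(truth_one_species, 0.125, seed=25)
        state = hm.assemble(sim, reference)
        assert len(state.contigs) == 1
        assert truth_one_species.genes["H1_sp1"] in state.contigs[0].seq

    def test_monotone_growth_and_recruitment(self, reads_err, seed_reference):
        state = seed_map(reads_err, seed_reference)
        lengths = {c.id: len(c.seq) for c in state.contigs}
        recruited = set(state.recruited)
        for _ in range(4):
            state.converged = False
            state = hm.extend_iterate(state, reads_err, max_iter=1)
            for contig in state.contigs:
                if contig.id in lengths:
                    assert len(contig.seq) >= lengths[contig.id]
            assert recruited <= state.recruited
            lengths = {c.id: len(c.seq) for c in state.contigs}
            recruited = set(state.recruited)

    def test_deterministic_final_consensus(self, truth_one_species):
        sim = hm.simulate_reads(
            truth_one_species, hm.ReadSimSpec(seed=26, coverage=40, error_rate=0.01)
        )
        reference = hm.heterologous_reference(truth_one_species, 0.125, seed=27)
        a = hm.assemble(sim, reference)
        b = hm.assemble(sim, reference)
        assert a.consensus() == b.consensus()


class TestAssignParalog:
    def _contigs(self):
        rng = np.random.default_rng(5)
        a = "".join("ACGT"[i] for i in rng.integers(4, size=400))
        b = list(a)
        for pos in rng.choice(400, size=120, replace=False):
            b[pos] = "ACGT"[(("ACGT".index(b[pos])) + 1 + int(rng.integers(3))) % 4]
        contigs = [
            hm.Contig(id="A", seq=a, coverage=np.ones(400, dtype=int)),
            hm.Contig(id="B", seq="".join(b), coverage=np.ones(400, dtype=int)),
        ]
        return a, "".join(b), contigs

    def test_strictly_better_contig_wins(self):
        a, _b, contigs = self._contigs()
        hits = assign_paralog(a[100:250], contigs, MappingParams())
        assert [h.contig_id for h in hits] == ["A"]
        assert not hits[0].ambiguous

    def test_equidistant_read_flagged_ambiguous_on_both(self):
        a, _b, _ = self._contigs()
        contigs = [
            hm.Contig(id="A", seq=a, coverage=np.ones(400, dtype=int)),
            hm.Contig(id="B", seq=a, coverage=np.ones(400, dtype=int)),
        ]
        hits = assign_paralog(a[100:250], contigs, MappingParams())
        assert sorted(h.contig_id for h in hits) == ["A", "B"]
        assert all(h.ambiguous for h in hits)

    def test_ambiguity_increases_as_paralogs_converge(self):
        rates = []
        for divergence in (0.30, 0.02, 0.005):
            truth = hm.generate_paralog_pair(
                hm.scaled_down_spec(seed=31, paralog_divergence=divergence, species_divergence=0.0)
            )
            sim = hm.simulate_reads(truth, hm.ReadSimSpec(seed=32, coverage=10, error_rate=0.0))
            contigs = [
                hm.Contig(id=label, seq=seq, coverage=np.ones(len(seq), dtype=int))
                for label, seq in sorted(truth.transcripts.items())
            ]
            n_amb = n = 0
            for _rid, seq in sim.reads[::5]:
                hits = assign_paralog(seq, contigs, MappingParams())
                if hits:
                    n += 1
                    n_amb += hits[0].ambiguous
            rates.append(n_amb / n)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > max(0.2, rates[0])
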