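
import numpy as np
import pytest

from spaceracq import (
    Read,
    ReadSet,
    SimulationConfig,
    analyze_escapers,
    call_deletions,
    dereplicate,
    deletion_spectrum,
    filter_primer_anchored,
    merge_pairs,
    revcomp,
    simulate_escaper_reads,
)
from spaceracq.escapers import EscaperVariant, InsertionAnomalyError, left_normalize
from spaceracq.simulate import escaper_amplicon


def toy_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMergePairs:
    def _pair(self, amplicon, rlen=60, q1=None, q2=None):
        r1 = amplicon[:rlen]
        r2 = revcomp(amplicon[-rlen:])
        return ReadSet(
            [Read("p/1", r1, q1 or "I" * rlen), Read("p/2", r2, q2 or "I" * rlen)],
            pairing="paired",
        )

    def test_perfect_overlap_reconstructs_amplicon(self):
        amp = toy_seq(100)
        merged, dropped = merge_pairs(self._pair(amp, 60))
        assert dropped == 0
        assert merged.reads[0].sequence == amp

    def test_insufficient_overlap_dropped(self):
        amp = toy_seq(200)
        merged, dropped = merge_pairs(self._pair(amp, 60), min_overlap=20)
        assert dropped == 1 and len(merged) == 0

    def test_conflict_resolved_by_quality(self):
        amp = toy_seq(100)
        rlen = 60
        r1 = amp[:rlen]
        conflict_pos = 50  # inside the 20 bp overlap
        r1 = r1[:conflict_pos] + ("A" if r1[conflict_pos] != "A" else "C") + r1[conflict_pos + 1 :]
        q1 = "I" * rlen
        q2 = "#" * rlen  # much lower quality
        rs = ReadSet(
            [Read("p/1", r1, q1), Read("p/2", revcomp(amp[-rlen:]), q2)],
            pairing="paired",
        )
        merged, _ = merge_pairs(rs)
        assert merged.reads[0].sequence[conflict_pos] == r1[conflict_pos]


class TestPrimerFilter:
    fwd, rev = "ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG"

    def _amplicon(self):
        return self.fwd + toy_seq(100, 3) + revcomp(self.rev)

    def test_both_primers_kept(self):
        rs = ReadSet([Read("a", self._amplicon())])
        kept, removed = filter_primer_anchored(rs, self.fwd, self.rev)
        assert len(kept) == 1 and removed == 0

    def test_missing_three_prime_primer_removed(self):
        rs = ReadSet([Read("a", self.fwd + toy_seq(100, 3))])
        kept, removed = filter_primer_anchored(rs, self.fwd, self.rev)
        assert len(kept) == 0 and removed == 1

    def test_reverse_complemented_read_canonicalized(self):
        rs = ReadSet([Read("a", revcomp(self._amplicon()))])
        kept, removed = filter_primer_anchored(rs, self.fwd, self.rev)
        assert removed == 0
        assert kept.reads[0].sequence == self._amplicon()


class TestDereplicate:
    def test_counts_and_order(self):
        reads = [Read(f"r{i}", "AAAA") for i in range(3)] + [Read("r9", "CCCC")]
        variants = dereplicate(ReadSet(reads))
        assert [(v.sequence, v.count) for v in variants] == [("AAAA", 3), ("CCCC", 1)]

    def test_empty(self):
        assert dereplicate(ReadSet([])) == []

    def test_order_invariant_under_permutation(self):
        seqs = ["AA", "CC", "AA", "GG", "CC", "AA"]
        a = dereplicate(ReadSet([Read(f"r{i}", s) for i, s in enumerate(seqs)]))
        b = dereplicate(ReadSet([Read(f"r{i}", s) for i, s in enumerate(reversed(seqs))]))
        assert [(v.sequence, v.count) for v in a] == [(v.sequence, v.count) for v in b]


def exhaustive_single_deletion_placements(variant, reference):
    """Oracle: every single-block placement reproducing the variant, by
    brute-force enumeration of all (start, length) excisions."""
    d = len(reference) - len(variant)
    return {
        s for s in range(len(reference) - d + 1)
        if reference[:s] + reference[s + d :] == variant
    }


def apply_deletions(reference, deletions):
    """Excise (start, length) blocks given in reference coordinates."""
    out = reference
    for s, l in sorted(deletions, reverse=True):
        out = out[:s] + out[s + l :]
    return out


class TestCallDeletions:
    def test_identity(self):
        ref = toy_seq(80, 1)
        assert call_deletions(ref, ref) == ([], 0)

    def test_single_excision_leftmost(self):
        ref = toy_seq(300, 2)
        var = ref[:120] + ref[123:]
        dels, mm = call_deletions(var, ref)
        assert mm == 0
        assert dels == [left_normalize((120, 3), ref)]

    def test_homopolymer_leftmost_placement(self):
        ref = "ACGT" + "A" * 10 + "CGTACGTACGTACGTACGTACGT"
        var = ref[:8] + ref[11:]  # delete 3 of the A run, ambiguous placement
        dels, _ = call_deletions(var, ref)
        assert dels == [(4, 3)]  # shifted to the start of the run

    @pytest.mark.parametrize("dlen", [3, 99, 270])
    def test_implanted_deletion_exact_length(self, dlen, phage):
        cfg = SimulationConfig(seed=8)
        amp, ps, _, _ = escaper_amplicon(phage, "early_03", cfg)
        start = ps[0] - dlen // 3
        var = amp[:start] + amp[start + dlen :]
        dels, mm = call_deletions(var, amp)
        assert mm == 0
        assert len(dels) == 1 and dels[0][1] == dlen

    def test_agrees_with_exhaustive_oracle_on_toys(self):
        """On short references with one or two implanted deletions, calls
        reconstruct the variant exactly; single-deletion placements match
        the leftmost brute-force enumeration."""
        rng = np.random.default_rng(5)
        for trial in range(40):
            ref = toy_seq(int(rng.integers(40, 61)), seed=100 + trial)
            n_del = 1 if rng.random() < 0.7 else 2
            var = ref
            for _ in range(n_del):
                if len(var) < 15:
                    break
                dlen = int(rng.integers(1, 7))
                s = int(rng.integers(0, len(var) - dlen))
                var = var[:s] + var[s + dlen :]
            dels, mm = call_deletions(var, ref)
            assert mm == 0
            assert sum(l for _, l in dels) == len(ref) - len(var)
            assert apply_deletions(ref, dels) == var
            if len(dels) == 1:
                placements = exhaustive_single_deletion_placements(var, ref)
                assert dels[0][0] == min(placements)

    def test_insertion_anomaly_flagged(self):
        ref = toy_seq(50, 9)
        with pytest.raises(InsertionAnomalyError):
            call_deletions(ref + "ACGTA", ref)


class TestSpectrum:
    def _variant(self, dels, count=1):
        total = sum(l for _, l in dels)
        return EscaperVariant(
            sequence="N", count=count, deletions=dels,
            frame_preserving=total % 3 == 0,
        )

    def test_multiples_of_three_frame_preserving(self):
        variants = [self._variant([(10, d)]) for d in (3, 99, 270)]
        s = deletion_spectrum(variants, (0, 38))
        assert s["frame_preserving_fraction_unweighted"] == 1.0

    def test_length_four_frameshift(self):
        s = deletion_spectrum([self._variant([(10, 4)])], (0, 38))
        assert s["frame_preserving_fraction_unweighted"] == 0.0

    def test_weighted_vs_unweighted(self):
        variants = [self._variant([(10, 3)], count=9), self._variant([(10, 4)], count=1)]
        s = deletion_spectrum(variants, (0, 38))
        assert s["frame_preserving_fraction_unweighted"] == 0.5
        assert s["frame_preserving_fraction_weighted"] == 0.9


class TestEndToEnd:
    def test_essential_run_recovers_all_deletions(self, phage):
        cfg = SimulationConfig(seed=31, escaper_n_reads=600, escaper_n_variants=15)
        amp, ps, fwd, rev = escaper_amplicon(phage, "early_01", cfg)
        reads, truth = simulate_escaper_reads(amp, ps, essential=True, config=cfg)
        variants, summary = analyze_escapers(reads, amp, fwd, rev, ps)
        assert summary["frame_preserving_fraction_unweighted"] == 1.0
        assert summary["wildtype_read_fraction"] == pytest.approx(0.5, abs=0.08)
        called = {
            (d[0], d[1]) for v in variants for d in v.deletions
        }
        want = {
            left_normalize((int(r.start), int(r.length)), amp) for r in truth.itertuples()
        }
        assert want <= called | {left_normalize(c, amp) for c in called}
        # every truth deletion recovered with exact length
        called_lengths = sorted(l for _, l in called)
        assert set(truth["length"]) <= set(called_lengths)

    def test_read_count_conservation(self, phage):
        cfg = SimulationConfig(seed=31, escaper_n_reads=300, escaper_n_variants=10)
        amp, ps, fwd, rev = escaper_amplicon(phage, "early_01", cfg)
        reads, _ = simulate_escaper_reads(amp, ps, essential=False, config=cfg)
        variants, summary = analyze_escapers(reads, amp, fwd, rev, ps)
        kept = sum(v.count for v in variants)
        assert kept + summary["reads_primer_removed"] == summary["reads_input"]
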