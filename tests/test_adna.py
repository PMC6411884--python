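"""Read QC, pileup consensus, terminal damage profiles, fragment lengths, SNVs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleovia.adna import (
    AlignedRead,
    build_pileup,
    call_snvs,
    filter_reads,
    fit_damage_model,
    fragment_length_distribution,
    revcomp,
    terminal_damage_profile,
)
from tests.conftest import make_read


class TestFilterReads:
    def test_ambiguous_bases_removed(self):
        reads = [make_read("r1", 0, "NNNNN"), make_read("r2", 0, "ACGTA")]
        kept, counts = filter_reads(reads)
        assert [r.id for r in kept] == ["r2"]
        assert counts["contains_n"] == 1

    def test_duplicates_collapsed(self):
        reads = [make_read("r1", 5, "ACGTA"), make_read("r2", 5, "ACGTA")]
        kept, counts = filter_reads(reads)
        assert len(kept) == 1 and counts["duplicate"] == 1
        # different strand or length is not a duplicate
        reads = [make_read("r1", 5, "ACGTA"), make_read("r2", 5, "ACGTA", strand="-")]
        kept, _ = filter_reads(reads)
        assert len(kept) == 2

    def test_mean_quality_boundary_strict_less(self):
        low = make_read("low", 0, "ACGT")
        low.qualities = np.array([19, 20, 20, 20])  # mean 19.75 < 20 -> removed
        exact = make_read("exact", 1, "ACGT", qual=20)  # mean 20.0 -> retained
        kept, counts = filter_reads([low, exact])
        assert [r.id for r in kept] == ["exact"]
        assert counts["low_quality"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        reads = [
            make_read(f"r{i}", int(rng.integers(0, 50)), "ACGTACGT",
                      qual=int(rng.integers(15, 40)))
            for i in range(40)
        ]
        once, _ = filter_reads(reads)
        twice, counts = filter_reads(once)
        assert [r.id for r in twice] == [r.id for r in once]
        assert counts["low_quality"] == counts["contains_n"] == counts["duplicate"] == 0


class TestPileup:
    def test_all_agree(self):
        ref = "ACGTACGTACGT"
        reads = [make_read(f"r{i}", i, ref[i : i + 5]) for i in range(4)]
        pile = build_pileup(reads, len(ref), reference=ref)
        assert (pile["n_different"] == 0).all()
        assert (pile["n_common"] == pile["depth"]).all()

    def test_plurality_counts(self):
        reads = [make_read(f"a{i}", 0, "A") for i in range(3)] + [
            make_read(f"g{i}", 0, "G") for i in range(2)
        ]
        pile = build_pileup(reads, 1)
        row = pile.iloc[0]
        assert row.consensus == "A" and row.n_common == 3 and row.n_different == 2

    def test_tie_break_to_reference_and_flag(self):
        reads = [make_read(f"a{i}", 0, "A") for i in range(2)] + [
            make_read(f"g{i}", 0, "G") for i in range(2)
        ]
        with_ref = build_pileup(reads, 1, reference="G")
        assert with_ref.iloc[0].consensus == "G" and with_ref.iloc[0].ambiguous
        lexicographic = build_pileup(reads, 1)
        assert lexicographic.iloc[0].consensus == "A" and lexicographic.iloc[0].ambiguous

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_conservation_vs_bruteforce_recount(self, data):
        """n_common + n_different = depth at every site, against a per-site recount."""
        n_reads = data.draw(st.integers(1, 12))
        reads = []
        for i in range(n_reads):
            start = data.draw(st.integers(0, 15))
            seq = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=8))
            reads.append(make_read(f"r{i}", start, seq))
        ref_len = 30
        pile = build_pileup(reads, ref_len)
        assert (pile["n_common"] + pile["n_different"] == pile["depth"]).all()
        for row in pile.itertuples():
            bases = [
                r.sequence[row.site - r.start]
                for r in reads
                if r.start <= row.site < min(r.end, ref_len)
            ]
            assert len(bases) == row.depth
            assert row.n_common == max(bases.count(b) for b in "ACGT")


class TestDamageProfile:
    def test_undamaged_reads_zero_profile(self):
        ref = "ACGT" * 50
        reads = [make_read(f"r{i}", i, ref[i : i + 20]) for i in range(0, 100, 7)]
        prof = terminal_damage_profile(reads, ref, k=10)
        assert np.nansum(prof.ct5_freq) == 0.0
        assert np.nansum(prof.ga3_freq) == 0.0

    def test_reference_without_c_gives_null_5p(self):
        ref = "AGT" * 40  # no C anywhere
        ref = ref.replace("G", "A")  # and no G: both profiles undefined
        reads = [make_read("r0", 0, ref[:20])]
        prof = terminal_damage_profile(reads, ref, k=5)
        assert (prof.ct5_den == 0).all() and np.isnan(prof.ct5_freq).all()

    def test_known_substitution_counted_at_5p(self):
        ref = "CCAACCAACCAA"
        read = make_read("r0", 0, "TCAACCAACCAA")  # C->T at 5' position 0
        prof = terminal_damage_profile([read], ref, k=4)
        assert prof.ct5_num[0] == 1 and prof.ct5_den[0] == 1
        assert prof.ct5_num[1] == 0 and prof.ct5_den[1] == 1

    def test_minus_strand_read_counts_from_its_own_5p(self):
        ref = "AAGGAAAAAA"
        # '-' read covering [0,10): oriented ref = revcomp -> TTTTTTCCTT
        # a G->A on forward position 3 is a C->T at oriented (5') position 6
        seq_fwd = "AAGAAAAAAA"
        read = make_read("r0", 0, seq_fwd, strand="-")
        prof = terminal_damage_profile([read], ref, k=10)
        assert prof.ct5_num[6] == 1
        # the template strand of this molecule has no G, so no 3' G->A events
        assert prof.ga3_num.sum() == 0

    def test_reverse_complement_symmetry(self):
        """Flipping reference, coordinates and strands leaves the profile unchanged."""
        rng = np.random.default_rng(13)
        ref = "".join(rng.choice(list("ACGT"), 300))
        reads = []
        for i in range(60):
            L = int(rng.integers(20, 40))
            start = int(rng.integers(0, 300 - L))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = list(ref[start : start + L])
            if rng.random() < 0.5:  # sprinkle a mutation
                j = int(rng.integers(0, L))
                seq[j] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(make_read(f"r{i}", start, "".join(seq), strand=strand))
        prof = terminal_damage_profile(reads, ref, k=15)
        flipped_ref = revcomp(ref)
        flipped = [
            make_read(
                r.id, len(ref) - r.end, revcomp(r.sequence),
                strand="+" if r.strand == "-" else "-",
            )
            for r in reads
        ]
        prof2 = terminal_damage_profile(flipped, flipped_ref, k=15)
        np.testing.assert_array_equal(prof.ct5_num, prof2.ct5_num)
        np.testing.assert_array_equal(prof.ct5_den, prof2.ct5_den)
        np.testing.assert_array_equal(prof.ga3_num, prof2.ga3_num)
        np.testing.assert_array_equal(prof.ga3_den, prof2.ga3_den)


class TestDamageFit:
    def geometric_profile(self, delta0, decay, k=8, den=1000):
        from paleovia.adna import DamageProfile

        pos = np.arange(k)
        freq = delta0 * decay**pos
        num = np.rint(freq * den).astype(int)
        d = np.full(k, den)
        return DamageProfile(
            positions=pos, ct5_freq=num / d, ct5_num=num, ct5_den=d,
            ga3_freq=num / d, ga3_num=num, ga3_den=d,
        )

    def test_noiseless_inversion(self):
        prof = self.geometric_profile(0.3, 0.5, k=6, den=10**6)
        fit = fit_damage_model(prof)
        assert fit.ok
        assert fit.delta0 == pytest.approx(0.3, abs=5e-4)
        assert fit.decay == pytest.approx(0.5, abs=5e-4)

    def test_flat_zero_profile_flagged(self):
        prof = self.geometric_profile(0.0, 0.5)
        fit = fit_damage_model(prof)
        assert not fit.ok and fit.delta0 == 0.0 and fit.decay is None

    def test_too_few_positions_rejected(self):
        prof = self.geometric_profile(0.3, 0.5, k=2)
        with pytest.raises(ValueError, match="3 positions"):
            fit_damage_model(prof)

    def test_3p_end_fit(self):
        prof = self.geometric_profile(0.2, 0.6, k=6, den=10**6)
        fit = fit_damage_model(prof, end="3p")
        assert fit.delta0 == pytest.approx(0.2, abs=5e-4)
        assert fit.decay == pytest.approx(0.6, abs=5e-4)


class TestFragmentLengths:
    def test_monomodal_nucleosome(self):
        reads = [make_read(f"r{i}", i, "A" * 160) for i in range(30)]
        fld = fragment_length_distribution(reads)
        assert fld.modal_length == pytest.approx(160.0, abs=2.5)
        assert fld.nucleosome_peak

    def test_long_fragments_no_nucleosome_peak(self):
        reads = [make_read(f"r{i}", i, "A" * 600) for i in range(30)]
        fld = fragment_length_distribution(reads)
        assert not fld.nucleosome_peak

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fragment_length_distribution([])


class TestSNVs:
    def pileup_from(self, rows):
        return pd.DataFrame(
            rows,
            columns=["site", "depth", "A", "C", "G", "T", "other", "consensus",
                     "n_common", "n_different", "ambiguous"],
        )

    def test_boundary_inclusive(self):
        ref = "AAAA"
        pile = self.pileup_from([
            (0, 3, 1, 0, 2, 0, 0, "G", 2, 1, False),  # depth 3, alt 2 -> called
            (1, 2, 0, 0, 2, 0, 0, "G", 2, 0, False),  # depth 2 -> not called
            (2, 5, 4, 0, 1, 0, 0, "A", 4, 1, False),  # alt 1 -> not called
        ])
        calls = call_snvs(pile, ref)
        assert calls["site"].tolist() == [0]
        assert calls.iloc[0].alt == "G" and calls.iloc[0].alt_count == 2

    def test_top_alternate_only(self):
        pile = self.pileup_from([(0, 9, 2, 3, 4, 0, 0, "G", 4, 5, False)])
        calls = call_snvs(pile, "T")
        assert len(calls) == 1 and calls.iloc[0].alt == "G"

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_thresholds(self, data):
        """Relaxing either threshold never removes a call."""
        n_sites = data.draw(st.integers(1, 10))
        rows = []
        for s in range(n_sites):
            counts = [data.draw(st.integers(0, 6)) for _ in range(4)]
            depth = sum(counts)
            if depth == 0:
                counts[0] = 1
                depth = 1
            best = max(counts)
            rows.append((s, depth, *counts, 0, "ACGT"[counts.index(best)], best,
                         depth - best, False))
        pile = self.pileup_from(rows)
        ref = "A" * n_sites
        strict = call_snvs(pile, ref, min_depth=4, min_alt=3)
        relaxed_depth = call_snvs(pile, ref, min_depth=3, min_alt=3)
        relaxed_alt = call_snvs(pile, ref, min_depth=4, min_alt=2)
        assert set(strict["site"]) <= set(relaxed_depth["site"])
        assert set(strict["site"]) <= set(relaxed_alt["site"])
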