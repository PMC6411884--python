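"""Ground-truth generators: determinism, trivial cases, closed-form expectations."""

import numpy as np
import pandas as pd
import pytest

from paleovia import adna, imaging, simulate
from paleovia.simulate import (
    CohortSpec,
    DamageSimParams,
    ImageSimParams,
    NucleusSpec,
    gen_ancient_reads,
    gen_ddi_cohort,
    gen_nucleus_stack,
    gen_psm_table,
    gen_xic_trace,
    random_reference,
)


class TestDeterminism:
    def test_all_generators_bit_identical_on_same_seed(self):
        params = ImageSimParams(
            nuclei=[NucleusSpec((22.0, 20.0, 20.0), 4.0, 80.0, 1.0)], seed=5
        )
        s1, t1 = gen_nucleus_stack(params)
        s2, t2 = gen_nucleus_stack(params)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        pd.testing.assert_frame_equal(t1, t2)

        spec = CohortSpec([("fresh", 10, ("lognormal", 0, 0.3))], "fresh")
        pd.testing.assert_frame_equal(gen_ddi_cohort(spec, seed=3), gen_ddi_cohort(spec, seed=3))

        p1, tr1 = gen_psm_table(10, 3, 0.3, seed=4)
        p2, tr2 = gen_psm_table(10, 3, 0.3, seed=4)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(tr1, tr2)

        ref = random_reference(2000, seed=6)
        dp = DamageSimParams(n_reads=200, seed=7)
        r1, u1 = gen_ancient_reads(ref, dp)
        r2, u2 = gen_ancient_reads(ref, dp)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert all((a.qualities == b.qualities).all() for a, b in zip(r1, r2))
        pd.testing.assert_frame_equal(u1, u2)


class TestNucleusStack:
    def test_zero_nuclei_pure_background(self):
        params = ImageSimParams(nuclei=[], background=10.0, noise_sd=1.0, seed=0)
        stack, truth = gen_nucleus_stack(params)
        assert truth.empty
        assert stack.voxels.mean() == pytest.approx(10.0, abs=0.1)

    def test_zero_damage_zero_gamma_truth(self):
        params = ImageSimParams(
            nuclei=[NucleusSpec((22.0, 20.0, 20.0), 4.0, 80.0, 0.0)], seed=0
        )
        _, truth = gen_nucleus_stack(params)
        assert truth["gamma_signal"].iloc[0] == 0.0
        assert truth["h2b_signal"].iloc[0] > 0.0

    def test_boundary_overlap_rejected(self):
        params = ImageSimParams(
            nuclei=[NucleusSpec((2.0, 2.0, 2.0), 5.0, 80.0, 1.0)], seed=0
        )
        with pytest.raises(ValueError, match="boundary"):
            gen_nucleus_stack(params)

    def test_truth_signal_linear_in_brightness(self):
        signals = []
        for b in (50.0, 100.0, 150.0):
            params = ImageSimParams(
                nuclei=[NucleusSpec((22.0, 20.0, 20.0), 4.0, b, 1.0)], seed=0
            )
            _, truth = gen_nucleus_stack(params)
            signals.append(truth["h2b_signal"].iloc[0])
        s = np.array(signals)
        # equally spaced brightness levels: increments equal, intercept zero
        assert s[1] - s[0] == pytest.approx(s[2] - s[1], rel=1e-9)
        assert s[1] == pytest.approx(2 * s[0], rel=1e-9)

    def test_segmentation_recovers_rendered_truth(self, two_sphere_stack):
        stack, truth = two_sphere_stack
        masks = imaging.segment_nuclei(stack, 0, min_volume=50)
        assert len(masks) == 2
        vz, vy, vx = stack.voxel_size
        true_centroids = {
            (row.centroid_z_um / vz, row.centroid_y_um / vy, row.centroid_x_um / vx)
            for row in truth[truth.frame == 0].itertuples()
        }
        from scipy import ndimage as ndi

        for mask in masks:
            c = ndi.center_of_mass(mask)
            assert any(max(abs(a - b) for a, b in zip(c, tc)) <= 1.0 for tc in true_centroids)


class TestCohort:
    def test_unknown_reference_group_rejected(self):
        with pytest.raises(ValueError, match="reference group"):
            CohortSpec([("fresh", 5, ("constant", 1.0))], "missing")

    def test_reference_median_ddi_exactly_one(self):
        spec = CohortSpec(
            [("fresh", 17, ("lognormal", 0, 0.4)), ("FT_20", 12, ("lognormal", 1.0, 0.4))],
            "fresh",
        )
        cohort = gen_ddi_cohort(spec, seed=1)
        ddi = imaging.compute_ddi(cohort, "fresh")
        assert float(ddi.loc[ddi.group == "fresh", "ddi"].median()) == 1.0

    def test_outcome_declines_with_damage(self):
        spec = CohortSpec(
            [("low", 400, ("constant", 0.5)), ("high", 400, ("constant", 3.5))], "low"
        )
        cohort = gen_ddi_cohort(spec, seed=2)
        rates = cohort.groupby("group")["developed"].mean()
        assert rates["low"] > 0.8 > 0.2 > rates["high"]


class TestPSMs:
    def test_prob_zero_no_deamidation(self):
        _, truth = gen_psm_table(30, 4, 0.0, seed=0)
        assert not truth["deamidated"].any()

    def test_prob_one_flags_every_nq_peptide(self):
        _, truth = gen_psm_table(30, 4, 1.0, seed=0)
        nq = truth[truth.has_nq]
        assert len(nq) > 0
        assert nq["deamidated"].all()
        assert not truth.loc[~truth.has_nq, "deamidated"].any()

    def test_scoring_reproduces_truth_flags(self):
        from paleovia.proteomics import deamidation_rates, filter_psms

        psms, truth = gen_psm_table(50, 5, 0.3, seed=9)
        kept = filter_psms(psms, min_confidence=0.0)  # keep all: truth covers every PSM
        rates = deamidation_rates(kept)
        expected = truth[truth.has_nq]
        assert rates.loc[0, "n_sequences_with_nq"] == len(expected)
        assert rates.loc[0, "n_deamidated"] == int(expected["deamidated"].sum())


class TestXICGen:
    def test_single_peak_area_conserved(self):
        trace = gen_xic_trace([("nondeamidated", 40.0, 123.0, 0.3)])
        area = np.trapezoid(trace.channels["nondeamidated"], trace.time)
        assert area == pytest.approx(123.0, rel=0.005)

    def test_zero_peaks_flat(self):
        trace = gen_xic_trace([])
        assert all(np.all(y == 0) for y in trace.channels.values())

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            gen_xic_trace([("nondeamidated", 40.0, 1.0, 0.0)])


class TestAncientReads:
    def test_delta0_zero_no_mismatches(self):
        ref = random_reference(3000, seed=1)
        reads, truth = gen_ancient_reads(ref, DamageSimParams(n_reads=300, delta0=0.0, seed=2))
        assert truth["n_damaged"].sum() == 0
        for r in reads:
            assert r.sequence == ref[r.start : r.end]

    def test_decay_zero_damage_only_terminal(self):
        ref = random_reference(3000, seed=3)
        _, truth = gen_ancient_reads(
            ref, DamageSimParams(n_reads=2000, delta0=0.5, decay=0.0, seed=4)
        )
        for row in truth.itertuples():
            if row.n_damaged:
                positions = {int(p) for p in row.damaged_positions_5p.split(";")}
                assert positions <= {0, row.length - 1}

    def test_terminal_frequencies_match_closed_form(self):
        """Generator expectation: freq(i) = delta0 * decay**i at the 5' end."""
        ref = random_reference(5000, seed=5)
        reads, _ = gen_ancient_reads(
            ref, DamageSimParams(n_reads=10_000, delta0=0.3, decay=0.5, seed=6)
        )
        prof = adna.terminal_damage_profile(reads, ref, k=10)
        for i, expected in enumerate([0.3, 0.15, 0.075]):
            n, d = int(prof.ct5_num[i]), int(prof.ct5_den[i])
            ci = 3 * np.sqrt(expected * (1 - expected) / d)
            assert abs(n / d - expected) < ci
            n3, d3 = int(prof.ga3_num[i]), int(prof.ga3_den[i])
            assert abs(n3 / d3 - expected) < 3 * np.sqrt(expected * (1 - expected) / d3)

    def test_modal_fragment_length_in_dominant_component(self):
        ref = random_reference(4000, seed=7)
        params = DamageSimParams(
            n_reads=5000,
            frag_length_mix=[(158.0, 8.0, 0.8), (320.0, 30.0, 0.2)],
            seed=8,
        )
        reads, _ = gen_ancient_reads(ref, params)
        fld = adna.fragment_length_distribution(reads)
        assert 150.0 <= fld.modal_length <= 166.0  # mean +/- 1 sd

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gen_ancient_reads("", DamageSimParams(n_reads=10))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DamageSimParams(delta0=1.5)
        with pytest.raises(ValueError):
            DamageSimParams(decay=1.0)
        with pytest.raises(ValueError):
            DamageSimParams(frag_length_mix=[(150.0, 5.0, 0.5)])
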