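"""mSINGS-style scoring, baseline construction and the MSI call rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmakit.msi import (
    MsiCaller,
    allele_count,
    build_baseline,
    call_msi,
    count_mutations,
    dilution_benchmark,
    msi_score,
    score_locus,
)
from plasmakit.types import MsatProfile, SomaticVariant


def _profile(counts, locus="MS000", start=12):
    counts = np.asarray(counts)
    return MsatProfile(locus, start + np.arange(counts.size), counts)


class TestAlleleCount:
    def test_single_allele(self):
        assert allele_count(_profile([0, 0, 100, 0, 0])) == 1

    def test_minor_allele_below_peak_fraction_not_counted(self):
        # 4 reads < 5% of the 100-read modal peak
        assert allele_count(_profile([0, 4, 100, 0, 0])) == 1
        assert allele_count(_profile([0, 5, 100, 0, 0])) == 2

    @given(
        counts=st.lists(st.integers(0, 500), min_size=1, max_size=12).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(deadline=None)
    def test_matches_exhaustive_recount(self, counts):
        """Equivalence oracle: plain-python recount of qualifying alleles."""
        profile = _profile(counts)
        modal = max(counts)
        expected = sum(1 for c in counts if c > 0 and c >= 0.05 * modal)
        assert allele_count(profile) == expected


class TestBaseline:
    def test_identical_single_allele_normals(self):
        normals = [[_profile([0, 0, 50, 0, 0])] for _ in range(3)]
        baseline = build_baseline(normals, min_depth=30)
        mu, sd, n = baseline["MS000"]
        assert (mu, sd, n) == (1.0, 0.0, 3)

    def test_population_sd_convention(self):
        # allele counts 2 and 4 across two normals: mu 3, population SD 1
        normals = [
            [_profile([0, 30, 30, 0, 0])],
            [_profile([20, 20, 20, 20, 0])],
        ]
        mu, sd, n = build_baseline(normals, min_depth=30)["MS000"]
        assert (mu, sd, n) == (3.0, 1.0, 2)

    def test_locus_covered_in_fewer_than_two_normals_excluded(self):
        normals = [
            [_profile([0, 0, 50, 0, 0]), _profile([0, 0, 50, 0, 0], locus="MS001")],
            [_profile([0, 0, 50, 0, 0])],
        ]
        baseline = build_baseline(normals, min_depth=30)
        assert "MS000" in baseline and "MS001" not in baseline

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_baseline([])

    def test_synthetic_mss_cohort_has_tight_baseline(self, msat_bank):
        baseline = build_baseline(msat_bank["normals"])
        sds = [sd for _, sd, _ in baseline.stats.values()]
        assert max(sds) < 1.0


class TestScoreLocus:
    def test_single_allele_profile_is_stable(self):
        assert score_locus(_profile([0, 0, 100, 0, 0]), (1.0, 0.0)) is False

    def test_excess_alleles_flagged_unstable(self):
        profile = _profile([40, 40, 100, 40, 0])  # 4 qualifying alleles
        assert score_locus(profile, (1.5, 0.5)) is True  # 4 > 1.5 + 2*0.5

    def test_low_depth_locus_not_evaluated(self):
        assert score_locus(_profile([2, 3, 10, 0, 0]), (1.0, 0.0), min_depth=30) is None


class TestMsiScore:
    def test_all_stable(self, msat_bank):
        baseline = build_baseline(msat_bank["normals"])
        fraction, n_eval, n_unstable = msi_score(
            msat_bank["mss"][0].msat_profiles, baseline
        )
        assert n_unstable <= 1 and fraction < 0.05
        assert n_eval > 90

    def test_fraction_is_ratio(self):
        stable = [_profile([0, 0, 200, 0, 0], locus=f"MS{i:03d}") for i in range(88)]
        unstable = [
            _profile([100, 0, 100, 0, 100], locus=f"MS{i:03d}") for i in range(88, 100)
        ]
        normals = [
            [_profile([0, 0, 200, 0, 0], locus=f"MS{i:03d}") for i in range(100)]
            for _ in range(2)
        ]
        baseline = build_baseline(normals)
        fraction, n_eval, n_unstable = msi_score(stable + unstable, baseline)
        assert (fraction, n_eval, n_unstable) == (0.12, 100, 12)

    def test_msi_sample_scores_at_least_its_unstable_fraction(self, msat_bank):
        baseline = build_baseline(msat_bank["normals"])
        sample = msat_bank["msi"][0]
        fraction, _, _ = msi_score(sample.msat_profiles, baseline)
        planted = len(sample.ground_truth.unstable_loci) / 100
        assert fraction >= planted - 0.02


class TestCountMutations:
    def test_empty(self):
        assert count_mutations([]) == (0, 0)

    def test_all_classes_included(self):
        def v(effect, ref, alt, pos):
            return SomaticVariant(
                chrom="chr1", pos=pos, ref=ref, alt=alt, gene="G", effect=effect,
                cfdna_ref_depth=90, cfdna_alt_depth=10,
            )

        variants = (
            [v("synonymous", "A", "G", 100 + i) for i in range(3)]
            + [v("intronic", "C", "T", 200 + i) for i in range(2)]
            + [v("frameshift", "CA", "C", 300)]
        )
        assert count_mutations(variants) == (5, 1)


class TestCallMsi:
    def test_low_tumor_fraction_not_evaluable(self):
        assert call_msi(0.2, (50, 30), tf=0.05).call == "not_evaluable"

    def test_msi_called_with_elevated_mutations(self):
        result = call_msi(0.15, (60, 40), tf=0.3, cna_burden=0.05,
                          mutation_count_reference=10)
        assert result.call == "MSI" and not result.low_confidence

    def test_cin_exception_downgrades_to_mss(self):
        # high score, no mutation elevation, heavy copy-number burden
        result = call_msi(0.12, (6, 2), tf=0.80, cna_burden=0.5,
                          mutation_count_reference=10)
        assert result.call == "MSS" and result.cin_exception

    def test_score_below_cutoff_is_mss(self):
        assert call_msi(0.09, (60, 40), tf=0.5).call == "MSS"

    def test_cutoff_inclusive(self):
        assert call_msi(0.10, (60, 40), tf=0.5,
                        mutation_count_reference=10).call == "MSI"

    def test_high_score_without_cin_evidence_is_low_confidence_msi(self):
        result = call_msi(0.12, (6, 2), tf=0.8, cna_burden=0.05,
                          mutation_count_reference=10)
        assert result.call == "MSI" and result.low_confidence


class TestMsiCallerEstimator:
    def test_get_set_params_roundtrip(self):
        caller = MsiCaller()
        caller.set_params(k=3.0, min_loci=20)
        assert caller.get_params()["k"] == 3.0
        with pytest.raises(ValueError):
            caller.set_params(bogus=1)

    def test_predict_requires_fit(self, msat_bank):
        with pytest.raises(RuntimeError):
            MsiCaller().predict([msat_bank["mss"][0].msat_profiles])

    def test_separates_msi_from_mss(self, msat_bank):
        caller = MsiCaller().fit(msat_bank["normals"])
        msi_pred = caller.predict([s.msat_profiles for s in msat_bank["msi"]])
        mss_pred = caller.predict([s.msat_profiles for s in msat_bank["mss"]])
        assert msi_pred.all()
        assert not mss_pred.any()

    def test_score_monotone_in_number_of_unstable_loci(self, msat_bank):
        from plasmakit.simulate import SimulationConfig, simulate_sample

        caller = MsiCaller().fit(msat_bank["normals"])
        scores = []
        for frac in (0.05, 0.10, 0.20, 0.40):
            cfg = SimulationConfig(seed=31, n_patients=1, true_tf=1.0,
                                   msi_status=True, unstable_locus_fraction=frac)
            scores.append(caller.score_samples(
                [simulate_sample(cfg, 0).msat_profiles])[0])
        assert all(a < b for a, b in zip(scores, scores[1:]))


class TestDilutionBenchmark:
    def test_sensitivity_monotone_and_specificity_invariant(self, msat_bank):
        table = dilution_benchmark(
            [s.msat_profiles for s in msat_bank["msi"]],
            [s.msat_profiles for s in msat_bank["mss"]],
            msat_bank["normals"],
            purity_grid=[0.0, 0.10, 1.0],
            seed=2,
        )
        sens = table["sensitivity"].to_numpy()
        assert sens[0] < 0.5  # signal destroyed at purity 0
        assert (np.diff(sens) >= 0).all()
        assert table["specificity"].nunique() == 1

    def test_bad_purity_rejected(self, msat_bank):
        with pytest.raises(ValueError):
            dilution_benchmark(
                [s.msat_profiles for s in msat_bank["msi"]],
                [s.msat_profiles for s in msat_bank["mss"]],
                msat_bank["normals"],
                purity_grid=[-0.1],
            )
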