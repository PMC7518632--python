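import numpy as np
import pytest

from metabrand.cohort import read_cohort_table, write_cohort_table
from metabrand.synthetic import (
    ADNI_MARGINALS,
    CohortParams,
    HNR_MARGINALS,
    PhantomParams,
    adni_cohort_params,
    hnr_cohort_params,
    mechanism_cohort_params,
    participant_seed,
    simulate_cohort,
    simulate_metadata,
    simulate_volume,
)


class TestPhantomVolume:
    def test_shape_and_dtype(self):
        vol = simulate_volume("Control", PhantomParams(), seed=0)
        assert vol.depth == 192
        assert vol.slices.shape == (192, 224, 224)
        assert vol.slices.dtype == np.uint8

    def test_deterministic_per_seed(self):
        a = simulate_volume("aMCI", seed=4)
        b = simulate_volume("aMCI", seed=4)
        assert np.array_equal(a.slices, b.slices)
        c = simulate_volume("aMCI", seed=5)
        assert not np.array_equal(a.slices, c.slices)

    def test_noise_free_same_label_volumes_identical(self):
        params = PhantomParams(noise_sd=0.0, atrophy_sd=0.0)
        a = simulate_volume("Control", params, seed=1)
        b = simulate_volume("Control", params, seed=2)
        assert np.array_equal(a.slices, b.slices)

    def test_amci_has_larger_ventricles(self):
        """Low-intensity voxel count inside the brain is higher for aMCI."""
        params = PhantomParams(noise_sd=0.0)
        counts = {}
        for label in ("aMCI", "Control"):
            n_low = []
            for seed in range(10):
                vol = simulate_volume(label, params, seed=seed)
                mid = vol.slices[80:110]
                n_low.append(int(((mid > 0) & (mid < 50)).sum()))
            counts[label] = np.mean(n_low)
        assert counts["aMCI"] > counts["Control"]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            PhantomParams(ventricle_radii=(70.0, 90.0, 70.0))
        with pytest.raises(ValueError, match="167"):
            PhantomParams(depth=100)


class TestMetadataGeneration:
    def test_published_marginal_class_counts(self):
        cohort = simulate_metadata(params=hnr_cohort_params(), seed=1)
        counts = cohort.class_counts()
        assert len(cohort) == 120
        assert abs(counts["aMCI"] - 61) <= 8
        assert abs(counts["Control"] - 59) <= 8

    def test_table_counts_are_consistent(self):
        # HNR marital-status counts total 119 as printed (one participant
        # unaccounted for in the source summary); all other variables
        # total the cohort size.
        for marginals, n in ((HNR_MARGINALS, 120), (ADNI_MARGINALS, 624)):
            for var, weights in marginals.items():
                total = sum(weights.values())
                if marginals is HNR_MARGINALS and var == "marital_status":
                    assert total == 119
                else:
                    assert total == n

    def test_deterministic(self):
        a = simulate_metadata(params=hnr_cohort_params(), seed=3)
        b = simulate_metadata(params=hnr_cohort_params(), seed=3)
        assert a.records == b.records

    def test_generated_tables_pass_csv_roundtrip(self, tmp_path):
        cohort = simulate_metadata(params=adni_cohort_params(), seed=1)
        path = write_cohort_table(cohort, tmp_path / "cohort.csv")
        back = read_cohort_table(path, scheme="ADNI")
        assert back.records == cohort.records

    def test_independence_at_odds_ratio_one(self):
        params = CohortParams(n=5000, amci_fraction=0.5,
                              apoe_amci_association=1.0)
        cohort = simulate_metadata(params=params, seed=0)
        p = {
            lab: np.mean([r.apoe4 == "Positive" for r in cohort if r.label == lab])
            for lab in ("aMCI", "Control")
        }
        assert abs(p["aMCI"] - p["Control"]) < 0.04

    def test_implied_odds_ratio_recovered(self):
        """OR ~= 2.06 (positive-fraction 21/61 vs 12/59) at large n."""
        params = CohortParams(n=5000, amci_fraction=61 / 120,
                              apoe_amci_association=(21 / 40) / (12 / 47))
        cohort = simulate_metadata(params=params, seed=0)
        counts = {(lab, ap): 0 for lab in ("aMCI", "Control")
                  for ap in ("Positive", "Negative")}
        for r in cohort:
            counts[(r.label, r.apoe4)] += 1
        odds_a = counts[("aMCI", "Positive")] / counts[("aMCI", "Negative")]
        odds_c = counts[("Control", "Positive")] / counts[("Control", "Negative")]
        assert 1.4 <= odds_a / odds_c <= 3.2

    def test_marginals_converge(self):
        cohort = simulate_metadata(params=hnr_cohort_params(), seed=2)
        # at n=120 the empirical APOE marginal stays near 27.5%
        frac = np.mean([r.apoe4 == "Positive" for r in cohort])
        assert abs(frac - 33 / 120) < 0.12
        big = simulate_metadata(
            params=CohortParams(n=5000, amci_fraction=0.5), seed=2
        )
        frac = np.mean([r.apoe4 == "Positive" for r in big])
        assert abs(frac - 33 / 120) < 0.02

    def test_infeasible_marginals_rejected(self):
        bad = {k: dict(v) for k, v in HNR_MARGINALS.items()}
        bad["gender"] = {"Female": 0, "Male": 0}
        with pytest.raises(ValueError, match="infeasible"):
            CohortParams(marginals=bad)


class TestSimulateCohort:
    def test_signal_switches(self):
        params = mechanism_cohort_params(6)
        cohort, volumes = simulate_cohort(
            params, PhantomParams(), image_signal=False, metadata_signal=False,
            seed=0,
        )
        assert len(volumes) == len(cohort) == 6
        assert all(v.depth == 192 for v in volumes.values())

    def test_volume_seeds_derived_from_participant_id(self):
        assert participant_seed(1, "P0000") != participant_seed(1, "P0001")
        assert participant_seed(1, "P0000") == participant_seed(1, "P0000")
        assert 0 <= participant_seed(123, "x") < 2**31

    def test_cohort_reproducible(self):
        params = mechanism_cohort_params(4)
        a_cohort, a_vols = simulate_cohort(params, seed=9)
        b_cohort, b_vols = simulate_cohort(params, seed=9)
        assert a_cohort.records == b_cohort.records
        for pid in a_vols:
            assert np.array_equal(a_vols[pid].slices, b_vols[pid].slices)
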