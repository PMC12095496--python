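"""Screen equations and cryptic-repair inference."""

import numpy as np
import pandas as pd
import pytest

from evascore.outcomes import (
    MeasurementValidationError,
    death_corrected_frequency,
    grna_activity,
    infer_cryptic_repair,
    lsr_correction_factor,
    summarize_screen,
    validate_measurements,
)


class TestEquations:
    @pytest.mark.parametrize(
        "death,freq,expected",
        [(20, 50, 40.0), (0, 73, 73.0), (100, 50, 0.0), (50, 0, 0.0)],
    )
    def test_death_corrected_frequency(self, death, freq, expected):
        assert death_corrected_frequency(death, freq) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "death,freq,expected",
        [(50, 80, 90.0), (0, 59, 59.0), (30, 100, 100.0), (70, 100, 100.0)],
    )
    def test_grna_activity(self, death, freq, expected):
        assert grna_activity(death, freq) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "maxact,act,expected", [(80, 60, 0.5), (55, 55, 1.0), (90, 50, 0.2)]
    )
    def test_lsr_correction_factor(self, maxact, act, expected):
        assert lsr_correction_factor(maxact, act) == pytest.approx(expected)

    def test_saturated_activity_gives_undefined_factor(self):
        assert np.isnan(lsr_correction_factor(100, 100))

    def test_composition_identity_on_grid(self):
        deaths = np.linspace(0, 100, 21)
        freqs = np.linspace(0, 100, 21)
        for d in deaths:
            for f in freqs:
                assert grna_activity(d, f) == d + death_corrected_frequency(d, f)

    def test_activity_monotone_in_both_arguments(self):
        grid = np.linspace(0, 99, 12)
        for d in grid:
            acts = [grna_activity(d, f) for f in grid]
            assert all(a <= b for a, b in zip(acts, acts[1:]))
        for f in grid:
            acts = [grna_activity(d, f) for d in grid]
            assert all(a <= b + 1e-12 for a, b in zip(acts, acts[1:]))

    @pytest.mark.parametrize("bad", [(-1, 50), (50, 101), (130, 0)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(MeasurementValidationError):
            grna_activity(*bad)


def conditions(act_minus, act_plus, death=10.0, target="T1", donor=True):
    """Build condition means with the requested ±M3814 activities."""
    rows = []
    for m3814, act in ((False, act_minus), (True, act_plus)):
        editing = (act - death) / (100.0 - death) * 100.0
        rows.append(
            {
                "target": target,
                "donor": donor,
                "m3814": m3814,
                "cell_death": death,
                "indels": editing * 0.7,
                "substitutions": editing * 0.3,
            }
        )
    return pd.DataFrame(rows)


class TestInference:
    def test_higher_activity_with_m3814_means_perfect_repair(self):
        s = infer_cryptic_repair(conditions(60.0, 80.0))
        assert s.repair_class == "perfect_tendency"
        assert s.perfect_repair == pytest.approx(20.0)
        assert s.large_scale_repair == 0.0
        assert s.max_activity == pytest.approx(80.0)

    def test_lower_activity_with_m3814_means_large_scale_repair(self):
        s = infer_cryptic_repair(conditions(80.0, 60.0))
        assert s.repair_class == "large_scale_tendency"
        assert s.large_scale_repair == pytest.approx(20.0)
        assert s.perfect_repair == 0.0
        corr = s.corrected_frequency[(True, True)]
        assert corr["factor"] == pytest.approx(0.5)
        # corrected = death-corrected frequency x factor
        editing_plus = (60.0 - 10.0) / 90.0 * 100.0
        assert corr["indels"] == pytest.approx(
            death_corrected_frequency(10.0, editing_plus * 0.7) * 0.5
        )

    def test_small_difference_is_comparable(self):
        s = infer_cryptic_repair(conditions(70.0, 72.0))
        assert s.repair_class == "comparable"
        assert s.perfect_repair == 0.0 and s.large_scale_repair == 0.0

    def test_band_is_inclusive_at_five_points(self):
        assert infer_cryptic_repair(conditions(70.0, 75.0)).repair_class == "comparable"
        assert (
            infer_cryptic_repair(conditions(70.0, 75.1)).repair_class
            == "perfect_tendency"
        )

    def test_missing_condition_flagged_unavailable(self):
        df = conditions(70.0, 80.0).iloc[:1]
        s = infer_cryptic_repair(df)
        assert not s.available
        assert s.repair_class == "comparable"

    def test_donor_absent_pair_used_as_fallback(self):
        df = conditions(60.0, 80.0, donor=False)
        df["substitutions"] = 0.0
        s = infer_cryptic_repair(df)
        assert s.repair_class == "perfect_tendency"


def tidy_screen(n_rep=3):
    rows = []
    for target, (am, ap) in {"T1": (60.0, 80.0), "T2": (80.0, 60.0), "T3": (70.0, 71.0)}.items():
        for rep in range(1, n_rep + 1):
            for m3814, act in ((False, am), (True, ap)):
                for donor in (False, True):
                    editing = (act - 10.0) / 90.0 * 100.0
                    subs = editing * 0.3 if donor else 0.0
                    rows.append(
                        {
                            "target": target,
                            "donor": donor,
                            "m3814": m3814,
                            "replicate": rep,
                            "cell_death": 10.0,
                            "indels": editing - subs,
                            "substitutions": subs,
                        }
                    )
    return pd.DataFrame(rows)


class TestSummarizeScreen:
    def test_classification_partitions_targets(self):
        summary, _ = summarize_screen(tidy_screen())
        assert sorted(summary["repair_class"]) == [
            "comparable",
            "large_scale_tendency",
            "perfect_tendency",
        ]
        nonzero = (summary["perfect_repair"] > 0) & (summary["large_scale_repair"] > 0)
        assert not nonzero.any()

    def test_duplicate_replicates_correlate_perfectly(self):
        _, reps = summarize_screen(tidy_screen(n_rep=2))
        assert np.allclose(reps.dropna(subset=["r"])["r"], 1.0)

    def test_single_replicate_warns_and_omits_correlations(self):
        with pytest.warns(UserWarning, match="single replicate"):
            summary, reps = summarize_screen(tidy_screen(n_rep=1))
        assert len(reps) == 0
        assert len(summary) == 3

    def test_substitutions_without_donor_warn(self):
        df = tidy_screen()
        df.loc[(~df["donor"]), "substitutions"] = 5.0
        df.loc[(~df["donor"]), "indels"] -= 5.0
        with pytest.warns(UserWarning, match="donor"):
            validate_measurements(df)

    def test_schema_violation_rejected(self):
        with pytest.raises(MeasurementValidationError, match="replicate"):
            summarize_screen(tidy_screen().drop(columns=["replicate"]))
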