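"""Shield-length comparison protocol: eligibility, Bonferroni, summaries."""

import numpy as np
import pandas as pd
import pytest

from carcingeo.datasets import FOCAL_SPECIES, SyntheticDatasetSpec, generate_size_table
from carcingeo.errors import SchemaError, UndefinedTestError
from carcingeo.sizecomp import (
    GROUPS,
    comparison_counts,
    eligibility_filter,
    group_summary,
    pairwise_compare,
    source_contrast,
)
from carcingeo.stats import welch_t


def _records(spec_counts, rng=None, focal_mean=5.0):
    """Small builder: spec_counts maps species -> (nf, of, males)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for sp, (nf, of, m) in spec_counts.items():
        mean = focal_mean if sp == "focal" else 4.0
        for group, n, sex, ovig in [("nf", nf, "female", False),
                                    ("of", of, "female", True),
                                    ("m", m, "male", False)]:
            for _ in range(n):
                rows.append({"species": sp, "sex": sex, "ovigerous": ovig,
                             "shield_length": float(rng.normal(mean, 0.5)),
                             "source": "this_study"})
    return pd.DataFrame(rows)


def test_two_individuals_in_group_is_excluded():
    df = _records({"focal": (3, 3, 3), "sparse": (2, 3, 3)})
    elig = eligibility_filter(df)
    row = elig[(elig["species"] == "sparse")
               & (elig["group"] == "nonovig_female")].iloc[0]
    assert row["n"] == 2 and not row["eligible"]
    # three individuals is enough
    row3 = elig[(elig["species"] == "sparse")
                & (elig["group"] == "ovig_female")].iloc[0]
    assert row3["eligible"]


def test_empty_input_gives_empty_eligibility():
    empty = pd.DataFrame(columns=["species", "sex", "ovigerous",
                                  "shield_length"])
    assert len(eligibility_filter(empty)) == 0


def test_missing_focal_species_raises():
    df = _records({"a": (3, 3, 3)})
    with pytest.raises(SchemaError):
        comparison_counts(df, "focal")


def test_comparison_counts_reproduce_published_divisors():
    df = generate_size_table(SyntheticDatasetSpec(seed=2))
    counts = comparison_counts(df, FOCAL_SPECIES)
    assert counts == {"nonovig_female": 14, "ovig_female": 13,
                      "all_female": 15, "male": 20}
    # thresholds printed at 3 d.p.: 0.05/14 = 0.004, 0.05/20 = 0.003
    assert round(0.05 / counts["nonovig_female"], 3) == 0.004
    assert round(0.05 / counts["ovig_female"], 3) == 0.004
    assert round(0.05 / counts["all_female"], 3) == 0.003
    assert round(0.05 / counts["male"], 3) == 0.003


def test_pairwise_flags_published_size_gap():
    # male means 5.49 +- 0.56 vs 4.08 +- 1.11, n = 30 each: the published
    # focal-vs-congener contrast is detected at Bonferroni-adjusted alpha
    rng = np.random.default_rng(7)
    rows = []
    for sp, mean, sd in [("focal", 5.49, 0.56), ("other", 4.08, 1.11)]:
        for _ in range(30):
            rows.append({"species": sp, "sex": "male", "ovigerous": False,
                         "shield_length": float(rng.normal(mean, sd))})
    df = pd.DataFrame(rows)
    res = pairwise_compare(df, "focal", family_alpha=0.05)
    male = res[res["group"] == "male"].iloc[0]
    assert male["alpha_bonferroni"] == pytest.approx(0.05)  # single comparison
    assert male["significant"]
    assert male["t"] > 0


def test_single_comparison_uses_unadjusted_alpha():
    df = _records({"focal": (3, 0, 3), "only": (3, 0, 3)})
    res = pairwise_compare(df, "focal", family_alpha=0.05)
    assert np.allclose(res["alpha_bonferroni"], 0.05)


def test_bonferroni_monotone_in_comparison_count():
    # adding eligible species can only lower the per-test threshold, so a
    # result that is non-significant at m comparisons stays non-significant
    rng = np.random.default_rng(3)
    base = {"focal": (0, 0, 10), "a": (0, 0, 10)}
    df1 = _records(base, np.random.default_rng(3))
    res1 = pairwise_compare(df1, "focal")
    more = dict(base, **{f"x{i}": (0, 0, 10) for i in range(8)})
    df2 = _records(more, np.random.default_rng(3))
    res2 = pairwise_compare(df2, "focal")
    a1 = res1[res1["other_species"] == "a"].iloc[0]
    a2 = res2[res2["other_species"] == "a"].iloc[0]
    assert a1["t"] == pytest.approx(a2["t"], abs=1e-12)
    assert a2["alpha_bonferroni"] < a1["alpha_bonferroni"]
    assert (not a1["significant"]) or a1["p_raw"] <= a1["alpha_bonferroni"]
    if not a1["significant"]:
        assert not a2["significant"]


def test_pairwise_invariant_to_record_order():
    df = _records({"focal": (5, 5, 5), "a": (5, 5, 5), "b": (5, 5, 5)})
    res1 = pairwise_compare(df, "focal")
    res2 = pairwise_compare(df.sample(frac=1.0, random_state=9), "focal")
    pd.testing.assert_frame_equal(res1, res2)


def test_familywise_false_positive_rate_under_null():
    # identical distributions: chance of any significant comparison across
    # the family stays at or below the family alpha (binomial 3-sigma band)
    reps, hits = 300, 0
    for rep in range(reps):
        rng = np.random.default_rng(10_000 + rep)
        df = _records({"focal": (0, 0, 8), "a": (0, 0, 8), "b": (0, 0, 8),
                       "c": (0, 0, 8), "d": (0, 0, 8)},
                      rng, focal_mean=4.0)
        res = pairwise_compare(df, "focal", family_alpha=0.05)
        hits += int(res["significant"].any())
    rate = hits / reps
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_group_summary_hand_values_and_errors():
    df = pd.DataFrame({
        "species": ["s", "s"], "sex": ["female", "female"],
        "ovigerous": [False, False], "shield_length": [4.0, 5.0]})
    s = group_summary(df, "s", "all_female")
    assert s["report"]["mean"] == 4.5 and s["report"]["sd"] == 0.71
    single = group_summary(df.iloc[:1], "s", "all_female")
    assert np.isnan(single["sd"])
    with pytest.raises(UndefinedTestError):
        group_summary(df, "s", "male")


def test_source_contrast_detects_study_vs_literature_gap():
    rng = np.random.default_rng(11)
    rows = []
    for source, mean, n in [("this_study", 5.49, 20), ("literature", 4.08, 50)]:
        for _ in range(n):
            rows.append({"species": "focal", "sex": "male", "ovigerous": False,
                         "shield_length": float(rng.normal(mean, 1.0)),
                         "source": source})
    res = source_contrast(pd.DataFrame(rows), "focal")
    male = res[res["group"] == "male"].iloc[0]
    assert male["t"] > 0 and male["p"] < 0.01


def test_shared_welch_routine_consistency():
    # the isotope and size modules report identical statistics for
    # identical samples because they share one implementation
    x = np.array([5.1, 5.3, 4.9, 5.6])
    y = np.array([4.0, 4.4, 3.9, 4.6])
    from carcingeo.isotopes import welch_t as welch_iso
    a, b = welch_iso(x, y), welch_t(x, y)
    assert a.t == b.t and a.df == b.df and a.p == b.p
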