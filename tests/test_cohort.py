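"""Region grouping, eligibility, age summaries, age-matched subsampling."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ceplane import RegionGroup, age_matched_subsample, age_summary, build_groups


def make_metadata(female_patients, male_patients, region="reg", hemisphere="L",
                  channels_per_patient=2):
    rows = []
    for sex, patients in (("F", female_patients), ("M", male_patients)):
        for pid, age in patients.items():
            for c in range(channels_per_patient):
                rows.append(
                    dict(patient_id=pid, sex=sex, age=age, region=region,
                         hemisphere=hemisphere, channel_id=f"{pid}c{c}")
                )
    return pd.DataFrame(rows)


def make_group(f_ages, m_ages, **kwargs):
    female = {f"F{i:02d}": [f"F{i:02d}c0"] for i in range(len(f_ages))}
    male = {f"M{i:02d}": [f"M{i:02d}c0"] for i in range(len(m_ages))}
    ages = {pid: a for pid, a in zip(sorted(female), f_ages)}
    ages.update({pid: a for pid, a in zip(sorted(male), m_ages)})
    return RegionGroup(region="reg", hemisphere="L", female=female, male=male,
                       ages=ages, **kwargs)


class TestBuildGroups:
    def test_five_per_sex_is_eligible(self):
        md = make_metadata({f"F{i}": 30 for i in range(5)},
                           {f"M{i}": 35 for i in range(5)})
        (g,) = build_groups(md)
        assert g.eligible

    def test_four_female_is_not_eligible(self):
        md = make_metadata({f"F{i}": 30 for i in range(4)},
                           {f"M{i}": 35 for i in range(12)})
        (g,) = build_groups(md)
        assert not g.eligible

    def test_channels_never_count_as_patients(self):
        # one female with 10 channels is still a single patient
        md = make_metadata({"F0": 28}, {f"M{i}": 35 for i in range(5)},
                           channels_per_patient=10)
        (g,) = build_groups(md)
        assert len(g.female) == 1
        assert not g.eligible

    def test_one_group_per_region_hemisphere(self):
        md = pd.concat([
            make_metadata({"F0": 30}, {"M0": 35}, region="a", hemisphere="L"),
            make_metadata({"F1": 30}, {"M1": 35}, region="a", hemisphere="R"),
            make_metadata({"F2": 30}, {"M2": 35}, region="b", hemisphere="L"),
        ])
        groups = build_groups(md)
        assert {(g.region, g.hemisphere) for g in groups} == {
            ("a", "L"), ("a", "R"), ("b", "L")
        }

    def test_eligibility_monotone_in_patients(self, rng):
        # adding one patient of either sex never flips eligible -> ineligible
        for _ in range(20):
            nf, nm = rng.integers(1, 9, size=2)
            md = make_metadata({f"F{i}": 30 for i in range(nf)},
                               {f"M{i}": 35 for i in range(nm)})
            (g,) = build_groups(md)
            extra_sex = "F" if rng.random() < 0.5 else "M"
            md2 = pd.concat([md, make_metadata(
                {"Fx": 40} if extra_sex == "F" else {},
                {"Mx": 40} if extra_sex == "M" else {})])
            (g2,) = build_groups(md2)
            assert not (g.eligible and not g2.eligible)

    def test_missing_column_raises_schema_error(self):
        md = make_metadata({"F0": 30}, {"M0": 35}).drop(columns=["age"])
        with pytest.raises(KeyError, match="age"):
            build_groups(md)

    def test_unnormalized_sex_rejected(self):
        md = make_metadata({"F0": 30}, {"M0": 35})
        md.loc[0, "sex"] = "female"
        with pytest.raises(ValueError, match="sex"):
            build_groups(md)


class TestAgeSummary:
    def test_hand_computed_mean_and_sd(self):
        g = make_group([20, 30, 40], [25, 35])
        summ = age_summary(g)
        assert summ["F"].mean_years == 30
        assert summ["F"].sd_years == pytest.approx(10.0)
        assert summ["F"].n == 3

    def test_single_patient_is_degenerate_with_zero_sd(self):
        summ = age_summary(make_group([44], [30, 40]))
        assert summ["F"].sd_years == 0.0
        assert summ["F"].degenerate

    def test_duplicate_patient_rows_collapse(self):
        md = make_metadata({"F0": 20, "F1": 40}, {"M0": 30}, channels_per_patient=7)
        (g,) = build_groups(md)
        summ = age_summary(g)
        assert summ["F"].n == 2
        assert summ["F"].mean_years == 30


def exhaustive_best(f_ages, m_ages, k, lam=0.1):
    """Independent oracle: enumerate every k-subset pair, return best objective."""
    best = None
    for sf in combinations(range(len(f_ages)), k):
        af = np.array([f_ages[i] for i in sf])
        for sm in combinations(range(len(m_ages)), k):
            am = np.array([m_ages[i] for i in sm])
            sd_f = af.std(ddof=1) if k > 1 else 0.0
            sd_m = am.std(ddof=1) if k > 1 else 0.0
            obj = abs(af.mean() - am.mean()) + lam * (sd_f + sd_m)
            if best is None or obj < best[0]:
                best = (obj, sf, sm)
    return best


class TestAgeMatchedSubsample:
    def test_matches_exhaustive_oracle(self):
        f_ages = [20, 25, 30, 35, 40, 60]
        m_ages = [30, 35, 40, 45, 50]
        g = make_group(f_ages, m_ages)
        sub = age_matched_subsample(g, k=5)
        obj_star, sf, _ = exhaustive_best(f_ages, m_ages, 5)
        chosen_f = sorted(np.array(f_ages)[list(sf)])
        assert sorted(sub.ages[p] for p in sub.female) == chosen_f
        summ = age_summary(sub)
        got = abs(summ["F"].mean_years - summ["M"].mean_years) + 0.1 * (
            summ["F"].sd_years + summ["M"].sd_years
        )
        assert got == pytest.approx(obj_star)

    def test_never_beaten_by_oracle_on_random_groups(self, rng):
        for _ in range(15):
            nf, nm = rng.integers(5, 11, size=2)
            f_ages = rng.integers(18, 66, size=nf).tolist()
            m_ages = rng.integers(18, 66, size=nm).tolist()
            g = make_group(f_ages, m_ages)
            sub = age_matched_subsample(g, k=5)
            summ = age_summary(sub)
            got = abs(summ["F"].mean_years - summ["M"].mean_years) + 0.1 * (
                summ["F"].sd_years + summ["M"].sd_years
            )
            assert got <= exhaustive_best(f_ages, m_ages, 5)[0] + 1e-12

    def test_exact_size_group_returned_whole(self):
        g = make_group([20, 25, 30, 35, 40], [22, 27, 32, 37, 42])
        sub = age_matched_subsample(g, k=5)
        assert sub.female == g.female
        assert sub.male == g.male

    def test_deterministic(self):
        g = make_group(list(range(20, 44, 2)), list(range(25, 49, 2)))
        a = age_matched_subsample(g, k=5, seed=1)
        b = age_matched_subsample(g, k=5, seed=1)
        assert sorted(a.female) == sorted(b.female)
        assert sorted(a.male) == sorted(b.male)

    def test_subsampled_group_keeps_channels(self):
        g = make_group([20, 25, 30, 35, 40, 60], [30, 35, 40, 45, 50])
        sub = age_matched_subsample(g, k=5)
        for pid, chans in sub.female.items():
            assert chans == g.female[pid]

    def test_too_few_patients_rejected(self):
        g = make_group([20, 25, 30], [30, 35, 40, 45, 50])
        with pytest.raises(ValueError, match="needs"):
            age_matched_subsample(g, k=5)
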