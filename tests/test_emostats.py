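"""Permutation statistics: exactness, calibration, FDR behaviour and power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emogait import emostats
from emogait.mocap_io import CONDITIONS


def _table(Y: np.ndarray, genders=None, conditions=None, feature="feat") -> pd.DataFrame:
    n, k = Y.shape
    conditions = conditions or list(CONDITIONS[:k])
    genders = genders if genders is not None else ["female"] * n
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:02d}" for i in range(n)], k),
            "gender": np.repeat(genders, k),
            "condition": np.tile(conditions, n),
            feature: Y.ravel(),
        }
    )


class TestPermRmAnova:
    def test_within_subject_constant_feature_is_null(self, rng):
        # every subject has an identical value across conditions
        Y = np.tile(rng.normal(size=(10, 1)), (1, 5))
        res = emostats.perm_rm_anova(_table(Y), "feat", n_perm=500, seed=0)
        assert res.p_perm > 0.9

    def test_matches_exhaustive_enumeration_on_4x2_design(self, rng):
        """Sampling with n_perm = the full 2^4 space equals hand enumeration."""
        Y = rng.normal(size=(4, 2))
        res = emostats.perm_rm_anova(_table(Y), "feat", exhaustive=True)
        f_obs = emostats.rm_anova_f(Y)
        fs = []
        for flips in itertools.product([0, 1], repeat=4):
            Yp = np.array([row[::-1] if fl else row for row, fl in zip(Y, flips)])
            fs.append(emostats.rm_anova_f(Yp))
        p_hand = (np.asarray(fs) >= f_obs - 1e-12).mean()
        assert res.p_perm == pytest.approx(p_hand)
        assert res.n_permutations == 16

    def test_parametric_f_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1))
        df = _table(Y)
        res = pg.rm_anova(
            data=df, dv="feat", within="condition", subject="subject_id"
        )
        assert emostats.rm_anova_f(Y) == pytest.approx(res["F"].iloc[0], rel=1e-9)

    def test_missing_cells_dropped_listwise(self, rng):
        Y = rng.normal(size=(8, 5))
        df = _table(Y)
        df.loc[(df.subject_id == "S00") & (df.condition == "fear"), "feat"] = np.nan
        res = emostats.perm_rm_anova(df, "feat", n_perm=200, seed=0)
        assert res.n_subjects == 7

    def test_degenerate_inputs_rejected(self, rng):
        df = _table(rng.normal(size=(1, 5)))
        with pytest.raises(ValueError, match="two complete subjects"):
            emostats.perm_rm_anova(df, "feat", n_perm=100)
        with pytest.raises(KeyError):
            emostats.perm_rm_anova(df, "nope")

    def test_type_one_error_is_calibrated(self, rng):
        """Under the null, P(p <= alpha) stays within Monte-Carlo error of
        alpha for alpha in {0.01, 0.05, 0.1}."""
        n_rep = 400
        ps = np.empty(n_rep)
        for r in range(n_rep):
            Y = rng.normal(size=(10, 5)) + rng.normal(size=(10, 1))
            f_obs = emostats.rm_anova_f(Y)
            colsums = emostats._permuted_colsums(Y, 300, rng)
            f_perm = emostats._f_from_colsums(colsums, Y)
            ps[r] = ((f_perm >= f_obs - 1e-12).sum() + 1) / 301
        for alpha in (0.01, 0.05, 0.1):
            rate = (ps <= alpha).mean()
            eps = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
            assert rate <= alpha + eps
            assert rate >= alpha - eps - 1.0 / 301


class TestPairwise:
    def test_bh_step_up_hand_case(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_pair_adjusted_equals_raw(self, rng):
        Y = rng.normal(size=(8, 2))
        rows = emostats.perm_pairwise(
            _table(Y), "feat", pairs=[("neutral", "happy")], n_perm=200, seed=0
        )
        assert rows[0]["p_fdr"] == pytest.approx(rows[0]["p_perm"])

    def test_signflip_matches_enumeration_n5(self, rng):
        Y = rng.normal(size=(5, 2))
        rows = emostats.perm_pairwise(
            _table(Y), "feat", pairs=[("neutral", "happy")], exhaustive=True
        )
        d = Y[:, 0] - Y[:, 1]
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        ts = []
        for signs in itertools.product([1.0, -1.0], repeat=5):
            ds = d * np.array(signs)
            ts.append(ds.mean() / (ds.std(ddof=1) / np.sqrt(5)))
        p_hand = (np.abs(ts) >= abs(t_obs) - 1e-12).mean()
        assert rows[0]["p_perm"] == pytest.approx(p_hand)
        assert rows[0]["n_permutations"] == 32

    def test_mirrored_differences_have_symmetric_null(self, rng):
        # condition B = -A differences: the sign-flip null is symmetric, so
        # the two-sided p from enumeration equals 1 for a zero-mean pattern
        d = np.array([1.0, -1.0, 2.0, -2.0, 0.5])
        Y = np.column_stack([d / 2, -d / 2])
        rows = emostats.perm_pairwise(
            _table(Y), "feat", pairs=[("neutral", "happy")], exhaustive=True
        )
        ts_pos = rows[0]["t_observed"]
        Y2 = -Y
        rows2 = emostats.perm_pairwise(
            _table(Y2), "feat", pairs=[("neutral", "happy")], exhaustive=True
        )
        assert rows2[0]["p_perm"] == pytest.approx(rows[0]["p_perm"])
        assert rows2[0]["t_observed"] == pytest.approx(-ts_pos)

    def test_too_few_pairs_rejected(self, rng):
        Y = rng.normal(size=(2, 2))
        with pytest.raises(ValueError, match="fewer than 3"):
            emostats.perm_pairwise(_table(Y), "feat", pairs=[("neutral", "happy")])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10))
    def test_bh_is_monotone_and_bounded(self, ps):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(ps, method="fdr_bh")[1]
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestTwoWay:
    def test_single_gender_table_rejected(self, rng):
        Y = rng.normal(size=(6, 5))
        with pytest.raises(ValueError, match="both genders"):
            emostats.perm_two_way(_table(Y), "feat", n_perm=50, seed=0)

    def test_mixed_f_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(10, 5)) + rng.normal(size=(10, 1))
        genders = ["female"] * 6 + ["male"] * 4
        df = _table(Y, genders=genders)
        res = pg.mixed_anova(
            data=df, dv="feat", within="condition",
            subject="subject_id", between="gender",
        )
        mine = emostats._mixed_f(Y, np.array(genders))
        by_source = dict(zip(res["Source"], res["F"]))
        assert mine["gender"] == pytest.approx(by_source["gender"], rel=1e-9)
        assert mine["emotion"] == pytest.approx(by_source["condition"], rel=1e-9)
        assert mine["interaction"] == pytest.approx(by_source["Interaction"], rel=1e-9)

    def test_female_only_effect_detected_as_interaction(self, rng):
        """A condition effect present only in female subjects shows up as a
        significant interaction with power > 0.5 at a large effect size."""
        hits = 0
        n_rep = 30
        genders = ["female"] * 14 + ["male"] * 10
        for _ in range(n_rep):
            Y = rng.normal(size=(24, 5)) + rng.normal(size=(24, 1))
            Y[:14, 2] += 1.5  # large female-only shift in one condition
            res = emostats.perm_two_way(
                _table(Y, genders=genders), "feat", n_perm=300,
                seed=int(rng.integers(2**31)),
            )
            hits += res["interaction"]["p_perm"] < 0.05
        assert hits / n_rep > 0.5


class TestScreenAll:
    def test_screen_reports_counts_and_is_reproducible(self, rng):
        n, k = 10, 5
        data = {f"f{j}": rng.normal(size=(n, k)) for j in range(6)}
        data["f0"][:, 1] += 2.0  # one real effect
        df = _table(data["f0"])
        df = df.rename(columns={"feat": "f0"})
        for j in range(1, 6):
            df[f"f{j}"] = data[f"f{j}"].ravel()
        s1 = emostats.screen_all(df, n_perm=400, seed=3)
        s2 = emostats.screen_all(df, n_perm=400, seed=3)
        pd.testing.assert_frame_equal(s1, s2)
        assert s1.loc["f0", "significant"]
        assert s1.attrs["n_significant"] >= 1

    def test_injected_sd_effect_is_flagged_reliably(self):
        """A +50% generative ML sway SD in one condition is flagged by the
        screen in >= 80% of replicate (reduced-scale, standing-only)
        studies."""
        import warnings

        from emogait import synthcap, standing_features as sf
        from emogait.mocap_io import COPSeries, cop_from_forceplate, synchronize

        eff = synthcap.EmotionEffectSpec.single("cop_sway_sd_ml", "sad", 1.5)
        n_rep, flagged = 15, 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(n_rep):
                rows = []
                for prof in synthcap.make_subjects(8, 4, seed=200 + rep):
                    for cond in CONDITIONS:
                        _, fp, _ = synthcap.generate_standing_segment(
                            prof, cond, eff, duration=35.0, seed=200 + rep
                        )
                        cop = cop_from_forceplate(synchronize(fp, 120.0))
                        w = COPSeries(120.0, cop.xy[:3600], cop.valid[:3600])
                        lab = sf.cluster_loci(w.xy, 0.02, rate=120.0)
                        out = sf.balance_features(w, lab)
                        rows.append({
                            "subject_id": prof.subject_id,
                            "gender": prof.gender,
                            "condition": cond,
                            "sd_ml": out["balance.standing.clustered.sd.ml"],
                        })
                res = emostats.perm_rm_anova(
                    pd.DataFrame(rows), "sd_ml", n_perm=500, seed=rep
                )
                flagged += res.p_perm < 0.05
        assert flagged / n_rep >= 0.8


class TestSensitivityPower:
    def test_null_effect_power_equals_alpha(self):
        p = emostats.sensitivity_power(
            0.0, n_subjects=12, n_conditions=5, corr=0.5,
            n_reps=200, n_perm=300, seed=4,
        )
        assert abs(p - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_huge_effect_power_saturates(self):
        p = emostats.sensitivity_power(
            1.5, n_subjects=12, n_conditions=5, corr=0.5,
            n_reps=40, n_perm=300, seed=4,
        )
        assert p == 1.0

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="corr"):
            emostats.sensitivity_power(0.2, corr=1.2, n_reps=2, n_perm=10)
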