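"""RCBD ANOVA partition, heterosis formulas, significance calibration."""

import numpy as np
import pandas as pd
import pytest

from heteropat.simdata import SimTrialSpec, simulate_trial
from heteropat.trials import TrialData, heterosis, heterosis_summary, rcbd_anova


def anova_oracle(values: dict[tuple[str, str], float]):
    """Closed-form RCBD sums of squares from first principles."""
    entries = sorted({e for e, _ in values})
    blocks = sorted({b for _, b in values})
    grand = np.mean(list(values.values()))
    b, g = len(blocks), len(entries)
    ss_block = g * sum((np.mean([values[(e, bl)] for e in entries]) - grand) ** 2 for bl in blocks)
    ss_geno = b * sum((np.mean([values[(e, bl)] for bl in blocks]) - grand) ** 2 for e in entries)
    ss_total = sum((v - grand) ** 2 for v in values.values())
    return ss_block, ss_geno, ss_total - ss_block - ss_geno


class TestAnova:
    def test_hand_computed_3x2_example(self, rcbd_3x2):
        with pytest.warns(RuntimeWarning, match="error mean square"):
            an = rcbd_anova(rcbd_3x2, "t")
        assert an.ss_block == pytest.approx(6.0, abs=1e-9)
        assert an.ss_genotype == pytest.approx(400.0, abs=1e-9)
        assert an.ss_error == 0.0
        assert an.ems == 0.0
        assert an.f_ratio == np.inf

    def test_all_values_equal(self):
        obs = pd.DataFrame(
            [(e, "parent", b, "t", 5.0) for e in ("x", "y") for b in ("B1", "B2")],
            columns=["entry", "role", "block", "trait", "value"],
        )
        t = TrialData(obs, pd.DataFrame({"trait": ["t"], "direction": ["high"]}))
        with pytest.warns(RuntimeWarning):
            an = rcbd_anova(t, "t")
        assert an.ss_genotype == an.ss_block == an.ss_error == 0.0
        assert an.cv_pct == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_partition_matches_first_principles_oracle(self, seed):
        rng = np.random.default_rng(seed)
        entries, blocks = [f"e{i}" for i in range(5)], ["B1", "B2", "B3"]
        values = {(e, b): float(rng.normal(50, 5)) for e in entries for b in blocks}
        obs = pd.DataFrame(
            [(e, "parent", b, "t", v) for (e, b), v in values.items()],
            columns=["entry", "role", "block", "trait", "value"],
        )
        t = TrialData(obs, pd.DataFrame({"trait": ["t"], "direction": ["high"]}))
        an = rcbd_anova(t, "t")
        ss_b, ss_g, ss_e = anova_oracle(values)
        assert an.ss_block == pytest.approx(ss_b, rel=1e-8)
        assert an.ss_genotype == pytest.approx(ss_g, rel=1e-8)
        assert an.ss_error == pytest.approx(ss_e, rel=1e-8)
        assert an.f_ratio == pytest.approx(an.gms / an.ems, rel=1e-12)
        grand = np.mean(list(values.values()))
        assert an.cv_pct == pytest.approx(100 * np.sqrt(an.ems) / grand, rel=1e-12)

    def test_zero_noise_trial_genotype_ss_closed_form(self):
        spec = SimTrialSpec(
            females=("F",), males=("M1", "M2"), n_blocks=3,
            traits={"y": "high"}, parent_mean_ranges={"y": (50, 150)},
            target_mph=5.0, error_sd=0.0, seed=7,
        )
        sim = simulate_trial(spec)
        an = rcbd_anova(sim.trial, "y")
        means = sim.trial.entry_means("y")
        expect = 3 * ((means - means.mean()) ** 2).sum()
        assert an.ss_error == 0.0
        assert an.ss_genotype == pytest.approx(expect, rel=1e-9)

    def test_unbalanced_rejected(self, rcbd_3x2):
        t = TrialData(
            rcbd_3x2.observations.iloc[:-1], rcbd_3x2.traits
        )
        with pytest.raises(ValueError, match="balanced"):
            rcbd_anova(t, "t")


def two_parent_trial(f1_mean, p1_mean, p2_mean, direction="high", noise_seed=None, sd=0.0):
    rows = []
    rng = np.random.default_rng(noise_seed)
    for b in ("B1", "B2", "B3"):
        for entry, role, mu in (
            ("P1", "parent", p1_mean), ("P2", "parent", p2_mean), ("H", "F1", f1_mean)
        ):
            rows.append((entry, role, b, "t", mu + (rng.normal(0, sd) if sd else 0.0)))
    obs = pd.DataFrame(rows, columns=["entry", "role", "block", "trait", "value"])
    return TrialData(obs, pd.DataFrame({"trait": ["t"], "direction": [direction]}))


class TestHeterosis:
    def test_formula_example_direction_high(self):
        t = two_parent_trial(99.0, 100.0, 80.0)
        rec = heterosis(t, [("H", "P1", "P2")]).iloc[0]
        assert rec.midparent == 90.0
        assert rec.mph == pytest.approx(10.0)
        assert rec.better_parent == 100.0
        assert rec.bph == pytest.approx(-1.0)

    def test_direction_low_uses_lower_parent(self):
        # earliness: the better parent is the earlier (lower-mean) one
        t = two_parent_trial(85.0, 100.0, 80.0, direction="low")
        rec = heterosis(t, [("H", "P1", "P2")]).iloc[0]
        assert rec.better_parent == 80.0
        assert rec.bph == pytest.approx(100 * (85 - 80) / 80)

    def test_f1_at_midparent_is_ns(self):
        t = two_parent_trial(90.0, 100.0, 80.0, noise_seed=3, sd=1.0)
        rec = heterosis(t, [("H", "P1", "P2")]).iloc[0]
        assert abs(rec.mph) < 5  # noise-scale deviation only
        assert rec.mph_sig in ("ns", "*")  # cannot be promoted past noise

    def test_bph_not_above_mph_for_high_traits(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p1, p2 = rng.uniform(50, 150, 2)
            f1 = rng.uniform(40, 160)
            t = two_parent_trial(f1, p1, p2)
            rec = heterosis(t, [("H", "P1", "P2")]).iloc[0]
            assert rec.bph <= rec.mph + 1e-9

    def test_invariant_to_block_relabeling(self):
        t = two_parent_trial(95.0, 100.0, 80.0, noise_seed=5, sd=2.0)
        relabeled = TrialData(
            t.observations.assign(
                block=t.observations.block.map({"B1": "Bz", "B2": "Ba", "B3": "Bm"})
            ),
            t.traits,
        )
        a = heterosis(t, [("H", "P1", "P2")]).iloc[0]
        b = heterosis(relabeled, [("H", "P1", "P2")]).iloc[0]
        assert a.mph == pytest.approx(b.mph) and a.mph_p == pytest.approx(b.mph_p)

    def test_gd_attached_and_missing_pair_warns(self):
        t = two_parent_trial(99.0, 100.0, 80.0)
        rec = heterosis(t, [("H", "P1", "P2")], gd={("P1", "P2"): 0.3}).iloc[0]
        assert rec.gd == 0.3
        from heteropat.popgen import DistanceMatrix

        dm = DistanceMatrix(sample_ids=["P1", "X"], values=np.zeros((2, 2)))
        with pytest.warns(RuntimeWarning, match="absent"):
            rec = heterosis(t, [("H", "P1", "P2")], gd=dm).iloc[0]
        assert np.isnan(rec.gd)

    def test_star_flag_type_i_error_near_nominal(self):
        # H0: F1 true mean equals midparent; 1,000 noisy RCBD replicates
        reps, hits = 1000, 0
        for seed in range(reps):
            t = two_parent_trial(90.0, 100.0, 80.0, noise_seed=seed, sd=2.0)
            rec = heterosis(t, [("H", "P1", "P2")]).iloc[0]
            hits += rec.mph_p < 0.05
        rate = hits / reps
        assert rate <= 0.07
        assert rate >= 0.03  # the test should not be grossly conservative either

    def test_summary_statistics_rounded(self):
        t = two_parent_trial(99.0, 100.0, 80.0)
        rec = heterosis(t, [("H", "P1", "P2")], gd={("P1", "P2"): 0.3})
        summ = heterosis_summary(rec)
        row = summ[(summ.trait == "t") & (summ.statistic == "mean")].iloc[0]
        assert row.mph == 10.0 and row.bph == -1.0 and row.gd == 0.3
        mins = summ[summ.statistic == "min"].iloc[0]
        maxs = summ[summ.statistic == "max"].iloc[0]
        assert mins.mph == maxs.mph == 10.0  # single record: mean=min=max
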