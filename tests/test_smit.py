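"""Co-transcriptional splicing curves, bias inversion and AUC resistance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from intronsens import InsertLengthDist, SimConfig, SmitCurve, SmitModel
from intronsens.smit import (
    average_comparisons,
    delta_auc,
    detect_onset,
    estimate_insert_dist,
    normalize_fraction_spliced,
    raw_fraction_spliced,
    wilcoxon_paired,
    windowed_auc,
)
from intronsens.synthio import (
    designed_smit_panel,
    logistic_splicing_curve,
    simulate_smit_reads,
)


def make_curve(positions, norm, gene="g", cond="c", bin_width=10, n=100):
    bins = pd.DataFrame(
        {
            "position": np.asarray(positions, float),
            "raw": norm,
            "norm": np.asarray(norm, float),
            "n_spliced": 0,
            "n_unspliced": 0,
            "n": n,
            "reliable": True,
        }
    )
    return SmitCurve(gene_id=gene, condition=cond, bin_width=bin_width, bins=bins)


class TestRawFraction:
    def test_hand_tally_single_bin(self):
        reads = pd.DataFrame(
            {
                "gene_id": ["g"] * 4,
                "condition": ["c"] * 4,
                "polII_pos": [12, 14, 15, 18],
                "spliced": [1, 1, 1, 0],
                "insert_len": [200] * 4,
            }
        )
        curve = raw_fraction_spliced(reads, bin_width=10)
        assert curve.bins["raw"].iloc[0] == pytest.approx(0.75)

    def test_zero_spliced_bin(self):
        reads = pd.DataFrame(
            {
                "gene_id": ["g"] * 3,
                "condition": ["c"] * 3,
                "polII_pos": [5, 6, 7],
                "spliced": [0, 0, 0],
                "insert_len": [200] * 3,
            }
        )
        assert raw_fraction_spliced(reads, 10).bins["raw"].iloc[0] == 0.0

    def test_fifty_reads_five_bins_hand_tally(self):
        rng = np.random.default_rng(23)
        pos = np.repeat([5, 15, 25, 35, 45], 10)
        spliced = (rng.random(50) < np.repeat([0.0, 0.2, 0.5, 0.8, 1.0], 10)).astype(int)
        reads = pd.DataFrame(
            {
                "gene_id": "g",
                "condition": "c",
                "polII_pos": pos,
                "spliced": spliced,
                "insert_len": 200,
            }
        )
        curve = raw_fraction_spliced(reads, 10)
        for b, center in enumerate([5.0, 15.0, 25.0, 35.0, 45.0]):
            mask = pos // 10 == b
            expected = spliced[mask].sum() / mask.sum()
            row = curve.bins[curve.bins["position"] == center].iloc[0]
            assert row["raw"] == pytest.approx(expected)

    def test_impossible_upstream_spliced_reads_excluded(self, caplog):
        reads = pd.DataFrame(
            {
                "gene_id": ["g"] * 3,
                "condition": ["c"] * 3,
                "polII_pos": [-20, -20, -20],
                "spliced": [1, 0, 0],
                "insert_len": [200] * 3,
            }
        )
        curve = raw_fraction_spliced(reads, 10)
        assert curve.bins["n"].sum() == 2
        assert "excluded" in caplog.text

    def test_empty_input_gives_empty_curve(self):
        curve = raw_fraction_spliced(pd.DataFrame(columns=[
            "gene_id", "condition", "polII_pos", "spliced", "insert_len"]))
        assert curve.bins.empty


class TestInsertDist:
    def test_point_mass_up_to_pseudocount(self):
        reads = pd.DataFrame({"insert_len": [250] * 500})
        dist = estimate_insert_dist(reads, support=(248, 252), pseudocount=0.5)
        # mass at 250: (500 + 0.5) / (500 + 5*0.5)
        assert dist.prob(250) == pytest.approx(500.5 / 502.5)

    def test_empty_class_gets_exact_pseudocount_mass(self):
        reads = pd.DataFrame({"insert_len": [200] * 300})
        eps = 0.25
        dist = estimate_insert_dist(reads, support=(200, 203), pseudocount=eps)
        assert dist.prob(202) == pytest.approx(eps / (300 + 4 * eps))

    def test_uniform_sample_near_uniform_masses(self):
        rng = np.random.default_rng(31)
        reads = pd.DataFrame({"insert_len": rng.integers(100, 120, 20000)})
        dist = estimate_insert_dist(reads, support=(100, 119))
        # multinomial bound: each mass within ~4 sd of 1/20
        p = 1 / 20
        sd = np.sqrt(p * (1 - p) / 20000)
        assert np.abs(dist.pmf - p).max() < 4.5 * sd

    def test_refuses_too_few_reads(self):
        with pytest.raises(ValueError, match="200"):
            estimate_insert_dist(pd.DataFrame({"insert_len": [250] * 10}))

    def test_masses_sum_to_one(self):
        dist = InsertLengthDist.from_normal(250, 60, (100, 600))
        assert dist.pmf.sum() == pytest.approx(1.0)


class TestNormalize:
    def _flat_dist(self):
        return InsertLengthDist(np.arange(100, 601), np.ones(501) / 501)

    def test_equal_weights_leave_raw_unchanged(self):
        curve_raw = make_curve([105.0], [0.37])
        curve_raw.bins["raw"] = 0.37
        out = normalize_fraction_spliced(curve_raw, self._flat_dist(),
                                         intron_length=100, primer_offset=150)
        assert out.bins["norm"].iloc[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_absorbing_states_unchanged(self, f):
        dist = InsertLengthDist.from_normal(250, 60, (100, 600))
        curve_raw = make_curve([155.0], [f])
        curve_raw.bins["raw"] = f
        curve_raw.bins["n_spliced"] = int(100 * f)
        curve_raw.bins["n_unspliced"] = 100 - int(100 * f)
        out = normalize_fraction_spliced(curve_raw, dist,
                                         intron_length=100, primer_offset=120)
        assert out.bins["norm"].iloc[0] == pytest.approx(f)

    def test_nonpositive_spliced_product_flagged(self):
        dist = InsertLengthDist.from_normal(250, 60, (100, 600))
        # at x=5 with offset 120 and intron 300: L_s = 125 - 300 < 0
        curve_raw = make_curve([5.0], [0.0])
        out = normalize_fraction_spliced(curve_raw, dist,
                                         intron_length=300, primer_offset=120)
        assert not out.bins["reliable"].iloc[0]
        assert np.isnan(out.bins["norm"].iloc[0])

    def test_roundtrip_recovers_truth_at_reliable_bins(self):
        """Generator with capture bias -> raw -> inversion recovers f_true."""
        cfg = designed_smit_panel(seed=0, reads_per_gene=5000,
                                  smit_conditions={"control": 1.0})
        reads, truth = simulate_smit_reads(cfg)
        dist = InsertLengthDist.from_normal(
            cfg.insert_mean, cfg.insert_sd, cfg.insert_support
        )
        n_checked = 0
        for gene, sub in reads.groupby("gene_id"):
            tr = truth[truth["gene_id"] == gene].iloc[0]
            curve = normalize_fraction_spliced(
                raw_fraction_spliced(sub, 40), dist,
                intron_length=int(tr["intron_length"]),
                primer_offset=int(tr["primer_offset"]),
            )
            b = curve.bins
            ok = (b["reliable"] & b["norm"].notna()).to_numpy()
            f_true = logistic_splicing_curve(
                b["position"].to_numpy(), tr["midpoint"], tr["slope"], tr["f_max"]
            )
            err = np.abs(b["norm"].to_numpy() - f_true)[ok]
            assert (err <= 0.05).all()
            n_checked += ok.sum()
        assert n_checked >= 5  # the flag must not be vacuous


class TestOnset:
    def test_step_curve_onset(self):
        pos = np.arange(-45.0, 300.0, 10.0)
        f = np.where(pos >= 120, 0.8, 0.0)
        assert detect_onset(make_curve(pos, f)) == 125.0  # first bin center >= 120

    def test_all_zero_curve_excluded(self):
        pos = np.arange(5.0, 200.0, 10.0)
        assert detect_onset(make_curve(pos, np.zeros(len(pos)))) is None

    def test_noisy_logistic_matches_hand_scan(self):
        rng = np.random.default_rng(41)
        pos = np.arange(5.0, 400.0, 10.0)
        f = np.clip(0.9 / (1 + np.exp(-(pos - 150) / 25)) + rng.normal(0, 0.01, len(pos)), 0, 1)
        theta, w = 0.05, 2
        # hand scan of the stated rule
        above = f > theta
        expected = None
        for i in range(len(pos) - w + 1):
            if above[i : i + w].all():
                expected = pos[i]
                break
        got = detect_onset(make_curve(pos, f), theta=theta, w=w)
        assert got == expected is not None

    def test_single_spike_not_onset_with_w2(self):
        pos = np.arange(5.0, 200.0, 10.0)
        f = np.zeros(len(pos))
        f[3] = 0.5  # isolated noise spike
        f[-2:] = 0.5
        assert detect_onset(make_curve(pos, f), theta=0.05, w=2) == pos[-2]


class TestWindowedAuc:
    def test_constant_one_gives_window_length(self):
        pos = np.arange(5.0, 400.0, 10.0)
        auc = windowed_auc(make_curve(pos, np.ones(len(pos))), onset=50, window_len=200)
        assert auc == pytest.approx(200.0, rel=0.01)

    def test_constant_half_gives_half(self):
        pos = np.arange(5.0, 400.0, 10.0)
        auc = windowed_auc(make_curve(pos, np.full(len(pos), 0.5)), onset=50,
                           window_len=200)
        assert auc == pytest.approx(100.0, rel=0.01)

    def test_piecewise_linear_matches_fine_riemann(self):
        pos = np.arange(5.0, 400.0, 10.0)
        f = np.interp(pos, [0, 100, 200, 400], [0.0, 0.2, 0.9, 0.9])
        auc = windowed_auc(make_curve(pos, f), onset=55, window_len=200)
        # fine-grid Riemann oracle on the same piecewise-linear curve
        grid = np.linspace(55, 255, 200001)
        fg = np.interp(grid, pos, f)
        riemann = fg.sum() * (grid[1] - grid[0])
        assert auc == pytest.approx(riemann, rel=0.01)

    def test_missing_bins_interpolated(self):
        pos = np.arange(5.0, 400.0, 10.0)
        f = np.full(len(pos), 0.6)
        f[10:13] = np.nan  # 3 of ~20 window bins missing
        auc = windowed_auc(make_curve(pos, f), onset=50, window_len=200)
        assert auc == pytest.approx(0.6 * 200, rel=0.02)

    def test_mostly_missing_window_withheld(self):
        pos = np.arange(5.0, 400.0, 10.0)
        f = np.full(len(pos), np.nan)
        f[:3] = 0.5
        assert windowed_auc(make_curve(pos, f), onset=50, window_len=200) is None

    def test_auc_monotone_in_pointwise_ordering(self):
        rng = np.random.default_rng(47)
        pos = np.arange(5.0, 400.0, 10.0)
        lo = rng.uniform(0, 0.5, len(pos))
        hi = lo + rng.uniform(0, 0.5, len(pos))
        auc_lo = windowed_auc(make_curve(pos, lo), onset=50, window_len=200)
        auc_hi = windowed_auc(make_curve(pos, hi), onset=50, window_len=200)
        assert auc_hi >= auc_lo


class TestDeltaAuc:
    @pytest.mark.parametrize(
        "c,t,d,r", [(100, 100, 0.0, 100.0), (100, 40, 0.6, 40.0), (100, 0, 1.0, 0.0)]
    )
    def test_examples(self, c, t, d, r):
        delta, ctx = delta_auc(c, t)
        assert delta == pytest.approx(d)
        assert ctx == pytest.approx(r)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            delta_auc(0.0, 50.0)

    def test_ratio_invariant_to_common_scaling(self):
        d1, r1 = delta_auc(120.0, 80.0)
        d2, r2 = delta_auc(1.2, 0.8)
        assert d1 == pytest.approx(d2)
        assert r1 == pytest.approx(r2)


class TestWilcoxonPaired:
    def test_identical_curves_withheld(self):
        pos = np.arange(5.0, 300.0, 10.0)
        f = np.linspace(0.1, 0.9, len(pos))
        p, n = wilcoxon_paired(make_curve(pos, f), make_curve(pos, f), onset=10)
        assert p is None and n == 0

    def test_six_positive_differences_exact(self):
        pos = np.arange(5.0, 65.0, 10.0)
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
        b = a - np.array([0.05, 0.04, 0.06, 0.03, 0.07, 0.02])
        p, n = wilcoxon_paired(make_curve(pos, a), make_curve(pos, b),
                               onset=0, window_len=100)
        assert n == 6
        assert p == pytest.approx(2 * (1 / 2**6))  # 0.03125

    def test_exact_p_matches_sign_pattern_enumeration(self):
        """n=8 differences: scipy exact equals full 2^8 enumeration."""
        rng = np.random.default_rng(53)
        pos = np.arange(5.0, 85.0, 10.0)
        a = rng.uniform(0.2, 0.9, 8)
        diffs = rng.uniform(0.01, 0.1, 8) * rng.choice([-1, 1], 8)
        b = a - diffs
        p, n = wilcoxon_paired(make_curve(pos, a), make_curve(pos, b),
                               onset=0, window_len=100)
        assert n == 8
        # brute-force null: all sign assignments of the |diff| ranks
        ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
        w_obs = ranks[diffs > 0].sum()
        dist = []
        for signs in itertools.product([0, 1], repeat=8):
            dist.append(sum(r for r, s in zip(ranks, signs) if s))
        dist = np.array(dist)
        p_lo = (dist <= w_obs).mean()
        p_hi = (dist >= w_obs).mean()
        p_exact = min(1.0, 2 * min(p_lo, p_hi))
        assert p == pytest.approx(p_exact)

    def test_too_few_pairs_withheld(self):
        pos = np.arange(5.0, 45.0, 10.0)
        a = np.array([0.5, 0.6, 0.7, 0.8])
        p, n = wilcoxon_paired(make_curve(pos, a), make_curve(pos, a - 0.1),
                               onset=0, window_len=100)
        assert p is None and n == 4


class TestAverageComparisons:
    def test_mean_of_three(self):
        mean, partial = average_comparisons([40.0, 44.0, 48.0])
        assert mean == pytest.approx(44.0) and not partial

    def test_identical_triplet(self):
        mean, partial = average_comparisons([55.0, 55.0, 55.0])
        assert mean == 55.0 and not partial

    def test_partial_flagged(self):
        mean, partial = average_comparisons([40.0, 50.0])
        assert mean == 45.0 and partial

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_comparisons([])


class TestSmitModelEndToEnd:
    def test_null_comparison_near_100(self):
        cfg = designed_smit_panel(seed=2, reads_per_gene=5000,
                                  smit_conditions={"control": 1.0, "mock": 1.0})
        reads, truth = simulate_smit_reads(cfg)
        genes = (
            truth[["gene_id", "intron_length", "primer_offset"]]
            .drop_duplicates("gene_id").set_index("gene_id")
        )
        res = SmitModel(reads, genes).fit(bin_width=40)
        tbl = res.comparison_table
        assert len(tbl) == 3
        assert tbl["ctx_resistance"].mean() == pytest.approx(100.0, abs=5.0)

    def test_half_inhibition_near_50(self):
        cfg = designed_smit_panel(seed=2, reads_per_gene=5000,
                                  smit_conditions={"control": 1.0, "treated": 0.5})
        reads, truth = simulate_smit_reads(cfg)
        genes = (
            truth[["gene_id", "intron_length", "primer_offset"]]
            .drop_duplicates("gene_id").set_index("gene_id")
        )
        res = SmitModel(reads, genes).fit(bin_width=40)
        tbl = res.comparison_table
        assert tbl["ctx_resistance"].mean() == pytest.approx(50.0, abs=5.0)

    def test_summary_reports_comparisons(self):
        cfg = designed_smit_panel(seed=3, reads_per_gene=3000)
        reads, truth = simulate_smit_reads(cfg)
        genes = (
            truth[["gene_id", "intron_length", "primer_offset"]]
            .drop_duplicates("gene_id").set_index("gene_id")
        )
        res = SmitModel(reads, genes).fit(bin_width=40)
        assert "comparisons computed" in res.summary()
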