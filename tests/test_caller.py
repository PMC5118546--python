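"""Exact tests, BH correction, the consistency vote, ranking, and the full screen."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from coldscreen.caller import (
    CallerConfig,
    bh_adjust,
    call_modified,
    fisher_gene_test,
    per_sample_tests,
    run_screen,
    significant_direction_counts,
    top_induced,
)
from coldscreen.model import ColdscreenError, CountMatrix, GeneCall
from coldscreen.simulate import SimulationConfig, simulate_counts

from conftest import make_annotation, make_counts, make_samples


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: sum hypergeometric point probabilities <= observed.

    Enumerates every table with the observed margins; the minimum-likelihood
    two-sided definition with the same 1e-7 relative tie tolerance the
    implementation documents.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    n = r1 + r2
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


class TestFisher:
    def test_enumerated_example(self):
        # margins (10, 10, 10, 10): significant outcomes k in {0, 1, 9, 10}
        # sum C(10,k)C(10,10-k)/C(20,10) = (1 + 100 + 100 + 1)/184756
        assert fisher_gene_test(1, 9, 9, 1) == pytest.approx(202 / 184756, rel=1e-9)

    def test_identical_proportions(self):
        assert fisher_gene_test(5, 95, 5, 95) == 1.0

    def test_degenerate_margin_is_uninformative(self):
        assert fisher_gene_test(0, 10, 0, 10) == 1.0
        assert fisher_gene_test(0, 0, 3, 7) == 1.0

    def test_rejects_negative_cells(self):
        with pytest.raises(ColdscreenError, match="nonnegative"):
            fisher_gene_test(-1, 2, 3, 4)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_gene_test(a, b, c, d) == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
        )


def bh_step_up_by_hand(p):
    """Oracle: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1, in input order."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = [p[order[j]] * m / (j + 1) for j in range(m)]
    for j in range(m - 2, -1, -1):
        q_sorted[j] = min(q_sorted[j], q_sorted[j + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_singleton_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_propagate_top_rank(self):
        assert bh_adjust([0.05] * 6) == pytest.approx([0.05] * 6)

    def test_out_of_range_fatal(self):
        with pytest.raises(ColdscreenError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ColdscreenError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_hand_step_up_and_invariants(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(bh_step_up_by_hand(p), rel=1e-12, abs=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in idx])
        assert q_perm == pytest.approx([q[i] for i in idx], rel=1e-12, abs=1e-15)


CFG = CallerConfig()
FLIP = {"up": "down", "down": "up", "flat": "flat"}


class TestVote:
    @pytest.mark.parametrize(
        "q, dirs, expected",
        [
            # 3-of-4 significant, all same direction
            ([0.01, 0.02, 0.01, 0.20], ["up"] * 4, "up"),
            # opposite-direction veto: 3 up + 1 down, all significant
            ([0.01, 0.01, 0.01, 0.01], ["up", "up", "up", "down"], "unchanged"),
            # nothing significant
            ([0.20, 0.30, 0.40, 0.50], ["up"] * 4, "unchanged"),
            # only 2 of 4 significant
            ([0.01, 0.01, 0.20, 0.20], ["up"] * 4, "unchanged"),
            # symmetric downregulation
            ([0.01, 0.02, 0.01, 0.20], ["down"] * 4, "down"),
            # significant flat never counts as change
            ([0.001] * 4, ["flat"] * 4, "unchanged"),
            # 4-of-4 up
            ([0.001] * 4, ["up"] * 4, "up"),
            # 3 significant up, 4th significant flat: no veto, call up
            ([0.01, 0.01, 0.01, 0.01], ["up", "up", "up", "flat"], "up"),
        ],
    )
    def test_truth_table(self, q, dirs, expected):
        assert call_modified(q, dirs, CFG) == expected

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        st.lists(st.sampled_from(["up", "down", "flat"]), min_size=4, max_size=4),
    )
    def test_direction_negation_symmetry(self, q, dirs):
        call = call_modified(q, dirs, CFG)
        flipped = call_modified(q, [FLIP[d] for d in dirs], CFG)
        expected = FLIP[call] if call in FLIP else "unchanged"
        assert flipped == expected

    def test_length_mismatch_fatal(self):
        with pytest.raises(ColdscreenError):
            call_modified([0.01] * 3, ["up"] * 3, CFG)

    def test_counts_significant_by_direction(self):
        n_up, n_down = significant_direction_counts(
            [0.01, 0.01, 0.2, 0.04], ["up", "down", "up", "down"], CFG
        )
        assert (n_up, n_down) == (1, 2)


def experiment_from_gene_counts(gene_rows, sizes=None, n_ctrl=4, n_cold=4):
    """One transcript per gene; counts in (controls..., colds...) order."""
    ids = [f"ctrl_{i}" for i in range(1, n_ctrl + 1)] + [
        f"cold_{i}" for i in range(1, n_cold + 1)
    ]
    sizes = sizes or {s: 1_000_000 for s in ids}
    annotation = make_annotation({f"{g}.t": (g, 1000) for g in gene_rows})
    samples = make_samples(
        {s: ("control" if s.startswith("ctrl") else "cold") for s in ids}, sizes
    )
    counts = make_counts(annotation, samples, {f"{g}.t": v for g, v in gene_rows.items()})
    return counts, samples


class TestPerSampleTests:
    def test_identical_proportions_all_flat(self):
        counts, samples = experiment_from_gene_counts({"gA": [50] * 8, "gB": [10] * 8})
        p, dirs, pooled = per_sample_tests(
            counts.gene_counts().loc["gA"], counts.library_sizes(), samples, CFG
        )
        assert p == [1.0] * 4 and pooled == 1.0 and dirs == ["flat"] * 4

    def test_directions_up_against_pooled_control(self):
        # cold samples 50,55,48,52 per 1e6; pooled control 40 per 4e6
        counts, samples = experiment_from_gene_counts(
            {"gA": [10, 10, 10, 10, 50, 55, 48, 52]}
        )
        p, dirs, pooled = per_sample_tests(
            counts.gene_counts().loc["gA"], counts.library_sizes(), samples, CFG
        )
        assert dirs == ["up"] * 4
        assert all(0 < x <= 1 for x in p) and 0 < pooled <= 1

    def test_paired_mode_uses_one_control_each(self):
        # control proportions straddle the cold value: pooled says down,
        # pairing by index says up for the pairs with small controls
        counts, samples = experiment_from_gene_counts(
            {"gA": [10, 10, 1000, 1000, 20, 20, 20, 20]}
        )
        gene = counts.gene_counts().loc["gA"]
        sizes = counts.library_sizes()
        _, dirs_pooled, _ = per_sample_tests(gene, sizes, samples, CFG)
        cfg_paired = CallerConfig(pairing="paired_by_index")
        _, dirs_paired, _ = per_sample_tests(gene, sizes, samples, cfg_paired)
        assert dirs_pooled == ["down"] * 4  # 20/1e6 < 2040/4e6
        assert dirs_paired == ["up", "up", "down", "down"]

    def test_paired_mode_requires_equal_groups(self):
        counts, samples = experiment_from_gene_counts({"gA": [10] * 7}, n_ctrl=3, n_cold=4)
        with pytest.raises(ColdscreenError, match="equal group sizes"):
            per_sample_tests(
                counts.gene_counts().loc["gA"],
                counts.library_sizes(),
                samples,
                CallerConfig(pairing="paired_by_index"),
            )


def _up_call(gene_id, fc, pooled_p=0.001):
    return GeneCall(
        gene_id=gene_id,
        fold_change=fc,
        pooled_p=pooled_p,
        per_sample_p=(0.001,) * 4,
        per_sample_q=(0.004,) * 4,
        per_sample_direction=("up",) * 4,
        n_significant_up=4,
        n_significant_down=0,
        call="up",
    )


class TestTopInduced:
    def test_top_decile_of_twenty(self):
        calls = [_up_call(f"g{i:02d}", fc=float(i)) for i in range(1, 21)]
        assert top_induced(calls, CFG) == ["g20", "g19"]

    def test_empty_when_nothing_up(self):
        assert top_induced([], CFG) == []

    def test_tie_broken_by_pooled_p(self):
        calls = [
            _up_call("g_late", 4.5, pooled_p=0.01),
            _up_call("g_early", 4.5, pooled_p=0.001),
            *[_up_call(f"g{i}", 1.5) for i in range(18)],
        ]
        top = top_induced(calls, CFG)
        assert top == ["g_early", "g_late"]

    def test_infinite_fold_ranks_first(self):
        calls = [_up_call("g_inf", math.inf), _up_call("g_big", 500.0)]
        assert top_induced(calls, CallerConfig(top_fraction=0.5)) == ["g_inf"]


class TestRunScreen:
    def test_overwhelming_induction_called_up(self):
        # one gene 10x in every cold sample at high expression, others flat
        rows = {"g_hot": [1000] * 4 + [10000] * 4}
        rows.update({f"g_bg{i}": [500] * 8 for i in range(20)})
        counts, _ = experiment_from_gene_counts(rows)
        calls, summary = run_screen(counts)
        hot = next(c for c in calls if c.gene_id == "g_hot")
        assert hot.call == "up"
        assert hot.fold_change == pytest.approx(10.0, rel=1e-9)
        assert summary.n_up >= 1 and summary.n_modified == summary.n_up + summary.n_down

    def test_empty_expressed_set(self):
        counts, _ = experiment_from_gene_counts({"g0": [0] * 8})
        calls, summary = run_screen(counts)
        assert calls == []
        assert summary.n_expressed == 0 and summary.n_modified == 0
        assert summary.pct_modified == 0.0

    def test_cold_sample_count_checked_against_config(self):
        counts, _ = experiment_from_gene_counts({"g0": [5] * 6}, n_ctrl=3, n_cold=3)
        with pytest.raises(ColdscreenError, match="cold samples"):
            run_screen(counts, CallerConfig(n_cold_samples=4))
        calls, _ = run_screen(counts, CallerConfig(n_cold_samples=3, min_consistent=3))
        assert len(calls) == 1

    def test_bh_family_literal_mode_runs(self):
        rows = {f"g{i}": [50 + i] * 8 for i in range(5)}
        counts, _ = experiment_from_gene_counts(rows)
        calls, _ = run_screen(counts, CallerConfig(bh_family="per_gene_across_samples"))
        for c in calls:
            assert all(q >= p - 1e-15 for p, q in zip(c.per_sample_p, c.per_sample_q))

    def test_null_calibration_under_binomial_sampling(self):
        # with no biological overdispersion the Fisher sampling model is exact:
        # the modified-call rate on pure-null data stays below alpha
        rates = []
        for seed in range(1, 11):
            counts, *_ = simulate_counts(
                SimulationConfig(n_genes=150, nb_dispersion=0.0, seed=seed)
            )
            _, summary = run_screen(counts)
            rates.append(summary.n_modified / max(summary.n_expressed, 1))
        assert max(rates) <= CFG.alpha


class TestCallerConfig:
    def test_validation(self):
        with pytest.raises(ColdscreenError):
            CallerConfig(alpha=1.5)
        with pytest.raises(ColdscreenError):
            CallerConfig(min_consistent=5, n_cold_samples=4)
        with pytest.raises(ColdscreenError):
            CallerConfig(bh_family="bonferroni")
        with pytest.raises(ColdscreenError):
            CallerConfig(top_fraction=0.0)

    def test_text_round_trip(self):
        cfg = CallerConfig(alpha=0.01, min_consistent=4, top_fraction=0.25)
        assert CallerConfig.from_text(cfg.to_text()) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ColdscreenError, match="unknown config key"):
            CallerConfig.from_text("gamma = 1\n")
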