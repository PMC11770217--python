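"""Enrichment statistics: percent-difference formula, BH-FDR step-up,
rank concordance, and the per-trait pipeline composition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from overlapenrich.enrichment import (
    bh_fdr,
    enrichment_percent,
    finalize_results,
    rank_concordance,
    read_sldsc_results,
    results_to_frame,
    run_trait,
    write_results_tsv,
)
from overlapenrich.intervals import GenomeDefinition, IntervalSet, merge
from overlapenrich.mapping import ElementSet


class TestEnrichmentPercent:
    @pytest.mark.parametrize(
        "observed,bg,expected",
        [(2.0, [1.0], 100.0), (1.0, [1.0], 0.0), (0.5, [1.0], -50.0)],
    )
    def test_percent_difference_formula(self, observed, bg, expected):
        assert enrichment_percent(observed, bg) == expected

    def test_uses_background_mean(self):
        assert enrichment_percent(3.0, [1.0, 2.0, 3.0]) == 50.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(0.5, 2.0, size=100)
        obs = 1.7
        base = enrichment_percent(obs, bg)
        for c in (0.01, 3.0, 1e6):
            assert enrichment_percent(obs * c, bg * c) == pytest.approx(base)

    def test_zero_background_flagged(self):
        with pytest.raises(ValueError, match="background mean"):
            enrichment_percent(1.0, [0.0, 0.0])


def brute_bh(pvals):
    """Step-up BH by the textbook definition (independent implementation)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_fdr(p), brute_bh(p))

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


def results_table(values, method="m", annot="a1"):
    n = len(values)
    return pd.DataFrame(
        {
            "trait_id": [f"t{i}" for i in range(n)],
            "annot_id": annot,
            "enrichment": values,
        }
    )


class TestRankConcordance:
    def test_identical_rankings_degenerate(self):
        a = results_table([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = results_table([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        res = rank_concordance(a, b)
        assert res.degenerate and res.pvalue == 1.0 and res.n_pairs == 6

    def test_full_reversal_gives_symmetric_differences(self):
        """A perfectly reversed ranking produces rank differences symmetric
        about zero, so the two-sided signed-rank test cannot reject: W+ equals
        W- and p = 1."""
        values = list(np.linspace(1.0, 5.0, 20))
        a = results_table(values)
        b = results_table(values[::-1])
        res = rank_concordance(a, b)
        assert not res.degenerate
        assert res.statistic == pytest.approx(105.0)  # n(n+1)/4 with n=20
        assert res.pvalue == pytest.approx(1.0)

    def test_asymmetric_rank_shift_detected(self):
        """A cyclic shift moves one trait far down and everything else up one
        rank; the skewed differences are strongly significant."""
        values = list(np.linspace(1.0, 5.0, 20))
        a = results_table(values)
        b = results_table(values[1:] + values[:1])  # cyclic permutation
        res = rank_concordance(a, b)
        assert res.pvalue < 0.05 and not res.degenerate

    def test_reversed_ranking_matches_normal_approx_oracle(self):
        """For a full reversal at n=20, every pair contributes a nonzero rank
        difference with symmetric signs; the test statistic matches the
        classical signed-rank computation done by hand with scipy rankdata."""
        values = list(np.linspace(1.0, 5.0, 20))
        a, b = results_table(values), results_table(values[::-1])
        res = rank_concordance(a, b)
        diffs = stats.rankdata(values) - stats.rankdata(values[::-1])
        nz = diffs[diffs != 0]
        ranks = stats.rankdata(np.abs(nz))
        w_plus = ranks[nz > 0].sum()
        w_minus = ranks[nz < 0].sum()
        assert res.statistic == pytest.approx(min(w_plus, w_minus))

    def test_disjoint_keys_error(self):
        a = results_table([1, 2, 3])
        b = results_table([1, 2, 3]).assign(trait_id=["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="no paired rows"):
            rank_concordance(a, b)

    def test_symmetric_two_sided_p(self):
        rng = np.random.default_rng(2)
        a = results_table(rng.normal(size=15))
        b = results_table(rng.normal(size=15))
        assert rank_concordance(a, b).pvalue == pytest.approx(
            rank_concordance(b, a).pvalue
        )

    def test_underpowered_warns(self):
        a = results_table([1.0, 2.0, 3.0])
        b = results_table([3.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="underpowered"):
            rank_concordance(a, b)

    def test_duplicate_keys_rejected(self):
        a = results_table([1.0, 2.0])
        dup = pd.concat([a, a])
        with pytest.raises(ValueError, match="duplicate"):
            rank_concordance(dup, a)


def element_set_on(genome, lengths, gap, trait="t"):
    rows, pos = [], 0
    for i, L in enumerate(lengths):
        rows.append(("chr1", pos, pos + L, f"g{i}"))
        pos += L + gap
    return ElementSet(
        trait_id=trait,
        elements=IntervalSet.from_intervals(rows, build_label=genome.build_label),
        n_input_hits=len(lengths),
    )


class TestRunTrait:
    def test_whole_genome_annotation_gives_zero_enrichment(self):
        genome = GenomeDefinition("toy", {"chr1": 1_000_000})
        es = element_set_on(genome, [1000] * 20, 5000)
        annot = merge(
            IntervalSet.from_intervals([("chr1", 0, 1_000_000)], build_label="toy")
        )
        res = run_trait(es, annot, genome, n_reps=100, rng_seed=0)
        # observed = background = every element overlaps
        assert res.observed_count == 20
        assert res.I_percent == pytest.approx(0.0, abs=1e-9)
        assert res.fit_note  # degenerate background flagged

    def test_deterministic_under_seed(self):
        genome = GenomeDefinition("toy", {"chr1": 1_000_000})
        es = element_set_on(genome, [500, 800, 1200] * 10, 20_000)
        annot = merge(
            IntervalSet.from_intervals(
                [("chr1", i * 30_000, i * 30_000 + 3000) for i in range(30)],
                build_label="toy",
            )
        )
        r1 = run_trait(es, annot, genome, n_reps=200, rng_seed=5)
        r2 = run_trait(es, annot, genome, n_reps=200, rng_seed=5)
        assert (r1.observed, r1.bg_mean, r1.I_percent, r1.p) == (
            r2.observed,
            r2.bg_mean,
            r2.I_percent,
            r2.p,
        )

    def test_finalize_fills_q_per_family(self):
        genome = GenomeDefinition("toy", {"chr1": 1_000_000})
        annot = merge(
            IntervalSet.from_intervals(
                [("chr1", i * 30_000, i * 30_000 + 3000) for i in range(30)],
                build_label="toy",
            )
        )
        results = [
            run_trait(
                element_set_on(genome, [600] * 15, 25_000, trait=f"t{i}"),
                annot,
                genome,
                n_reps=100,
                rng_seed=i,
            )
            for i in range(4)
        ]
        finalize_results(results)
        assert all(r.q is not None and r.q >= r.p - 1e-12 for r in results)
        assert np.allclose([r.q for r in results], bh_fdr([r.p for r in results]))


class TestResultsIO:
    def test_write_fixed_format(self, tmp_path):
        genome = GenomeDefinition("toy", {"chr1": 1_000_000})
        es = element_set_on(genome, [500] * 10, 50_000)
        annot = merge(
            IntervalSet.from_intervals(
                [("chr1", i * 40_000, i * 40_000 + 4000) for i in range(20)],
                build_label="toy",
            )
        )
        res = finalize_results([run_trait(es, annot, genome, n_reps=100, rng_seed=0)])
        out = tmp_path / "results.tsv"
        write_results_tsv(res, out, header_lines=["seed=0"])
        lines = out.read_text().splitlines()
        assert lines[0] == "# seed=0"
        assert lines[1].split("\t")[0] == "trait_id"
        assert len(lines) == 3

    def test_sldsc_results_adapter(self, tmp_path):
        p = tmp_path / "trait.results"
        p.write_text(
            "Category Prop._SNPs Prop._h2 Enrichment Enrichment_std_error Enrichment_p\n"
            "har_annotL2_1 0.01 0.05 5.0 1.2 0.003\n"
            "baseL2_1 0.5 0.5 1.0 0.1 0.9\n"
        )
        df = read_sldsc_results(p, trait_id="height")
        assert list(df["annot_id"]) == ["har_annot", "base"]
        assert df.loc[0, "enrichment"] == 5.0 and df.loc[0, "se"] == 1.2
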