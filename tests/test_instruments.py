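"""Instrument selection and harmonization: significance/F filters, greedy
clumping against a brute-force oracle, allele alignment including
palindromes, and the merge-then-clump multivariable union."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netmr import (
    EmptyInstrumentSet,
    InstrumentConfig,
    clump,
    harmonize,
    mvmr_instrument_union,
    select_instruments,
)

from conftest import block_ld, identity_ld, make_sumstats


def brute_force_clump(table, ld, r2, window_bp):
    """Independent greedy reference: repeatedly promote the best remaining
    variant (p, then chr, pos, id) and discard its LD partners in window."""
    remaining = table.sort_values(["pval", "chr", "pos", "variant_id"]).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["variant_id"])
        survivors = []
        for cand in remaining:
            same_chr = cand["chr"] == index["chr"]
            close = abs(cand["pos"] - index["pos"]) <= window_bp
            if same_chr and close and ld.r2(index["variant_id"], cand["variant_id"]) >= r2:
                continue
            survivors.append(cand)
        remaining = survivors
    return sorted(kept)


class TestClump:
    def test_independent_variants_all_retained(self):
        t = make_sumstats(
            [(f"rs{i}", "1", 1000 * i, "A", "G", 0.3, 0.1, 0.01, 1e-9 * (i + 1), 1000)
             for i in range(6)]
        )
        out = clump(t, identity_ld(t), r2=0.001, window_bp=10_000_000)
        assert len(out) == 6

    def test_perfect_ld_keeps_smaller_p(self):
        t = make_sumstats(
            [
                ("rs_best", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                ("rs_worse", "1", 2000, "T", "C", 0.3, 0.1, 0.01, 1e-9, 1000),
            ]
        )
        ld = identity_ld(t)
        ld.r[0, 1] = ld.r[1, 0] = 1.0
        out = clump(t, ld, r2=0.5, window_bp=10_000_000)
        assert list(out["variant_id"]) == ["rs_best"]
        assert out.attrs["clumped_away"] == [("rs_worse", "rs_best")]

    def test_matches_brute_force_oracle_on_block_fixture(self):
        rng = np.random.default_rng(12)
        t = make_sumstats(
            [(f"rs{i:02d}", "1", 50_000 * i, "A", "G", 0.3, 0.1, 0.01,
              float(rng.uniform(1e-12, 1e-6)), 1000) for i in range(12)]
        )
        ld = block_ld(t, rho=0.9, block_size=4)
        got = clump(t, ld, r2=0.1, window_bp=10_000_000)
        assert sorted(got["variant_id"]) == brute_force_clump(t, ld, 0.1, 10_000_000)
        assert len(got) == 3  # one index per LD block

    def test_window_limits_clumping_reach(self):
        # same chromosome, r2 above threshold, but outside the window
        t = make_sumstats(
            [
                ("rs_a", "1", 1_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                ("rs_b", "1", 60_000_000, "T", "C", 0.3, 0.1, 0.01, 1e-9, 1000),
            ]
        )
        ld = identity_ld(t)
        ld.r[0, 1] = ld.r[1, 0] = 0.9
        out = clump(t, ld, r2=0.001, window_bp=10_000_000)
        assert len(out) == 2

    def test_missing_ld_pair_within_window_errors(self):
        t = make_sumstats(
            [
                ("rs_a", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                ("rs_unknown", "1", 2000, "T", "C", 0.3, 0.1, 0.01, 1e-9, 1000),
            ]
        )
        ld = identity_ld(t.iloc[:1])
        with pytest.raises(KeyError, match="rs_unknown"):
            clump(t, ld, r2=0.001, window_bp=10_000_000)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_greedy_maximality_property(self, seed):
        """Retained variants are pairwise below the r2 threshold within the
        window, and every removed variant is claimed by a retained one."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 11))
        t = make_sumstats(
            [(f"rs{i}", "1", int(rng.integers(1, 5_000_000)), "A", "G", 0.3, 0.1, 0.01,
              float(rng.uniform(1e-10, 1e-4)), 1000) for i in range(m)]
        )
        ld = block_ld(t, rho=float(rng.uniform(0.2, 0.95)), block_size=3)
        r2, window = 0.1, 2_000_000
        out = clump(t, ld, r2=r2, window_bp=window)
        kept = out.set_index("variant_id")
        for i, a in enumerate(kept.index):
            for b in kept.index[i + 1:]:
                within = abs(kept.loc[a, "pos"] - kept.loc[b, "pos"]) <= window
                if within:
                    assert ld.r2(a, b) < r2
        removed = {v for v, _ in out.attrs["clumped_away"]}
        assert removed | set(kept.index) == set(t["variant_id"])


class TestSelectInstruments:
    @pytest.fixture
    def config(self):
        return InstrumentConfig()

    def test_f_statistic_screen(self, config):
        t = make_sumstats(
            [
                ("rs_strong", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),  # F=100
                ("rs_weak", "2", 1000, "T", "C", 0.3, 0.02, 0.01, 1e-9, 1000),  # F=4
            ]
        )
        out = select_instruments(t, config, identity_ld(t))
        assert list(out["variant_id"]) == ["rs_strong"]
        assert ("rs_weak", "f_statistic", "weak_instrument") in out.attrs["exclusions"]

    def test_null_variants_do_not_survive_genome_wide_threshold(self, config):
        rng = np.random.default_rng(7)
        pvals = rng.uniform(size=50)  # true beta 0 -> uniform p
        t = make_sumstats(
            [(f"rs{i}", "1", 1000 * i, "A", "G", 0.3, 0.001, 0.01, float(pvals[i]), 1000)
             for i in range(50)]
        )
        with pytest.raises(EmptyInstrumentSet, match="significance"):
            select_instruments(t, config, identity_ld(t))

    def test_low_maf_excluded(self, config):
        t = make_sumstats(
            [
                ("rs_ok", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                ("rs_rare", "1", 900_000_000, "T", "C", 0.005, 0.1, 0.01, 1e-10, 1000),
            ]
        )
        ld = identity_ld(t)
        out = select_instruments(t, config, ld)
        assert ("rs_rare", "filters", "low_maf") in out.attrs["exclusions"]

    def test_every_variant_accounted_for(self, default_tables):
        tables, ld, cfg = default_tables
        out = select_instruments(tables["education"], InstrumentConfig(), ld)
        excluded = {v for v, _, _ in out.attrs["exclusions"]}
        assert excluded | set(out["variant_id"]) == set(tables["education"]["variant_id"])
        assert len(excluded) + len(out) == len(tables["education"])


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, exp_eaf=0.3, out_eaf=0.3, out_beta=0.3):
        exp = make_sumstats([("rs1", "1", 100, *exp_alleles, exp_eaf, 0.1, 0.01, 1e-10, 1000)])
        out = make_sumstats([("rs1", "1", 100, *out_alleles, out_eaf, out_beta, 0.02, 0.5, 1000)])
        return exp, out

    def test_same_alleles_unchanged(self):
        exp, out = self._pair(("A", "G"), ("A", "G"))
        h = harmonize(exp, out)
        assert h.beta_outcome[0] == pytest.approx(0.3)

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._pair(("A", "G"), ("G", "A"))
        h = harmonize(exp, out)
        assert h.beta_outcome[0] == pytest.approx(-0.3)

    def test_strand_flip_resolved(self):
        # T/C on the other strand reads A/G; effect direction is preserved
        exp, out = self._pair(("A", "G"), ("T", "C"))
        h = harmonize(exp, out)
        assert h.beta_outcome[0] == pytest.approx(0.3)

    def test_ambiguous_palindrome_excluded(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), exp_eaf=0.45, out_eaf=0.45)
        extra_exp = make_sumstats([("rs2", "1", 200, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        extra_out = make_sumstats([("rs2", "1", 200, "A", "G", 0.3, 0.2, 0.02, 0.5, 1000)])
        h = harmonize(pd.concat([exp, extra_exp]), pd.concat([out, extra_out]))
        assert ("rs1", "ambiguous_palindrome") in h.exclusions
        assert h.variant_ids == ["rs2"]

    def test_low_maf_palindrome_aligned_by_frequency(self):
        # EAFs on opposite sides of 0.5 -> the outcome allele is flipped
        exp, out = self._pair(("A", "T"), ("A", "T"), exp_eaf=0.10, out_eaf=0.88)
        h = harmonize(exp, out)
        assert h.beta_outcome[0] == pytest.approx(-0.3)
        same_side, _ = self._pair(("A", "T"), ("A", "T"), exp_eaf=0.10, out_eaf=0.12)
        h2 = harmonize(same_side, _)
        assert h2.beta_outcome[0] == pytest.approx(0.3)

    def test_irreconcilable_alleles_excluded(self):
        exp, out = self._pair(("A", "G"), ("A", "C"))
        extra_exp = make_sumstats([("rs2", "1", 200, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        extra_out = make_sumstats([("rs2", "1", 200, "A", "G", 0.3, 0.2, 0.02, 0.5, 1000)])
        h = harmonize(pd.concat([exp, extra_exp]), pd.concat([out, extra_out]))
        assert ("rs1", "allele_mismatch") in h.exclusions

    def test_zero_shared_variants_errors(self):
        exp = make_sumstats([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        out = make_sumstats([("rs9", "1", 900, "A", "G", 0.3, 0.3, 0.02, 0.5, 1000)])
        with pytest.raises(ValueError, match="zero shared"):
            harmonize(exp, out)

    def test_idempotence(self, default_tables):
        tables, ld, cfg = default_tables
        exp = tables["education"].head(30)
        out = tables["lower_respiratory"]
        h1 = harmonize(exp, out)
        h2 = harmonize(h1.exposure_tables[0], h1.outcome_table)
        np.testing.assert_allclose(h2.beta_outcome, h1.beta_outcome)
        np.testing.assert_allclose(h2.beta_exposures, h1.beta_exposures)
        assert h2.variant_ids == h1.variant_ids

    def test_multi_exposure_accounting(self, default_tables):
        tables, ld, cfg = default_tables
        exp1 = tables["smoking"].head(40)
        h = harmonize(
            [exp1, tables["bmi"], tables["education"]],
            tables["lower_respiratory"],
            exposure_names=["smoking", "bmi", "education"],
        )
        assert h.k == 3
        accounted = set(h.variant_ids) | {v for v, _ in h.exclusions}
        assert accounted == set(exp1["variant_id"])


class TestMvmrUnion:
    def test_disjoint_significant_sets_fully_retained(self):
        t1 = make_sumstats(
            [("rs_a", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
             ("rs_null1", "1", 2000, "A", "G", 0.3, 0.0, 0.01, 0.9, 1000)]
        )
        t2 = make_sumstats(
            [("rs_b", "2", 1000, "T", "C", 0.3, 0.1, 0.01, 1e-12, 1000),
             ("rs_null2", "2", 2000, "A", "G", 0.3, 0.0, 0.01, 0.8, 1000)]
        )
        all_ids = pd.concat([t1, t2])
        out = mvmr_instrument_union([t1, t2], InstrumentConfig(), identity_ld(all_ids))
        assert sorted(out["variant_id"]) == ["rs_a", "rs_b"]

    def test_shared_variant_uses_smallest_p_for_ranking(self):
        t1 = make_sumstats([("rs_x", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
        t2 = make_sumstats([("rs_x", "1", 1000, "A", "G", 0.3, 0.12, 0.01, 1e-12, 1000)])
        out = mvmr_instrument_union([t1, t2], InstrumentConfig(), identity_ld(t1))
        assert out.loc[0, "pval"] == pytest.approx(1e-12)

    def test_matches_literal_two_step_oracle(self):
        """Union of per-trait significant variants, min-p per variant,
        one clumping pass — executed independently in the test."""
        rng = np.random.default_rng(5)
        rows1, rows2 = [], []
        for i in range(8):
            p1 = float(rng.uniform(1e-12, 1e-6)) if i < 5 else float(rng.uniform(0.1, 1))
            p2 = float(rng.uniform(1e-12, 1e-6)) if i > 2 else float(rng.uniform(0.1, 1))
            rows1.append((f"rs{i}", "1", 100_000 * i, "A", "G", 0.3, 0.1, 0.01, p1, 1000))
            rows2.append((f"rs{i}", "1", 100_000 * i, "A", "G", 0.3, 0.1, 0.01, p2, 1000))
        t1, t2 = make_sumstats(rows1), make_sumstats(rows2)
        ld = block_ld(t1, rho=0.95, block_size=4)
        cfg = InstrumentConfig(p_threshold=1e-5, clump_r2=0.1)
        got = mvmr_instrument_union([t1, t2], cfg, ld)

        # oracle: literal re-execution of the two-step procedure
        merged = {}
        for t in (t1, t2):
            for _, row in t[t["pval"] < 1e-5].iterrows():
                v = row["variant_id"]
                if v not in merged or row["pval"] < merged[v]["pval"]:
                    merged[v] = row
        union = pd.DataFrame(list(merged.values()))
        expected = brute_force_clump(union, ld, 0.1, cfg.clump_window_bp)
        assert sorted(got["variant_id"]) == expected

    def test_requires_two_tables(self):
        t1 = make_sumstats([("rs_a", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        with pytest.raises(ValueError, match="at least two"):
            mvmr_instrument_union([t1], InstrumentConfig(), identity_ld(t1))
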