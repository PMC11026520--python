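"""Phenotype harmonization rules, the mass-univariate screen, mode retention."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastcov.phewas import (
    PhenotypeTable,
    PhewasResult,
    harmonize,
    manhattan_table,
    screen,
    select_modes,
)


def _table(n=600, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        {
            "phen_num": rng.standard_normal(n),
            "phen_bin": rng.integers(0, 2, n).astype(float),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    dtypes = {"phen_num": "numerical", "phen_bin": "binary"}
    cats = {"phen_num": "lifestyle", "phen_bin": "cognitive"}
    if extra:
        for name, (col, dt) in extra.items():
            values[name] = col
            dtypes[name] = dt
            cats[name] = "other"
    return PhenotypeTable(values=values, datatypes=dtypes, categories=cats)


class TestHarmonize:
    def test_unordered_expands_to_per_level_binaries(self):
        n = 600
        rng = np.random.default_rng(1)
        levels = rng.integers(0, 3, n).astype(float)
        raw = _table(n, extra={"phen_cat": (levels, "categorical-unordered")})
        out = harmonize(raw)
        expanded = [c for c in out.columns if c.startswith("phen_cat__")]
        assert len(expanded) == 3
        assert all(out.datatypes[c] == "binary" for c in expanded)
        # one-hot rows sum to 1 where non-missing
        sums = out.values[expanded].sum(axis=1)
        assert (sums == 1.0).all()
        assert not any(t == "categorical-unordered" for t in out.datatypes.values())

    def test_missingness_boundary_499_dropped_500_kept(self):
        n = 600
        col499 = np.r_[np.full(101, np.nan), np.zeros(499) + np.random.default_rng(2).standard_normal(499)]
        col500 = np.r_[np.full(100, np.nan), np.random.default_rng(3).standard_normal(500)]
        raw = _table(
            n,
            extra={
                "phen_499": (col499, "numerical"),
                "phen_500": (col500, "numerical"),
            },
        )
        out = harmonize(raw)
        assert "phen_499" not in out.columns
        assert "phen_500" in out.columns
        reasons = {d["column"]: d["reason"] for d in out.drop_log}
        assert "fewer_than_500" in reasons["phen_499"]

    def test_duplicate_dropped_first_kept(self):
        n = 600
        rng = np.random.default_rng(4)
        base = rng.standard_normal(n)
        raw = _table(
            n,
            extra={
                "phen_a": (base, "numerical"),
                "phen_b": (base.copy(), "numerical"),
            },
        )
        out = harmonize(raw)
        assert "phen_a" in out.columns and "phen_b" not in out.columns

    def test_idempotent(self):
        n = 600
        rng = np.random.default_rng(5)
        raw = _table(
            n,
            extra={"phen_cat": (rng.integers(0, 4, n).astype(float), "categorical-unordered")},
        )
        once = harmonize(raw)
        twice = harmonize(once)
        assert once.columns == twice.columns
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_untagged_column_rejected(self):
        values = pd.DataFrame({"phen_x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="untagged"):
            PhenotypeTable(values=values, datatypes={})


class TestScreen:
    def test_bonferroni_threshold_printed_value(self):
        """m=977 at alpha=0.05 gives the canonical 5.11e-5 threshold."""
        res = PhewasResult(table=pd.DataFrame({"p": []}), alpha=0.05, fdr_q=0.05, m=977)
        assert res.bonferroni_threshold == pytest.approx(5.11e-5, abs=1e-7)

    def test_exact_copy_flagged_by_both(self):
        n = 600
        rng = np.random.default_rng(6)
        score = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
        raw = _table(n, extra={"phen_copy": (score.to_numpy(), "numerical")})
        res = screen(score, raw)
        row = res.table.set_index("phenotype").loc["phen_copy"]
        assert row["r"] == pytest.approx(1.0)
        assert row["bonferroni_significant"] and row["fdr_significant"]

    def test_bh_step_up_hand_case(self):
        """p = [0.001, 0.02, 0.03, 0.8] at q=0.05 rejects the first three."""
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(
            [0.001, 0.02, 0.03, 0.8], alpha=0.05, method="fdr_bh"
        )
        assert reject.tolist() == [True, True, True, False]

    def test_pairwise_complete_and_skip_rule(self):
        n = 600
        rng = np.random.default_rng(7)
        sparse = np.full(n, np.nan)
        sparse[:2] = [1.0, 2.0]  # only 2 complete pairs -> skipped
        half = rng.standard_normal(n)
        half[: n // 2] = np.nan
        raw = _table(n, extra={"phen_2": (sparse, "numerical"), "phen_half": (half, "numerical")})
        score = pd.Series(rng.standard_normal(n), index=raw.values.index)
        with pytest.warns(UserWarning, match="skipped"):
            res = screen(score, raw)
        assert "phen_2" in res.skipped
        row = res.table.set_index("phenotype").loc["phen_half"]
        assert row["n"] == n // 2

    def test_p_matches_t_transform(self):
        n = 200
        rng = np.random.default_rng(8)
        raw = _table(n, seed=8)
        score = pd.Series(rng.standard_normal(n), index=raw.values.index)
        res = screen(score, raw)
        row = res.table.set_index("phenotype").loc["phen_num"]
        r = row["r"]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_affine_invariance_of_scores(self):
        n = 400
        rng = np.random.default_rng(9)
        raw = _table(n, seed=9)
        score = pd.Series(rng.standard_normal(n), index=raw.values.index)
        r1 = screen(score, raw).table
        r2 = screen(3.7 * score - 11.0, raw).table
        np.testing.assert_allclose(r1["r"], r2["r"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)

    def test_bonferroni_fwer_controlled_under_null(self):
        """Family-wise error stays near alpha over independent replicates."""
        rng = np.random.default_rng(10)
        n, m, reps = 150, 40, 200
        fw_errors = 0
        for _ in range(reps):
            values = pd.DataFrame(
                rng.standard_normal((n, m)),
                columns=[f"phen_{j}" for j in range(m)],
            )
            raw = PhenotypeTable(
                values=values, datatypes={c: "numerical" for c in values.columns}
            )
            score = pd.Series(rng.standard_normal(n), index=values.index)
            res = screen(score, raw)
            fw_errors += res.n_bonferroni > 0
        # binomial 99% upper bound around alpha=0.05
        assert fw_errors / reps < 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / reps)


class TestSelectModes:
    def test_six_to_three_reduction_by_fdr_gate(self):
        """All six modes permutation-significant but FDR hits only in the first
        three: retention keeps exactly those."""
        perm_p = np.full(6, 0.001)
        results = []
        for l in range(6):
            n_hits = 3 if l < 3 else 0
            table = pd.DataFrame(
                {
                    "p": np.linspace(1e-6, 0.9, 10),
                    "fdr_significant": [True] * n_hits + [False] * (10 - n_hits),
                    "bonferroni_significant": [False] * 10,
                }
            )
            results.append(PhewasResult(table=table, alpha=0.05, fdr_q=0.05, m=10))
        assert select_modes(perm_p, results) == [0, 1, 2]

    def test_permutation_gate(self):
        perm_p = np.array([0.001, 0.5])
        table = pd.DataFrame({"p": [1e-6], "fdr_significant": [True], "bonferroni_significant": [True]})
        results = [PhewasResult(table=table, alpha=0.05, fdr_q=0.05, m=1)] * 2
        assert select_modes(perm_p, results) == [0]

    def test_empty_retention_allowed(self):
        table = pd.DataFrame({"p": [0.9], "fdr_significant": [False], "bonferroni_significant": [False]})
        results = [PhewasResult(table=table, alpha=0.05, fdr_q=0.05, m=1)]
        with pytest.warns(UserWarning, match="no mode"):
            assert select_modes(np.array([0.001]), results) == []


class TestManhattan:
    def test_neg_log10_and_thresholds(self):
        table = pd.DataFrame(
            {
                "phenotype": ["a", "b"],
                "category": ["c1", "c2"],
                "r": [0.5, 0.01],
                "p": [5.11e-5, 0.8],
                "n": [100, 100],
                "bonferroni_significant": [True, False],
                "fdr_significant": [True, False],
            }
        )
        res = PhewasResult(table=table, alpha=0.05, fdr_q=0.05, m=977)
        t = manhattan_table(res)
        assert t.set_index("phenotype").loc["a", "neg_log10_p"] == pytest.approx(4.2916, abs=1e-3)
        assert t["bonferroni_line"].iloc[0] == pytest.approx(-np.log10(0.05 / 977))
        assert t["fdr_line_empirical"].iloc[0] == pytest.approx(-np.log10(5.11e-5))

    def test_category_tags_preserved(self):
        n = 600
        raw = _table(n)
        score = pd.Series(np.random.default_rng(11).standard_normal(n), index=raw.values.index)
        res = screen(score, raw)
        t = manhattan_table(res)
        assert dict(zip(t["phenotype"], t["category"])) == {
            "phen_num": "lifestyle",
            "phen_bin": "cognitive",
        }
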