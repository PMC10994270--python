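from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from morphoscreen.enrich import (
    GMTParseError,
    filter_by_expression,
    hypergeometric_enrichment,
    read_gene_list,
    read_gmt,
)


def _exact_upper_tail(N, K, n, x):
    """Independent oracle: exact rational hypergeometric P(X >= x)."""
    total = Fraction(0)
    for i in range(x, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def _bh_stepup(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestReadGMT:
    def test_two_line_fixture(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("SET_A\tdesc a\tTP53\tBRCA1\nSET_B\tdesc b\tEGFR\tkras\tEGFR\n")
        coll = read_gmt(path)
        assert len(coll) == 2
        assert coll.sets["SET_A"] == {"TP53", "BRCA1"}
        assert coll.sets["SET_B"] == {"EGFR", "KRAS"}  # dedup + uppercase

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SET_A\tdesc\tTP53\nBROKEN\tonly-two-fields\n")
        with pytest.raises(GMTParseError, match=":2:"):
            read_gmt(path)

    def test_packaged_fixture_collection_is_valid(self):
        from morphoscreen.pipeline import _packaged

        coll = read_gmt(_packaged("genesets.gmt"))
        assert len(coll) >= 10
        assert all(len(s) > 0 for s in coll.sets.values())
        expressed = read_gene_list(_packaged("expressed_genes.txt"))
        assert len(expressed) > 100


class TestFilterByExpression:
    def test_intersection(self):
        assert filter_by_expression({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}

    def test_superset_background_is_identity(self):
        assert filter_by_expression({"A", "B"}, {"A", "B", "C"}) == {"A", "B"}

    def test_case_insensitive(self):
        assert filter_by_expression({"sorl1"}, {"SORL1"}) == {"SORL1"}

    def test_empty_expressed_list_rejected(self):
        with pytest.raises(ValueError):
            filter_by_expression({"A"}, set())


def _toy_collection(sets):
    import morphoscreen.enrich as e

    return e.GeneSetCollection(
        sets={k: frozenset(v) for k, v in sets.items()},
        descriptions={k: "" for k in sets},
    )


class TestHypergeometricEnrichment:
    def test_closed_form_full_overlap(self):
        """N=20, K=5, n=5, x=5: p = 1/C(20,5) = 1/15504."""
        bg = [f"G{i}" for i in range(20)]
        coll = _toy_collection({"S": bg[:5]})
        out = hypergeometric_enrichment(bg[:5], coll, bg)
        assert out.loc[0, "x"] == 5
        assert out.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_overlap_equal_to_expectation_gives_zero_strength(self):
        bg = [f"G{i}" for i in range(100)]
        coll = _toy_collection({"S": bg[:10]})
        query = bg[9:19]  # x=1, E = 10*10/100 = 1
        out = hypergeometric_enrichment(query, coll, bg)
        assert out.loc[0, "x"] == 1
        assert out.loc[0, "strength"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_overlap_gives_p_one_and_undefined_strength(self):
        bg = [f"G{i}" for i in range(30)]
        coll = _toy_collection({"S": bg[:5]})
        out = hypergeometric_enrichment(bg[20:25], coll, bg)
        assert out.loc[0, "p"] == 1.0
        assert np.isnan(out.loc[0, "strength"])

    def test_matches_exact_enumeration_for_all_small_instances(self):
        """Upper-tail p equals exhaustive rational enumeration for every
        (N, K, n, x) with N <= 30, within 1e-12."""
        from scipy.stats import hypergeom

        for N in range(1, 31):
            K_vals = range(0, N + 1, max(1, N // 6))
            n_vals = range(1, N + 1, max(1, N // 6))
            for K in K_vals:
                for n in n_vals:
                    for x in range(0, min(n, K) + 1):
                        p = float(hypergeom.sf(x - 1, N, K, n))
                        assert p == pytest.approx(
                            _exact_upper_tail(N, K, n, x), abs=1e-12
                        ), (N, K, n, x)

    def test_bh_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(20)
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q_sm, _bh_stepup(p), atol=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=40)
    )
    def test_bh_stepup_property(self, p):
        """BH adjusted p-values dominate the raw ones, stay in [0,1],
        and agree with the brute-force step-up on arbitrary inputs."""
        q = multipletests(np.asarray(p), method="fdr_bh")[1]
        assert np.allclose(q, _bh_stepup(p), atol=1e-12)
        assert np.all((q >= np.asarray(p) - 1e-15) & (q <= 1.0 + 1e-15))

    def test_background_enlargement_inflates_apparent_enrichment(self):
        """Padding the background with genes absent from query and sets
        shrinks the expected overlap, so every p monotonically decreases
        — the reason the background must be the expressed genes only."""
        bg = [f"G{i}" for i in range(40)]
        coll = _toy_collection({"S1": bg[:8], "S2": bg[8:20]})
        query = bg[:6] + bg[10:12]
        p_small = hypergeometric_enrichment(query, coll, bg).set_index("set_id")["p"]
        bigger = bg + [f"X{i}" for i in range(40)]
        p_big = hypergeometric_enrichment(query, coll, bigger).set_index("set_id")["p"]
        assert (p_big <= p_small + 1e-15).all()
        strength_small = hypergeometric_enrichment(query, coll, bg).set_index("set_id")["strength"]
        strength_big = hypergeometric_enrichment(query, coll, bigger).set_index("set_id")["strength"]
        assert (strength_big >= strength_small - 1e-12).all()

    def test_query_outside_background_dropped_with_warning(self):
        bg = [f"G{i}" for i in range(20)]
        coll = _toy_collection({"S": bg[:5]})
        with pytest.warns(UserWarning):
            out = hypergeometric_enrichment(bg[:3] + ["ALIEN"], coll, bg)
        assert out.loc[0, "n"] == 3

    def test_empty_query_after_intersection_rejected(self):
        bg = [f"G{i}" for i in range(10)]
        coll = _toy_collection({"S": bg[:5]})
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                hypergeometric_enrichment(["ALIEN"], coll, bg)

    def test_row_invariants(self):
        rng = np.random.default_rng(1)
        bg = [f"G{i}" for i in range(50)]
        coll = _toy_collection(
            {f"S{j}": rng.choice(bg, size=rng.integers(3, 15), replace=False)
             for j in range(8)}
        )
        query = list(rng.choice(bg, size=12, replace=False))
        out = hypergeometric_enrichment(query, coll, bg)
        assert ((out["x"] >= 0) & (out["x"] <= np.minimum(out["n"], out["K"]))).all()
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()
        assert (out["q"] >= out["p"] - 1e-15).all()
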