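"""Search thresholds, Fisher/BH statistics, prevalence, and ranges."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteogut.ecology import (DEFAULT_AGE_BINS, PrevalenceResult, QueryHit,
                               TaxonomicRange, bh_adjust, fisher_exact,
                               function_positive_fraction,
                               multi_protein_presence, prevalence_analysis,
                               presence_by_sample, read_hits_table, search,
                               taxonomic_range)
from proteogut.synthetic import AA_ALPHABET


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact integer arithmetic,
    using the same 1e-7 near-tie slack as the implementation."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weight = {x: math.comb(r1, x) * math.comb(r2, c1 - x)
              for x in range(lo, hi + 1)}
    w_obs = weight[a]
    num = sum(w for w in weight.values()
              if w * 10**7 <= w_obs * (10**7 + 1))
    return float(Fraction(num, sum(weight.values())))


def _subst(seq, n):
    # exactly n substitutions at evenly spaced interior positions
    chars = list(seq)
    positions = [2 + round(i * (len(seq) - 5) / max(n - 1, 1))
                 for i in range(n)]
    for p in sorted(set(positions)):
        chars[p] = AA_ALPHABET[(AA_ALPHABET.index(chars[p]) + 1) % 20]
    return "".join(chars)


class TestSearch:
    def _corpus_protein(self, rng, length=100):
        return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, length))

    def test_identical_query_hits_at_identity_one(self, rng):
        seq = self._corpus_protein(rng)
        hits = search({"q": seq}, {"1|ds|Bacteria|11|toolA": seq})
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0 and h.query_cov == 1.0 \
            and h.subject_cov == 1.0
        assert h.sample_or_genome == "ds"

    def test_85pct_identity_no_hit_at_defaults(self, rng):
        seq = self._corpus_protein(rng)
        variant = _subst(seq, 15)
        assert search({"q": variant}, {"s": seq}) == []

    def test_same_pair_hits_at_lowered_thresholds(self, rng):
        seq = self._corpus_protein(rng)
        variant = _subst(seq, 15)
        hits = search({"q": variant}, {"s": seq}, id_min=0.8, qcov_min=0.8,
                      scov_min=0.8)
        assert len(hits) == 1
        assert 0.8 <= hits[0].identity < 0.9

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            search({"q": "MKVL"}, {})

    def test_precomputed_hit_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts1\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t180\n"
                     "q\ts2\t85.0\t100\t15\t0\t1\t100\t1\t100\t1e-40\t150\n")
        hits = read_hits_table(p, {"q": 100}, {"s1": 100, "s2": 100})
        assert [h.subject_id for h in hits] == ["s1"]

    def test_presence_by_sample(self):
        hits = [QueryHit("q", "1|dsA|Bacteria|11|t", 1.0, 1.0, 1.0)]
        assert presence_by_sample(hits, ["dsA", "dsB"]) == \
            {"dsA": True, "dsB": False}


class TestFisher:
    def test_zero_margin_gives_one(self):
        assert fisher_exact([[0, 10], [0, 10]]) == 1.0

    def test_five_zero_zero_five(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252,
                                                               rel=1e-10)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
            if (a + b == 0 or c + d == 0) or (a + b + c + d == 0):
                continue
            expected = fisher_oracle(a, b, c, d)
            assert fisher_exact([[a, b], [c, d]]) == \
                pytest.approx(expected, rel=1e-10, abs=0)

    def test_matches_scipy(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], rel=1e-7)

    @given(st.tuples(*[st.integers(0, 12)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_symmetries(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0:
            return
        p = fisher_exact([[a, b], [c, d]])
        assert fisher_exact([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact([[b, a], [d, c]]) == pytest.approx(p, rel=1e-9)
        assert 0 <= p <= 1


class TestBH:
    def test_single_p_identity(self):
        assert list(bh_adjust([0.5])) == [0.5]

    def test_min_formula_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03, 0.04])) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_against_direct_min_formula(self, rng):
        for _ in range(30):
            p = rng.uniform(0, 1, int(rng.integers(1, 25)))
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank_idx, i in enumerate(order):
                vals = [p[order[j]] * m / (j + 1)
                        for j in range(rank_idx, m)]
                expected[i] = min(1.0, min(vals))
            assert list(bh_adjust(p)) == pytest.approx(list(expected))

    def test_never_decreases_p(self, rng):
        p = rng.uniform(0, 1, 20)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)

    def test_sorted_q_non_decreasing(self, rng):
        p = rng.uniform(0, 1, 40)
        q = bh_adjust(p)
        assert np.all(np.diff(np.sort(q)) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _toy_metadata(n_case=10, n_control=10):
    rows = []
    for i in range(n_case + n_control):
        case = i < n_case
        rows.append({"sample_id": f"s{i}", "age": 30 + i,
                     "sex": "female" if i % 2 else "male",
                     "CD": "yes" if case else "no", "UC": "no"})
    return pd.DataFrame(rows)


class TestPrevalence:
    def test_all_present_all_p_one(self):
        meta = _toy_metadata()
        presence = {f"s{i}": True for i in range(20)}
        for r in prevalence_analysis(presence, meta, variables=["sex"]):
            assert r.prevalence == 1.0
            assert r.p_value == pytest.approx(1.0)

    def test_engineered_split_matches_fisher(self):
        meta = _toy_metadata()
        # 9/10 cases positive, 1/10 controls positive
        presence = {f"s{i}": (i < 9 or i == 19) for i in range(20)}
        res = prevalence_analysis(presence, meta, mode="disease-vs-healthy",
                                  disease_flags=["CD"])
        cd = next(r for r in res if r.variable == "CD")
        assert cd.n_present == 9 and cd.n_total == 10
        assert cd.p_value == pytest.approx(fisher_exact([[9, 1], [1, 9]]),
                                           rel=1e-12)

    def test_no_healthy_controls_skipped(self, caplog):
        meta = _toy_metadata(n_case=20, n_control=0)
        presence = {f"s{i}": True for i in range(20)}
        with caplog.at_level("WARNING"):
            res = prevalence_analysis(presence, meta,
                                      mode="disease-vs-healthy")
        assert res == []
        assert any("healthy" in r.message for r in caplog.records)

    def test_group_totals_conserved(self):
        meta = _toy_metadata()
        meta.loc[3, "sex"] = None  # one missing value
        presence = {f"s{i}": i % 3 == 0 for i in range(20)}
        res = prevalence_analysis(presence, meta, variables=["sex"])
        assert sum(r.n_total for r in res) == 19

    def test_q_values_attached_within_variable(self):
        meta = _toy_metadata()
        presence = {f"s{i}": i % 2 == 0 for i in range(20)}
        res = prevalence_analysis(presence, meta, variables=["sex"])
        assert all(r.q_value is not None and r.q_value >= r.p_value - 1e-12
                   for r in res)


class TestMultiProtein:
    def test_single_query_identity(self):
        v = {"s1": True, "s2": False}
        assert multi_protein_presence([v]) == v

    def test_absence_in_any_query_negates(self):
        a = {"s1": True, "s2": True}
        b = {"s1": False, "s2": True}
        assert multi_protein_presence([a, b]) == {"s1": False, "s2": True}

    def test_three_chain_intersection(self):
        chains = [{"s1": True, "s2": True, "s3": False},
                  {"s1": True, "s2": False, "s3": True},
                  {"s1": True, "s2": True, "s3": True}]
        assert multi_protein_presence(chains) == \
            {"s1": True, "s2": False, "s3": False}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            multi_protein_presence([])


class TestFunctionPositiveFraction:
    def _matrix(self):
        return pd.DataFrame({"i1": [0.2, 0.3, 0.1], "i2": [0.0, 0.5, 0.4]},
                            index=["g1", "g2", "g3"])

    def test_empty_positive_set_zero(self):
        fractions = function_positive_fraction([], self._matrix())
        assert list(fractions) == [0.0, 0.0]

    def test_all_positive_equals_column_sum(self):
        m = self._matrix()
        fractions = function_positive_fraction(["g1", "g2", "g3"], m)
        assert list(fractions) == pytest.approx(list(m.sum(axis=0)))

    def test_printed_toy_sum(self):
        fractions = function_positive_fraction(["g1", "g3"], self._matrix())
        assert fractions["i1"] == pytest.approx(0.3)

    def test_monotone_in_positive_set(self):
        m = self._matrix()
        small = function_positive_fraction(["g1"], m)
        big = function_positive_fraction(["g1", "g2"], m)
        assert (big >= small - 1e-15).all()

    def test_missing_genome_warned_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            fractions = function_positive_fraction(["g1", "gX"],
                                                   self._matrix())
        assert fractions["i1"] == pytest.approx(0.2)
        assert any("absent" in r.message for r in caplog.records)

    def test_column_sum_over_one_rejected(self):
        bad = pd.DataFrame({"i1": [0.9, 0.9]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            function_positive_fraction(["g1"], bad)


class TestTaxonomicRange:
    TAX = {f"g{i}": (f"sp{i}", f"gen{i // 2}", f"fam{i // 4}",
                     f"phy{i // 6}") for i in range(12)}

    def test_single_species(self):
        tax = {"g1": ("sp1", "gen1", "fam1", "phy1")}
        r = taxonomic_range(["g1"], tax)
        assert r == TaxonomicRange(1, 1, 1, 1)
        assert not r.shared

    def test_shared_at_ten_species_two_phyla(self):
        r = taxonomic_range([f"g{i}" for i in range(10)], self.TAX)
        assert r.n_species == 10 and r.n_phyla == 2
        assert r.shared

    def test_hand_tally_on_twelve_genomes(self):
        r = taxonomic_range([f"g{i}" for i in range(12)], self.TAX)
        assert r == TaxonomicRange(12, 6, 3, 2)

    def test_unknown_genome_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            r = taxonomic_range(["g0", "missing"], self.TAX)
        assert r.n_species == 1
        assert any("no taxonomy" in rec.message for rec in caplog.records)
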