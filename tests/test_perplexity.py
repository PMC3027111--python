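import math

import numpy as np
import pytest
from scipy import stats

from prolang import (AlphabetPolicy, NgramLanguageModel, Proteome,
                     SmoothingPolicy, count_ngrams, divergence_report,
                     perplexity_scan)
from prolang.io import TaxonomyRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def oracle_cross_entropy(train_proteins, test_proteins, n, alphabet, alpha):
    """Independent term-by-term evaluation of the count-ratio entropy:
    pure-Python dict counting, scalar arithmetic, add-alpha smoothing with
    smoothed-unigram fallback for unseen contexts."""

    def counts(proteins, m):
        d = {}
        for p in proteins:
            for i in range(len(p) - m + 1):
                g = p[i : i + m]
                if all(ch in alphabet for ch in g):
                    d[g] = d.get(g, 0) + 1
        return d

    a = len(alphabet)
    c_train_n = counts(train_proteins, n)
    c_train_ctx = counts(train_proteins, n - 1) if n > 1 else None
    c_train_1 = counts(train_proteins, 1)
    n1_total = sum(c_train_1.values())
    c_test = counts(test_proteins, n)
    n_test = sum(c_test.values())
    e = 0.0
    for g, c in c_test.items():
        if n > 1:
            ctx_count = c_train_ctx.get(g[:-1], 0)
        else:
            ctx_count = sum(c_train_n.values())
        if ctx_count == 0:
            q = (c_train_1.get(g[-1], 0) + alpha) / (n1_total + alpha * a)
        else:
            q = (c_train_n.get(g, 0) + alpha) / (ctx_count + alpha * a)
        e -= c * math.log2(q)
    return e / n_test


class TestTraining:
    def test_trivial_bigram_counts(self):
        m = NgramLanguageModel(n=2).fit(Proteome("r", ["MKV"]))
        bigrams = count_ngrams(Proteome("r", ["MKV"]), 2)
        assert np.array_equal(m.ngram_counts_, bigrams.counts)
        assert bigrams.to_dict() == {"MK": 1, "KV": 1}
        ctx = {AA[i]: int(c) for i, c in enumerate(m.context_counts_) if c}
        assert ctx == {"M": 1, "K": 1, "V": 1}

    def test_periodic_sequence_contexts(self):
        """100 repeats of AACCT: five contexts, each with one continuation."""
        pol = AlphabetPolicy(NT)
        m = NgramLanguageModel(n=3, policy=pol).fit(
            Proteome("r", ["AACCT" * 100]))
        mat = m.conditional_matrix()
        ctx_counts = {NT[i // 4] + NT[i % 4]: int(c)
                      for i, c in enumerate(m.context_counts_) if c}
        assert set(ctx_counts) == {"AA", "AC", "CC", "CT", "TA"}
        assert all(99 <= c <= 100 for c in ctx_counts.values())
        # each seen context concentrates nearly all mass on one successor
        for i, c in enumerate(m.context_counts_):
            if c:
                assert mat[i].max() > 0.9

    def test_unigram_model_probabilities(self):
        m = NgramLanguageModel(
            n=1, smoothing=SmoothingPolicy("add_alpha", 1e-9)
        ).fit(Proteome("r", ["AAANTSDSQKE"]))
        probs = m.conditional_matrix()[0]
        assert probs[AA.index("A")] == pytest.approx(3 / 11, rel=1e-6)
        assert probs[AA.index("S")] == pytest.approx(2 / 11, rel=1e-6)
        assert probs[AA.index("E")] == pytest.approx(1 / 11, rel=1e-6)

    def test_context_count_at_least_ngram_count(self):
        rng = np.random.default_rng(5)
        prots = ["".join(rng.choice(list(AA), size=k))
                 for k in rng.integers(4, 80, size=10)]
        m = NgramLanguageModel(n=3).fit(Proteome("r", prots))
        ctx_of = np.repeat(m.context_counts_, 20)
        assert np.all(ctx_of >= m.ngram_counts_)

    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            NgramLanguageModel(n=4).fit(Proteome("r", ["MK"]))


class TestSmoothingNormalisation:
    def test_floor_smoothing_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        prots = ["".join(rng.choice(list(AA), size=k))
                 for k in rng.integers(5, 120, size=20)]
        m = NgramLanguageModel(
            n=3, smoothing=SmoothingPolicy("floor_prob", floor=1e-6)
        ).fit(Proteome("r", prots))
        rows = m.conditional_matrix().sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-9)

    @pytest.mark.parametrize("alpha", [1.0, 1e-4])
    def test_add_alpha_rows_sum_to_one_up_to_boundary_deficit(self, alpha):
        """Directly-counted contexts include each protein's terminal
        window, which has no continuation, so each protein can leave at
        most one unit of count-mass deficit in total; rows never exceed 1.
        """
        rng = np.random.default_rng(9)
        prots = ["".join(rng.choice(list(AA), size=k))
                 for k in rng.integers(5, 120, size=20)]
        m = NgramLanguageModel(
            n=3, smoothing=SmoothingPolicy("add_alpha", alpha)
        ).fit(Proteome("r", prots))
        rows = m.conditional_matrix().sum(axis=1)
        assert np.all(rows <= 1 + 1e-9)
        denom = m.context_counts_ + alpha * 20
        total_deficit_counts = float(((1.0 - rows) * denom).sum())
        assert total_deficit_counts <= len(prots) + 1e-6

    def test_unseen_smoothing_is_mandatory(self):
        with pytest.raises(ValueError):
            SmoothingPolicy("add_alpha", 0.0)
        with pytest.raises(ValueError):
            SmoothingPolicy("floor_prob", floor=0.0)


class TestCrossEntropy:
    def test_periodic_self_perplexity_near_one(self):
        """A trigram model of a period-5 repeat predicts it almost
        perfectly; only the terminal context leaks entropy."""
        p = Proteome("r", ["AACCT" * 100])
        m = NgramLanguageModel(
            n=3, policy=AlphabetPolicy(NT),
            smoothing=SmoothingPolicy("add_alpha", 1e-6),
        ).fit(p)
        res = m.cross_entropy(p)
        assert res.is_self
        assert res.perplexity == pytest.approx(1.0, rel=0.01)
        assert res.perplexity > 1.0

    def test_uniform_model_perplexity_equals_alphabet_size(self):
        u4 = NgramLanguageModel.uniform(AlphabetPolicy(NT), n=3)
        rng = np.random.default_rng(1)
        text = "".join(rng.choice(list(NT), size=500))
        assert u4.perplexity(Proteome("t", [text])) == pytest.approx(4.0,
                                                                     abs=1e-9)
        u20 = NgramLanguageModel.uniform(n=4)
        prot = "".join(np.random.default_rng(2).choice(list(AA), size=400))
        assert u20.perplexity(Proteome("t", [prot])) == pytest.approx(
            20.0, abs=1e-9)

    def test_matches_term_by_term_oracle(self):
        """Vectorised evaluation equals the independent scalar summation
        to 1e-12 relative error on random tiny train/test pairs."""
        rng = np.random.default_rng(42)
        for trial in range(25):
            n = int(rng.integers(1, 5))
            alpha = float(rng.choice([1.0, 0.5, 1e-3]))
            train = ["".join(rng.choice(list(AA), size=k))
                     for k in rng.integers(n, 40, size=4)]
            test = ["".join(rng.choice(list(AA), size=k))
                    for k in rng.integers(n, 40, size=4)]
            if not any(len(p) >= n for p in train):
                continue
            if not any(len(p) >= n for p in test):
                continue
            m = NgramLanguageModel(
                n=n, smoothing=SmoothingPolicy("add_alpha", alpha)
            ).fit(Proteome("r", train))
            got = m.cross_entropy(Proteome("t", test)).cross_entropy
            want = oracle_cross_entropy(train, test, n, AA, alpha)
            assert got == pytest.approx(want, rel=1e-12)

    def test_perplexity_is_two_to_the_entropy_and_at_least_one(self):
        rng = np.random.default_rng(8)
        train = ["".join(rng.choice(list(AA), size=100)) for _ in range(3)]
        test = ["".join(rng.choice(list(AA), size=100)) for _ in range(3)]
        m = NgramLanguageModel(n=2).fit(Proteome("r", train))
        res = m.cross_entropy(Proteome("t", test))
        assert res.perplexity == 2.0**res.cross_entropy
        assert res.perplexity >= 1.0
        assert 0.0 <= res.unseen_fraction <= 1.0

    def test_deterministic_bit_identical(self):
        rng = np.random.default_rng(4)
        train = ["".join(rng.choice(list(AA), size=200)) for _ in range(4)]
        test = ["".join(rng.choice(list(AA), size=200)) for _ in range(4)]
        m = NgramLanguageModel(n=3).fit(Proteome("r", train))
        r1 = m.cross_entropy(Proteome("t", test))
        r2 = m.cross_entropy(Proteome("t", test))
        assert r1.cross_entropy == r2.cross_entropy
        assert r1.perplexity == r2.perplexity

    def test_empty_test_raises(self):
        m = NgramLanguageModel(n=2).fit(Proteome("r", ["MKVL"]))
        with pytest.raises(ValueError):
            m.cross_entropy(Proteome("t", ["M"]))


class TestScanAndReport:
    def _collection(self, seed=0, n_prot=30, plen=120):
        rng = np.random.default_rng(seed)
        orgs = []
        for i in range(4):
            prots = ["".join(rng.choice(list(AA), size=plen))
                     for _ in range(n_prot)]
            orgs.append(Proteome(f"o{i}", prots))
        tax = [TaxonomyRecord(f"o{i}", "G1" if i < 2 else "G2", "C1", "P1",
                              branch_distance=0.1 * i) for i in range(4)]
        return orgs, tax

    def test_scan_has_one_self_row_and_sorted(self):
        orgs, tax = self._collection()
        m = NgramLanguageModel(n=2).fit(orgs[0])
        scan = perplexity_scan(m, orgs, tax)
        df = scan.to_frame()
        assert df["is_self"].sum() == 1
        assert (df["perplexity"].diff().dropna() >= 0).all()
        assert set(df["organism_id"]) == {o.organism_id for o in orgs}

    def test_identical_tests_identical_perplexity(self):
        orgs, tax = self._collection()
        dup = Proteome("o1_copy", list(orgs[1].proteins))
        m = NgramLanguageModel(n=2).fit(orgs[0])
        scan = perplexity_scan(m, [orgs[1], dup], None)
        vals = scan.to_frame()["perplexity"]
        assert vals.iloc[0] == vals.iloc[1]

    def test_divergence_report_three_point_closed_form(self):
        """Hand-constructed 3-point table: r = cov/(sd_x sd_y)."""
        orgs, _ = self._collection()
        m = NgramLanguageModel(n=2).fit(orgs[0])
        scan = perplexity_scan(m, orgs[:3], [
            TaxonomyRecord(f"o{i}", "G1", "C1", "P1", branch_distance=d)
            for i, d in enumerate([0.0, 0.1, 0.3])
        ])
        rep = divergence_report(scan)
        df = scan.to_frame().dropna(subset=["branch_distance"])
        x = df["branch_distance"].to_numpy()
        y = df["perplexity"].to_numpy()
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert rep["overall"]["pearson"] == pytest.approx(r_hand, rel=1e-9)
        # 3 distinct ranks: Spearman is Pearson on ranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rs_hand = np.corrcoef(rx, ry)[0, 1]
        assert rep["overall"]["spearman"] == pytest.approx(rs_hand, rel=1e-9)

    def test_equal_distances_yield_undefined_correlation(self):
        orgs, _ = self._collection()
        m = NgramLanguageModel(n=2).fit(orgs[0])
        scan = perplexity_scan(m, orgs[:2], [
            TaxonomyRecord(f"o{i}", "G1", "C1", "P1", branch_distance=0.2)
            for i in range(2)
        ])
        rep = divergence_report(scan)
        assert math.isnan(rep["overall"]["pearson"])

    def test_too_few_distances_raise(self):
        orgs, _ = self._collection()
        m = NgramLanguageModel(n=2).fit(orgs[0])
        scan = perplexity_scan(m, orgs[:2], None)
        with pytest.raises(ValueError):
            divergence_report(scan)
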