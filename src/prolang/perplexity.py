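"""Count-ratio n-gram language models and cross-perplexity.

A model trained on a reference proteome stores raw n-gram counts
``C_train(g)`` and directly-counted (n-1)-gram context counts
``C_train(ctx)``.  The conditional probability of the last residue given
its context is estimated by the (smoothed) count ratio

    q(g) = (C_train(g) + alpha) / (C_train(ctx) + alpha * |A|),

and the cross-entropy of a test proteome with n-gram counts C_test is

    E = -(1/N) * sum_g C_test(g) * log2 q(g),      B = 2**E,

where N is the total number of test n-gram tokens.  B is the perplexity:
the model's effective average branching factor per position — 1 for a
perfectly predictable sequence, |A| for one the model finds completely
random.  Low cross-perplexity means the test proteome "speaks the same
language" as the reference; within a genus it tracks evolutionary
divergence from the reference organism.

The raw count ratio is undefined for test n-grams unseen in training —
a certainty for 4-grams across divergent proteomes (20**4 = 160,000
types) — so some smoothing is mandatory.  Add-alpha over the |A|
continuations of each context is the default; contexts never seen in
training fall back to the smoothed unigram distribution of the final
residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import Proteome, TaxonomyRecord
from .ngrams import AlphabetPolicy, NgramCountTable, count_ngrams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoothingPolicy:
    """How unseen events get probability mass.

    ``add_alpha`` (default) adds ``alpha`` pseudo-counts per continuation
    symbol.  ``floor_prob`` clips the raw ratio from below at ``floor``
    and renormalises each context row.
    """

    kind: str = "add_alpha"
    alpha: float = 1.0
    floor: float = 1e-7

    def __post_init__(self) -> None:
        if self.kind not in ("add_alpha", "floor_prob"):
            raise ValueError(f"unknown smoothing kind {self.kind!r}")
        if self.kind == "add_alpha" and self.alpha <= 0:
            raise ValueError("add_alpha smoothing requires alpha > 0")
        if self.kind == "floor_prob" and self.floor <= 0:
            raise ValueError("floor_prob smoothing requires floor > 0")


@dataclass
class PerplexityResult:
    reference_id: str
    test_id: str
    n: int
    cross_entropy: float  # bits per n-gram token
    perplexity: float     # 2 ** cross_entropy
    unseen_fraction: float
    is_self: bool


class NgramLanguageModel(BaseEstimator):
    """Count-ratio n-gram language model of a reference proteome.

    Parameters
    ----------
    n:
        Model order (default 4, the headline whole-proteome setting).
        ``n=1`` is the context-free special case where the "context count"
        is the total token count.
    policy:
        Alphabet policy; default is the 20 canonical amino acids with
        windows containing other symbols dropped.
    smoothing:
        See :class:`SmoothingPolicy`.

    Attributes (after ``fit``)
    --------------------------
    reference_id_ : str
    ngram_counts_ : int64 array of length ``|A|**n``
    context_counts_ : int64 array of length ``|A|**(n-1)`` (counted
        directly from the text with the same windowing rules, so terminal
        per-protein windows are included)
    unigram_counts_ : int64 array of length ``|A|``
    """

    def __init__(
        self,
        n: int = 4,
        policy: Optional[AlphabetPolicy] = None,
        smoothing: Optional[SmoothingPolicy] = None,
    ):
        self.n = n
        self.policy = policy
        self.smoothing = smoothing

    # -- fitting ---------------------------------------------------------

    def fit(self, reference: Proteome) -> "NgramLanguageModel":
        if self.n < 1:
            raise ValueError("n must be >= 1")
        policy = self.policy or AlphabetPolicy()
        smoothing = self.smoothing or SmoothingPolicy()
        ngrams = count_ngrams(reference, self.n, policy)
        if ngrams.total == 0:
            raise ValueError(
                f"{reference.organism_id!r} yields no countable {self.n}-grams"
            )
        self.policy_ = ngrams.policy
        self.smoothing_ = smoothing
        self.reference_id_ = reference.organism_id
        self.ngram_counts_ = ngrams.counts
        if self.n > 1:
            self.context_counts_ = count_ngrams(
                reference, self.n - 1, self.policy_
            ).counts
        else:
            self.context_counts_ = np.array([ngrams.total], dtype=np.int64)
        if self.n == 1:
            self.unigram_counts_ = ngrams.counts
        else:
            self.unigram_counts_ = count_ngrams(reference, 1, self.policy_).counts
        self.uniform_ = False
        return self

    @classmethod
    def uniform(cls, policy: Optional[AlphabetPolicy] = None, n: int = 4
                ) -> "NgramLanguageModel":
        """A model whose conditional distribution is uniform over the
        alphabet for every context: q(g) = 1/|A| exactly, the analytic
        maximum-uncertainty limit (perplexity equals |A|)."""
        model = cls(n=n, policy=policy)
        p = policy or AlphabetPolicy()
        a = p.size
        model.policy_ = p
        model.smoothing_ = SmoothingPolicy()
        model.reference_id_ = f"<uniform|A|={a}>"
        model.ngram_counts_ = np.zeros(a**n, dtype=np.int64)
        model.context_counts_ = np.zeros(a ** (n - 1) if n > 1 else 1,
                                         dtype=np.int64)
        model.unigram_counts_ = np.zeros(a, dtype=np.int64)
        model.uniform_ = True
        return model

    # -- probabilities ---------------------------------------------------

    def _log2_q(self) -> np.ndarray:
        """log2 conditional probability for every possible n-gram index."""
        a = self.policy_.size
        if self.uniform_:
            return np.full(a**self.n, -np.log2(a))
        c_ng = self.ngram_counts_.astype(np.float64)
        c_ctx = np.repeat(self.context_counts_, a).astype(np.float64)
        sm = self.smoothing_
        if sm.kind == "add_alpha":
            q = (c_ng + sm.alpha) / (c_ctx + sm.alpha * a)
        else:  # floor_prob: clip ratios below, renormalise per context row
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(c_ctx > 0, c_ng / np.maximum(c_ctx, 1), 0.0)
            ratio = np.maximum(ratio, sm.floor)
            rows = ratio.reshape(-1, a)
            q = (rows / rows.sum(axis=1, keepdims=True)).ravel()
        # contexts never seen in training: back off to the smoothed
        # unigram distribution of the final residue
        unseen_ctx = np.repeat(self.context_counts_ == 0, a)
        if unseen_ctx.any():
            n1 = self.unigram_counts_.astype(np.float64)
            alpha = sm.alpha if sm.kind == "add_alpha" else sm.floor
            uni = (n1 + alpha) / (n1.sum() + alpha * a)
            q = np.where(unseen_ctx, np.tile(uni, a ** (self.n - 1)), q)
        return np.log2(q)

    def conditional_matrix(self) -> np.ndarray:
        """Smoothed conditional probabilities, shape (|A|**(n-1), |A|);
        every row sums to 1."""
        a = self.policy_.size
        return np.exp2(self._log2_q()).reshape(-1, a)

    # -- scoring ---------------------------------------------------------

    def _test_counts(self, test: Union[Proteome, NgramCountTable]
                     ) -> NgramCountTable:
        if isinstance(test, NgramCountTable):
            if test.n != self.n or test.policy.alphabet != self.policy_.alphabet:
                raise ValueError("test count table does not match model n/alphabet")
            return test
        return count_ngrams(test, self.n, self.policy_)

    def cross_entropy(self, test: Union[Proteome, NgramCountTable]
                      ) -> PerplexityResult:
        """Cross-entropy (bits per n-gram token) and perplexity of ``test``."""
        table = self._test_counts(test)
        n_test = table.total
        if n_test == 0:
            raise ValueError(
                f"test proteome {table.organism_id!r} has no countable "
                f"{self.n}-grams"
            )
        log_q = self._log2_q()
        if self.uniform_:
            # analytic limit: every term is -log2|A| exactly
            e = float(np.log2(self.policy_.size))
        else:
            e = float(-(table.counts @ log_q) / n_test)
        unseen = float(
            table.counts[self.ngram_counts_ == 0].sum() / n_test
        ) if not self.uniform_ else float(
            table.counts[self.ngram_counts_ == 0].sum() / n_test)
        return PerplexityResult(
            reference_id=self.reference_id_,
            test_id=table.organism_id,
            n=self.n,
            cross_entropy=e,
            perplexity=float(2.0**e),
            unseen_fraction=unseen,
            is_self=(table.organism_id == self.reference_id_),
        )

    def perplexity(self, test: Union[Proteome, NgramCountTable]) -> float:
        return self.cross_entropy(test).perplexity

    def score(self, test: Union[Proteome, NgramCountTable]) -> float:
        """Higher-is-better score (negative cross-entropy in bits)."""
        return -self.cross_entropy(test).cross_entropy


@dataclass
class PerplexityScan:
    """All-vs-one scan: perplexity of many test proteomes under one model."""

    reference_id: str
    n: int
    table: pd.DataFrame  # organism_id, perplexity, cross_entropy, ...

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def train_model(
    reference: Proteome,
    n: int = 4,
    policy: Optional[AlphabetPolicy] = None,
    smoothing: Optional[SmoothingPolicy] = None,
) -> NgramLanguageModel:
    """Thin functional wrapper over :class:`NgramLanguageModel`."""
    return NgramLanguageModel(n=n, policy=policy, smoothing=smoothing).fit(reference)


def cross_entropy(model: NgramLanguageModel,
                  test: Union[Proteome, NgramCountTable]) -> PerplexityResult:
    return model.cross_entropy(test)


def perplexity_scan(
    model: NgramLanguageModel,
    tests: Sequence[Union[Proteome, NgramCountTable]],
    taxonomy: Optional[Sequence[TaxonomyRecord]] = None,
) -> PerplexityScan:
    """Score every test proteome under ``model``, joined with taxonomy
    labels and branch distances where available; sorted ascending by
    perplexity."""
    if not tests:
        raise ValueError("need at least one test proteome")
    tax: Dict[str, TaxonomyRecord] = {
        r.organism_id: r for r in (taxonomy or [])
    }
    rows = []
    for t in tests:
        res = model.cross_entropy(t)
        rec = tax.get(res.test_id)
        if taxonomy is not None and rec is None:
            logger.warning("organism %r missing from taxonomy", res.test_id)
        rows.append(
            {
                "organism_id": res.test_id,
                "perplexity": res.perplexity,
                "cross_entropy": res.cross_entropy,
                "unseen_fraction": res.unseen_fraction,
                "is_self": res.is_self,
                "genus": rec.genus if rec else "",
                "class": rec.taxon_class if rec else "",
                "phylum": rec.phylum if rec else "",
                "branch_distance": rec.branch_distance if rec else None,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "perplexity", kind="stable"
    ).reset_index(drop=True)
    return PerplexityScan(model.reference_id_, model.n, table)


def divergence_report(scan: PerplexityScan) -> Dict[str, object]:
    """(branch_distance, perplexity) pairs plus their Pearson and Spearman
    correlations, overall and restricted to the reference's genus."""
    df = scan.table.dropna(subset=["branch_distance"])
    if len(df) < 2:
        raise ValueError("need >= 2 rows with branch_distance")

    def _corrs(sub: pd.DataFrame) -> Dict[str, float]:
        x = sub["branch_distance"].to_numpy(dtype=float)
        y = sub["perplexity"].to_numpy(dtype=float)
        if len(sub) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return {"pearson": float("nan"), "spearman": float("nan")}
        return {
            "pearson": float(stats.pearsonr(x, y).statistic),
            "spearman": float(stats.spearmanr(x, y).statistic),
        }

    ref_row = scan.table[scan.table["is_self"]]
    ref_genus = ref_row["genus"].iloc[0] if len(ref_row) else None
    report: Dict[str, object] = {
        "pairs": df[["organism_id", "branch_distance", "perplexity"]].copy(),
        "overall": _corrs(df),
    }
    if ref_genus:
        report["within_genus"] = _corrs(df[df["genus"] == ref_genus])
    return report


def save_model(model: NgramLanguageModel, prefix) -> None:
    """Serialise counts as two TSVs plus a small header file."""
    from pathlib import Path

    prefix = Path(prefix)
    a = model.policy_.alphabet
    tbl = NgramCountTable(model.reference_id_, model.n, model.policy_,
                          model.ngram_counts_)
    tbl.to_frame()[["ngram", "count"]].to_csv(
        f"{prefix}.ngrams.tsv", sep="\t", index=False)
    if model.n > 1:
        ctx = NgramCountTable(model.reference_id_, model.n - 1, model.policy_,
                              model.context_counts_)
        ctx.to_frame()[["ngram", "count"]].to_csv(
            f"{prefix}.contexts.tsv", sep="\t", index=False)
    sm = model.smoothing_
    with open(f"{prefix}.header.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"reference_id\t{model.reference_id_}\n")
        fh.write(f"n\t{model.n}\n")
        fh.write(f"alphabet\t{a}\n")
        fh.write(f"smoothing\t{sm.kind}\n")
        fh.write(f"alpha\t{sm.alpha}\n")
        fh.write(f"floor\t{sm.floor}\n")
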