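"""Modified Zipf-like comparative analysis of n-gram usage.

n-grams are sorted in descending order of their percentage frequency in a
chosen reference organism; every other organism's frequencies are then read
off in that fixed order.  Signature n-grams are those near the top of the
reference's ranking that are rare (or absent) in the comparison organisms.
Per-genus averages of the top-k frequency correlations quantify how well
the reference's n-gram usage is conserved within vs across genera.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import TaxonomyRecord
from .ngrams import FrequencyVector

logger = logging.getLogger(__name__)


@dataclass
class RankProfile:
    """Frequencies of every organism at the reference's ranked n-grams."""

    reference_id: str
    n: int
    ranked_ngrams: List[str]
    reference_freqs: np.ndarray              # percentages, non-increasing
    comparison_freqs: Dict[str, np.ndarray]  # organism -> aligned percentages

    def to_frame(self, taxonomy: Optional[Sequence[TaxonomyRecord]] = None
                 ) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_ngrams) + 1),
                "ngram": self.ranked_ngrams,
                self.reference_id: self.reference_freqs,
            }
        )
        for org, freqs in self.comparison_freqs.items():
            df[org] = freqs
        return df


@dataclass
class SignatureReport:
    reference_id: str
    n: int
    k: int
    rarity_quantile: float
    rarity_threshold: float
    signatures: List[Tuple[str, float, float]]  # (ngram, ref %, comparison quantile %)

    @property
    def ngrams(self) -> List[str]:
        return [s[0] for s in self.signatures]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures,
            columns=["ngram", "reference_freq", "comparison_quantile_freq"],
        )


@dataclass
class GenusCorrelationTable:
    reference_id: str
    n: int
    k: int
    table: pd.DataFrame  # genus, correlation, sd, n_species (desc. by mean)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


class ZipfProfiler(BaseEstimator):
    """Rank n-grams by a reference organism's frequencies and project other
    organisms onto that ordering.

    Ties in frequency are broken by alphabet (lexicographic) order of the
    n-gram, making the ranking — and every downstream export — deterministic.
    """

    def __init__(self, k: Optional[int] = None):
        self.k = k

    def fit(self, reference: FrequencyVector) -> "ZipfProfiler":
        # stable argsort on -freqs: ties fall back to ascending index order,
        # which is lexicographic over the alphabet
        order = np.argsort(-reference.freqs, kind="stable")
        if self.k is not None:
            if self.k < 1:
                raise ValueError("k must be >= 1")
            order = order[: self.k]
        self.reference_ = reference
        self.order_ = order
        self.ranked_ngrams_ = [reference.ngram_at(i) for i in order]
        self.reference_freqs_ = reference.freqs[order]
        return self

    def transform(self, others: Sequence[FrequencyVector]) -> RankProfile:
        comparison: Dict[str, np.ndarray] = {}
        for fv in others:
            if fv.n != self.reference_.n:
                raise ValueError(
                    f"{fv.organism_id}: n={fv.n} does not match reference "
                    f"n={self.reference_.n}"
                )
            if fv.policy.alphabet != self.reference_.policy.alphabet:
                raise ValueError(f"{fv.organism_id}: alphabet mismatch")
            comparison[fv.organism_id] = fv.freqs[self.order_]
        return RankProfile(
            reference_id=self.reference_.organism_id,
            n=self.reference_.n,
            ranked_ngrams=list(self.ranked_ngrams_),
            reference_freqs=self.reference_freqs_.copy(),
            comparison_freqs=comparison,
        )


def default_top_k(n: int) -> int:
    """k = 40 for 4-grams (the headline "top 40" setting); all 20 unigrams
    for n = 1; 40 otherwise."""
    return 20 if n == 1 else 40


def build_rank_profile(
    reference: FrequencyVector,
    others: Sequence[FrequencyVector],
    k: Optional[int] = None,
) -> RankProfile:
    return ZipfProfiler(k=k).fit(reference).transform(others)


def extract_signatures(
    profile: RankProfile,
    rarity_quantile: float = 0.5,
    rarity_threshold: float = 0.1,
) -> SignatureReport:
    """Flag top-k n-grams of the reference that are rare elsewhere.

    An n-gram is a signature when the chosen quantile (default: median) of
    its frequency across the comparison organisms falls below
    ``rarity_threshold`` times the reference's own frequency.
    """
    if not profile.comparison_freqs:
        raise ValueError("profile has no comparison organisms")
    if not 0 < rarity_quantile < 1:
        raise ValueError("rarity_quantile must be in (0, 1)")
    comp = np.vstack(list(profile.comparison_freqs.values()))
    qvals = np.quantile(comp, rarity_quantile, axis=0)
    signatures = [
        (g, float(rf), float(qv))
        for g, rf, qv in zip(profile.ranked_ngrams, profile.reference_freqs, qvals)
        if rf > 0 and qv < rarity_threshold * rf
    ]
    return SignatureReport(
        reference_id=profile.reference_id,
        n=profile.n,
        k=len(profile.ranked_ngrams),
        rarity_quantile=rarity_quantile,
        rarity_threshold=rarity_threshold,
        signatures=signatures,
    )


def genus_correlations(
    reference: FrequencyVector,
    others: Sequence[FrequencyVector],
    taxonomy: Sequence[TaxonomyRecord],
    k: Optional[int] = None,
    min_species: int = 9,
    method: str = "pearson",
) -> GenusCorrelationTable:
    """Per-genus mean/sd of the correlation between the reference's top-k
    n-gram frequencies and each member species' frequencies at those same
    n-grams.  Only genera with at least ``min_species`` species are
    reported; species with a constant frequency vector (correlation
    undefined) are excluded with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    k = k if k is not None else default_top_k(reference.n)
    if k < 3:
        raise ValueError("k must be >= 3 for a meaningful correlation")
    tax = {r.organism_id: r for r in taxonomy}
    profiler = ZipfProfiler(k=k).fit(reference)
    ref_vec = profiler.reference_freqs_

    per_genus: Dict[str, List[float]] = {}
    for fv in others:
        if fv.organism_id == reference.organism_id:
            continue
        rec = tax.get(fv.organism_id)
        if rec is None:
            logger.warning("organism %r missing from taxonomy; skipped",
                           fv.organism_id)
            continue
        vec = fv.freqs[profiler.order_]
        if np.ptp(vec) == 0 or np.ptp(ref_vec) == 0:
            logger.warning("organism %r: constant frequency vector; "
                           "correlation undefined, excluded", fv.organism_id)
            continue
        if method == "pearson":
            r = float(stats.pearsonr(ref_vec, vec).statistic)
        else:
            r = float(stats.spearmanr(ref_vec, vec).statistic)
        per_genus.setdefault(rec.genus, []).append(r)

    rows = [
        {
            "genus": genus,
            "correlation": float(np.mean(rs)),
            "sd": float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
            "n_species": len(rs),
        }
        for genus, rs in per_genus.items()
        if len(rs) >= min_species
    ]
    table = (
        pd.DataFrame(rows, columns=["genus", "correlation", "sd", "n_species"])
        .sort_values("correlation", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return GenusCorrelationTable(reference.organism_id, reference.n, k, table)
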