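"""Amino-acid (or nucleotide) n-gram counting for whole proteomes.

An n-gram is a window of ``n`` consecutive residues inside a single protein;
a protein of length ``L >= n`` contributes ``L - n + 1`` windows.  Windows
never span protein boundaries: concatenating proteins would manufacture
chimeric n-grams at the junctions, which are sequencing artifacts rather
than biology.

Counting is vectorised: residues are integer-encoded, each window is folded
into a base-``|A|`` integer (so index order equals lexicographic order over
the alphabet), and counts come from a single ``bincount``.  The dense count
vector of length ``|A|**n`` is the canonical in-memory container; sparse
dict views are derived from it on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .io import Proteome

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, in ASCII order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Nucleotide alphabet, for DNA-level analyses.
NUCLEOTIDES = "ACGT"

#: Conventional disambiguation of non-canonical one-letter codes:
#: B (Asx) -> D, Z (Glx) -> E, J (Leu/Ile) -> L, U (Sec) -> C, O (Pyl) -> K.
#: X (fully ambiguous) has no nearest residue and is always dropped.
NEAREST_CANONICAL = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

_SENTINEL = -1  # encodes out-of-alphabet symbols and protein boundaries


@dataclass(frozen=True)
class AlphabetPolicy:
    """Which symbols count, and what to do with the rest.

    Parameters
    ----------
    alphabet:
        Ordered string of allowed single-character symbols (default: the 20
        canonical amino acids).
    noncanonical_handling:
        ``"drop_ngram"`` (default) skips any window containing an
        out-of-alphabet symbol, keeping the vocabulary at ``|A|**n``;
        ``"map_to_nearest"`` rewrites known ambiguity codes to their
        conventional residue first; ``"keep"`` extends the alphabet on the
        fly with whatever symbols occur (vocabulary is then data-dependent).
    """

    alphabet: str = CANONICAL_AA
    noncanonical_handling: str = "drop_ngram"

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate symbols")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet needs at least 2 distinct symbols")
        if self.noncanonical_handling not in ("drop_ngram", "map_to_nearest", "keep"):
            raise ValueError(
                f"unknown noncanonical_handling {self.noncanonical_handling!r}"
            )

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def encoder(self) -> np.ndarray:
        """256-entry byte -> code lookup table (-1 marks invalid symbols)."""
        table = np.full(256, _SENTINEL, dtype=np.int16)
        for i, ch in enumerate(self.alphabet):
            table[ord(ch)] = i
        if self.noncanonical_handling == "map_to_nearest":
            for amb, canon in NEAREST_CANONICAL.items():
                if canon in self.alphabet:
                    table[ord(amb)] = self.alphabet.index(canon)
        return table

    def effective_alphabet(self, proteins: Iterable[str]) -> "AlphabetPolicy":
        """Under ``keep``, widen the alphabet with observed extra symbols."""
        if self.noncanonical_handling != "keep":
            return self
        seen = set().union(*(set(p) for p in proteins)) - set(self.alphabet)
        if not seen:
            return self
        return AlphabetPolicy(self.alphabet + "".join(sorted(seen)), "keep")


def vocabulary_size(policy: AlphabetPolicy, n: int) -> int:
    """Number of possible distinct n-grams, ``|A|**n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return policy.size**n


def _encode_concat(proteins: List[str], table: np.ndarray) -> np.ndarray:
    """Encode proteins into one code array with a sentinel between proteins."""
    parts = []
    for prot in proteins:
        codes = table[np.frombuffer(prot.encode("ascii", "replace"), dtype=np.uint8)]
        parts.append(codes)
        parts.append(np.array([_SENTINEL], dtype=np.int16))
    return np.concatenate(parts[:-1]) if parts else np.empty(0, dtype=np.int16)


@dataclass
class NgramCountTable:
    """Dense per-proteome n-gram counts over a fixed alphabet.

    ``counts[i]`` is the count of the n-gram whose base-``|A|`` digits are
    the alphabet indices of its residues; ``total`` is the number of counted
    n-gram tokens (the normaliser N of the entropy formula downstream).
    """

    organism_id: str
    n: int
    policy: AlphabetPolicy
    counts: np.ndarray
    skipped_windows: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (vocabulary_size(self.policy, self.n),):
            raise ValueError("counts vector has wrong length for alphabet/n")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index_of(self, ngram: str) -> int:
        if len(ngram) != self.n:
            raise ValueError(f"expected a {self.n}-gram, got {ngram!r}")
        idx = 0
        for ch in ngram:
            pos = self.policy.alphabet.find(ch)
            if pos < 0:
                raise KeyError(f"symbol {ch!r} not in alphabet")
            idx = idx * self.policy.size + pos
        return idx

    def ngram_at(self, index: int) -> str:
        a, n = self.policy.alphabet, self.n
        out = []
        for _ in range(n):
            index, r = divmod(index, len(a))
            out.append(a[r])
        return "".join(reversed(out))

    def get(self, ngram: str) -> int:
        return int(self.counts[self.index_of(ngram)])

    def to_dict(self) -> Dict[str, int]:
        """Sparse view: only n-grams with non-zero count."""
        nz = np.nonzero(self.counts)[0]
        return {self.ngram_at(i): int(self.counts[i]) for i in nz}

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: ngram, count, frequency_percent; descending count,
        ties broken lexicographically."""
        nz = np.nonzero(self.counts)[0]
        order = nz[np.argsort(-self.counts[nz], kind="stable")]
        total = self.total
        return pd.DataFrame(
            {
                "ngram": [self.ngram_at(i) for i in order],
                "count": self.counts[order],
                "frequency_percent": 100.0 * self.counts[order] / total,
            }
        )


@dataclass
class FrequencyVector:
    """Percentage n-gram frequencies (count / total * 100) of one proteome."""

    organism_id: str
    n: int
    policy: AlphabetPolicy
    freqs: np.ndarray  # percentages, aligned with NgramCountTable.counts

    def get(self, ngram: str) -> float:
        tmp = NgramCountTable(self.organism_id, self.n, self.policy,
                              np.zeros_like(self.freqs, dtype=np.int64))
        return float(self.freqs[tmp.index_of(ngram)])

    def ngram_at(self, index: int) -> str:
        tmp = NgramCountTable(self.organism_id, self.n, self.policy,
                              np.zeros_like(self.freqs, dtype=np.int64))
        return tmp.ngram_at(index)


def count_ngrams(
    proteome: Proteome, n: int, policy: Optional[AlphabetPolicy] = None
) -> NgramCountTable:
    """Count n-grams of ``proteome`` under the alphabet policy.

    Windows are taken within each protein independently; proteins shorter
    than ``n`` contribute nothing.  Under ``drop_ngram`` every window
    containing an out-of-alphabet symbol is skipped and tallied in
    ``skipped_windows``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not proteome.proteins:
        raise ValueError(f"proteome {proteome.organism_id!r} has no proteins")
    policy = policy or AlphabetPolicy()
    policy = policy.effective_alphabet(proteome.proteins)
    a = policy.size
    codes = _encode_concat(proteome.proteins, policy.encoder())

    m = len(codes) - n + 1
    if m <= 0:
        return NgramCountTable(proteome.organism_id, n, policy,
                               np.zeros(a**n, dtype=np.int64))
    idx = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for k in range(n):
        c = codes[k : k + m]
        valid &= c >= 0
        idx = idx * a + np.where(c >= 0, c, 0)
    counts = np.bincount(idx[valid], minlength=a**n)

    # windows lost to boundaries are structural, not "skipped": count only
    # in-protein windows that contained a non-alphabet residue
    n_boundary_windows = sum(
        min(len(p), n - 1) for p in proteome.proteins[:-1]
    )
    skipped = int(m - valid.sum()) - n_boundary_windows
    skipped = max(skipped, 0)
    if skipped:
        logger.info(
            "%s: skipped %d window(s) containing non-alphabet symbols",
            proteome.organism_id, skipped,
        )
    return NgramCountTable(proteome.organism_id, n, policy, counts, skipped)


def to_frequencies(table: NgramCountTable) -> FrequencyVector:
    """Convert raw counts to percentage frequencies (sums to 100)."""
    total = table.total
    if total == 0:
        raise ValueError(
            f"proteome {table.organism_id!r} has no countable {table.n}-grams"
        )
    return FrequencyVector(
        table.organism_id, table.n, table.policy,
        table.counts.astype(np.float64) * (100.0 / total),
    )


def write_count_table(table: NgramCountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
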