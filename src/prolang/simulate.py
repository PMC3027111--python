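"""Synthetic microbial proteome collections with known taxonomy.

Species proteomes are sampled from Markov chains over the 20 amino acids
whose conditional tables are derived by hierarchical perturbation along a
phylum -> class -> genus -> species taxonomy: each taxon's table is its
parent's table with independent Gaussian noise added to the logits
(softmax-renormalised), with a per-level magnitude sigma_phylum >=
sigma_class >= sigma_genus >= sigma_species.  Two species therefore share
n-gram statistics in proportion to how recently their lineages diverged,
which is exactly the structure the downstream analyses (genus signatures,
within-genus perplexity gradients) assume and try to recover.

The ground-truth branch distance between a species and the designated
reference organism is the sum of the perturbation magnitudes along the
taxonomy path connecting them — the generator's analogue of phylogenetic
tree distance.

The root conditional table is not an i.i.d. letter model: besides a
realistic amino-acid background composition it carries a context-dependent
"roughness" (logit noise, default sigma 0.5) shared by all taxa.  Real
proteomes use particular residue combinations far in excess of the product
of their letter frequencies; without roughness the top 4-gram frequencies
would be orders of magnitude flatter than in real data and the comparative
analyses would have essentially no dynamic range at realistic proteome
sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import Proteome, TaxonomyRecord
from .ngrams import CANONICAL_AA, AlphabetPolicy

logger = logging.getLogger(__name__)

#: Background amino-acid composition (Swiss-Prot-like averages, percent
#: renormalised to probabilities), indexed by CANONICAL_AA order.
BACKGROUND_AA_FREQS = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86, "G": 7.07,
    "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65, "M": 2.41, "N": 4.06,
    "P": 4.74, "Q": 3.93, "R": 5.53, "S": 6.64, "T": 5.35, "V": 6.86,
    "W": 1.10, "Y": 2.92,
}


def _background_vector() -> np.ndarray:
    v = np.array([BACKGROUND_AA_FREQS[a] for a in CANONICAL_AA])
    return v / v.sum()


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape and divergence structure of the synthetic taxonomy.

    Defaults mimic the shape of a ~1000-proteome microbial survey at
    roughly 1/10 size: 96 species across 3 phyla.  Divergence scales are
    logit-perturbation standard deviations per level and must be weakly
    decreasing from phylum to species.  ``species_divergences``, when
    given, replaces sigma_species with explicit per-species values applied
    within every genus (first species of the reference genus at divergence
    0 makes it a clean reference).
    """

    n_phyla: int = 3
    classes_per_phylum: int = 2
    genera_per_class: int = 4
    species_per_genus: int = 4
    sigma_phylum: float = 0.8
    sigma_class: float = 0.5
    sigma_genus: float = 0.3
    sigma_species: float = 0.1
    species_divergences: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_phyla", "classes_per_phylum", "genera_per_class",
                     "species_per_genus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        sig = (self.sigma_phylum, self.sigma_class, self.sigma_genus,
               self.sigma_species)
        if any(s < 0 for s in sig):
            raise ValueError("divergence scales must be >= 0")
        if not (sig[0] >= sig[1] >= sig[2] >= sig[3]):
            raise ValueError(
                "divergence scales must satisfy sigma_phylum >= sigma_class "
                ">= sigma_genus >= sigma_species"
            )
        if self.species_divergences is not None:
            if len(self.species_divergences) != self.species_per_genus:
                raise ValueError(
                    "species_divergences length must equal species_per_genus"
                )
            if any(d < 0 for d in self.species_divergences):
                raise ValueError("species_divergences must be >= 0")

    @property
    def n_species(self) -> int:
        return (self.n_phyla * self.classes_per_phylum
                * self.genera_per_class * self.species_per_genus)


@dataclass(frozen=True)
class GeneratorModel:
    """Sampling model: Markov order, root distribution, proteome shape.

    ``order`` is the context length of the generating chain (default 3,
    i.e. the chain carries 4-gram statistics).  Protein counts are uniform
    over ``protein_count_range`` (default ~2000 per species, microbial
    scale); lengths are lognormal with the given mean and log-sd, clipped
    to ``length_range`` (mean ~300 residues, the microbial average).
    ``planted`` holds (taxon_label, ngram, boost) signature directives —
    see :func:`plant_signatures`.
    """

    order: int = 3
    root_unigram_distribution: Optional[Tuple[float, ...]] = None
    root_roughness: float = 0.5
    protein_count_range: Tuple[int, int] = (1800, 2200)
    mean_protein_length: float = 300.0
    log_length_sd: float = 0.5
    length_range: Tuple[int, int] = (40, 3000)
    planted: Tuple[Tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.root_roughness < 0:
            raise ValueError("root_roughness must be >= 0")
        if self.protein_count_range[0] < 1 or (
            self.protein_count_range[1] < self.protein_count_range[0]
        ):
            raise ValueError("invalid protein_count_range")
        if self.length_range[0] <= self.order:
            raise ValueError("minimum protein length must exceed the order")

    def root_distribution(self) -> np.ndarray:
        if self.root_unigram_distribution is None:
            return _background_vector()
        v = np.asarray(self.root_unigram_distribution, dtype=float)
        if v.shape != (len(CANONICAL_AA),) or np.any(v < 0) or v.sum() <= 0:
            raise ValueError("root_unigram_distribution must be a valid "
                             "probability vector over the 20 amino acids")
        return v / v.sum()


def plant_signatures(
    model: GeneratorModel,
    taxon: str,
    ngrams: Sequence[str],
    boost: float,
) -> GeneratorModel:
    """Return a model in which ``taxon`` (a genus/class/phylum label, or a
    species id) over-produces the listed (order+1)-grams by ``boost``.

    The boost multiplies the conditional probability of each planted
    n-gram's final residue given its context in that taxon's table and
    renormalises the context row, so the plant propagates to the taxon's
    whole subtree.  ``boost = 1`` leaves the model unchanged.
    """
    if boost <= 0:
        raise ValueError("boost must be > 0")
    n = model.order + 1
    for g in ngrams:
        if len(g) != n:
            raise ValueError(f"planted n-gram {g!r} must have length {n}")
        if any(ch not in CANONICAL_AA for ch in g):
            raise ValueError(f"planted n-gram {g!r} has non-canonical symbols")
    if boost == 1:
        return model
    new = model.planted + tuple((taxon, g, float(boost)) for g in ngrams)
    return replace(model, planted=new)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _perturb(log_table: np.ndarray, sigma: float, rng: np.random.Generator
             ) -> np.ndarray:
    if sigma == 0:
        return log_table.copy()
    return log_table + rng.normal(0.0, sigma, size=log_table.shape)


def _apply_plants(log_table: np.ndarray, plants: List[Tuple[str, float]],
                  a: int) -> np.ndarray:
    """Boost planted n-grams in a taxon's log-conditional table."""
    table = _softmax_rows(log_table)
    for ngram, boost in plants:
        idx = [CANONICAL_AA.index(ch) for ch in ngram]
        row = 0
        for c in idx[:-1]:
            row = row * a + c
        raw = table[row, idx[-1]] * boost
        if raw > 1:
            logger.warning(
                "plant %r boost %.1f yields pre-normalisation probability "
                "%.3f > 1; renormalising", ngram, boost, raw,
            )
        table[row, idx[-1]] = raw
        table[row] /= table[row].sum()
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(table, 1e-300))


class _Node:
    def __init__(self, label: str, log_table: np.ndarray, depth_sigma: float,
                 parent: Optional["_Node"]):
        self.label = label
        self.log_table = log_table
        self.depth_sigma = depth_sigma  # perturbation magnitude from parent
        self.parent = parent

    def path_to_root(self) -> List["_Node"]:
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out


def _tree_distance(a: "_Node", b: "_Node") -> float:
    """Sum of perturbation magnitudes along the path a .. MRCA .. b."""
    pa = {id(n): i for i, n in enumerate(a.path_to_root())}
    dist = 0.0
    node = b
    while id(node) not in pa:
        dist += node.depth_sigma
        node = node.parent
    mrca = node
    node = a
    while node is not mrca:
        dist += node.depth_sigma
        node = node.parent
    return dist


def _sample_proteome(
    table: np.ndarray,
    order: int,
    n_proteins: int,
    model: GeneratorModel,
    rng: np.random.Generator,
) -> List[str]:
    """Vectorised sampling of all proteins of one species in parallel."""
    a = len(CANONICAL_AA)
    mu = math.log(model.mean_protein_length) - model.log_length_sd**2 / 2
    lengths = np.clip(
        np.round(rng.lognormal(mu, model.log_length_sd, size=n_proteins)),
        model.length_range[0], model.length_range[1],
    ).astype(np.int64)
    lengths[::-1].sort()  # descending: the active set is always a prefix

    # initial `order` residues i.i.d. from the species' marginal composition
    marginal = table.mean(axis=0)
    marginal = marginal / marginal.sum()
    seqs = np.zeros((n_proteins, int(lengths[0])), dtype=np.int8)
    init = rng.choice(a, size=(n_proteins, order), p=marginal)
    seqs[:, :order] = init

    ctx = np.zeros(n_proteins, dtype=np.int64)
    for k in range(order):
        ctx = ctx * a + init[:, k]

    cum = np.cumsum(table, axis=1)
    cum[:, -1] = 1.0
    mod = a ** (order - 1) if order > 1 else 1
    for t in range(order, int(lengths[0])):
        active = int(np.searchsorted(-lengths, -t))  # lengths > t
        if active == 0:
            break
        u = rng.random(active)
        rows = cum[ctx[:active]]
        nxt = (u[:, None] < rows).argmax(axis=1)
        seqs[:active, t] = nxt
        ctx[:active] = (ctx[:active] % mod) * a + nxt

    letters = np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)
    out = []
    for i in range(n_proteins):
        out.append(letters[seqs[i, : lengths[i]]].tobytes().decode("ascii"))
    return out


def _build_tree(
    spec: TaxonomySpec, model: GeneratorModel
) -> Tuple[List["_Node"], List[TaxonomyRecord], Dict[str, "_Node"],
           np.random.Generator]:
    """Derive the full taxonomy tree of conditional tables.

    The RNG stream is consumed identically whether or not the model
    carries planted signatures (plants do not draw random numbers), so a
    collection generated with plants is the same collection plus the
    boosts.
    """
    rng = np.random.default_rng(spec.seed)
    a = len(CANONICAL_AA)
    order = model.order

    root_log = np.tile(np.log(model.root_distribution()), (a**order, 1))
    root_log = _perturb(root_log, model.root_roughness, rng)
    root = _Node("root", root_log, 0.0, None)

    plants_by_taxon: Dict[str, List[Tuple[str, float]]] = {}
    for taxon, ngram, boost in model.planted:
        plants_by_taxon.setdefault(taxon, []).append((ngram, boost))

    nodes_by_label: Dict[str, _Node] = {"root": root}

    def make_child(parent: _Node, label: str, sigma: float) -> _Node:
        log_table = _perturb(parent.log_table, sigma, rng)
        if label in plants_by_taxon:
            log_table = _apply_plants(log_table, plants_by_taxon[label], a)
        node = _Node(label, log_table, sigma, parent)
        nodes_by_label[label] = node
        return node

    species_nodes: List[_Node] = []
    records: List[TaxonomyRecord] = []
    host_choices = ("animal", "plant", "none")
    for p in range(spec.n_phyla):
        phylum = make_child(root, f"P{p+1:02d}", spec.sigma_phylum)
        for c in range(spec.classes_per_phylum):
            cls = make_child(phylum, f"{phylum.label}.C{c+1:02d}",
                             spec.sigma_class)
            for g in range(spec.genera_per_class):
                genus = make_child(cls, f"{cls.label}.G{g+1:02d}",
                                   spec.sigma_genus)
                host = host_choices[rng.integers(len(host_choices))]
                for s in range(spec.species_per_genus):
                    sigma_s = (
                        spec.species_divergences[s]
                        if spec.species_divergences is not None
                        else spec.sigma_species
                    )
                    sp = make_child(genus, f"{genus.label}.S{s+1:02d}", sigma_s)
                    species_nodes.append(sp)
                    records.append(
                        TaxonomyRecord(
                            organism_id=sp.label,
                            genus=genus.label,
                            taxon_class=cls.label,
                            phylum=phylum.label,
                            superkingdom="Bacteria",
                            host_label=host,
                        )
                    )
    return species_nodes, records, nodes_by_label, rng


def _stationary_context_distribution(
    table: np.ndarray, order: int, a: int, n_iter: int = 40
) -> np.ndarray:
    """Stationary distribution over length-``order`` contexts of the chain
    (power iteration; proteins are long enough that the quasi-stationary
    regime dominates)."""
    mod = a ** (order - 1) if order > 1 else 1
    p = np.full(a**order, 1.0 / a**order)
    ctx_idx = np.arange(a**order)
    new_idx = ((ctx_idx % mod)[:, None] * a + np.arange(a)).ravel()
    for _ in range(n_iter):
        joint = (p[:, None] * table).ravel()
        p = np.bincount(new_idx, weights=joint, minlength=a**order)
        p /= p.sum()
    return p


def choose_plantable_ngrams(
    spec: TaxonomySpec,
    model: GeneratorModel,
    taxon: str,
    n_ngrams: int = 5,
    boost: float = 50.0,
) -> List[str]:
    """Pick (order+1)-grams that make effective planted signatures for
    ``taxon``: a high-probability context with a rare continuation.

    Real proteome signatures are exactly this shape — a residue
    combination an organism uses heavily that the background grammar
    almost never produces.  A rare continuation keeps the boost away from
    probability saturation (so the boosted-to-background frequency ratio
    stays near ``boost``), and a common context gives the boosted n-gram
    enough absolute frequency to enter the reference's top ranks.
    Deterministic given ``spec.seed``.
    """
    if n_ngrams < 1:
        raise ValueError("n_ngrams must be >= 1")
    _, _, nodes, _ = _build_tree(spec, model)
    if taxon not in nodes:
        raise ValueError(f"taxon {taxon!r} not in the taxonomy")
    table = _softmax_rows(nodes[taxon].log_table)
    a = len(CANONICAL_AA)
    order = model.order

    p_ctx = _stationary_context_distribution(table, order, a)
    p4 = (p_ctx[:, None] * table)
    top40 = np.sort(p4.ravel())[-40]

    # renormalised boosted conditional and its ratio to the background;
    # demand ratio >= 2x the default rarity threshold's reciprocal (20) so
    # the planted n-gram stays flaggable despite between-taxon noise
    boosted = (table * boost) / (1 + table * (boost - 1))
    ratio = boosted / np.maximum(table, 1e-300)
    ok = ratio >= min(20.0, boost * 0.9)
    pred_freq = np.where(ok, p_ctx[:, None] * boosted, -np.inf)
    flat_order = np.argsort(pred_freq.ravel())[::-1]
    chosen: List[str] = []
    used_rows = set()
    letters = CANONICAL_AA
    # 1.5x margin over the top-40 cutoff absorbs species-level perturbation
    # of the genus table and counting noise in the realized proteome
    for idx in flat_order:
        row, col = divmod(int(idx), a)
        if pred_freq[row, col] < 1.5 * top40:
            break
        if row in used_rows:
            continue
        used_rows.add(row)
        ctx = []
        r = row
        for _ in range(order):
            r, d = divmod(r, a)
            ctx.append(letters[d])
        chosen.append("".join(reversed(ctx)) + letters[col])
        if len(chosen) == n_ngrams:
            break
    if len(chosen) < n_ngrams:
        raise ValueError(
            f"only {len(chosen)} plantable n-gram(s) found for {taxon!r}"
        )
    return chosen


def generate_collection(
    spec: TaxonomySpec,
    model: Optional[GeneratorModel] = None,
    reference_index: int = 0,
) -> Tuple[List[Proteome], List[TaxonomyRecord]]:
    """Sample one proteome per species plus its taxonomy records.

    Fully reproducible from ``spec.seed``.  ``reference_index`` designates
    the species (in generation order) whose node anchors the
    ``branch_distance`` column.
    """
    model = model or GeneratorModel()
    species_nodes, records, _, rng = _build_tree(spec, model)

    if not 0 <= reference_index < len(species_nodes):
        raise ValueError("reference_index out of range")
    ref_node = species_nodes[reference_index]
    for rec, node in zip(records, species_nodes):
        rec.branch_distance = _tree_distance(ref_node, node)

    proteomes: List[Proteome] = []
    for rec, node in zip(records, species_nodes):
        n_proteins = int(rng.integers(model.protein_count_range[0],
                                      model.protein_count_range[1] + 1))
        table = _softmax_rows(node.log_table)
        if np.any(~np.isfinite(table)) or np.any(table.sum(axis=1) <= 0):
            raise ValueError(f"degenerate conditional table for {node.label}")
        proteins = _sample_proteome(table, model.order, n_proteins, model, rng)
        proteomes.append(Proteome(rec.organism_id, proteins, source_path=""))
    return proteomes, records


def genus_ladder_spec(
    divergences: Sequence[float] = (0.01, 0.0825, 0.155, 0.2275, 0.3),
    seed: int = 0,
    **kwargs,
) -> TaxonomySpec:
    """Single-genus ladder: a reference species at divergence 0 plus one
    species per requested divergence, used for perplexity-vs-divergence
    parameter recovery."""
    divs = (0.0,) + tuple(float(d) for d in divergences)
    return TaxonomySpec(
        n_phyla=1, classes_per_phylum=1, genera_per_class=1,
        species_per_genus=len(divs), sigma_phylum=1.0, sigma_class=1.0,
        sigma_genus=1.0, sigma_species=max(divs),
        species_divergences=divs, seed=seed, **kwargs,
    )
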