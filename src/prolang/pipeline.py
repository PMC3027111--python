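"""End-to-end pipeline: count -> zipf/signatures -> perplexity scan ->
classify, driven by a single YAML config, with a run manifest for
reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import accuracy_table
from .io import (Proteome, TaxonomyRecord, read_proteome, read_taxonomy,
                 taxonomy_to_frame)
from .ngrams import (AlphabetPolicy, count_ngrams, to_frequencies,
                     write_count_table)
from .perplexity import (NgramLanguageModel, SmoothingPolicy,
                         divergence_report, perplexity_scan)
from .zipf import (build_rank_profile, default_top_k, extract_signatures,
                   genus_correlations)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_dir: str
    taxonomy_path: str
    output_dir: str
    reference_id: str = ""
    n_orders: List[int] = field(default_factory=lambda: [1, 4])
    top_k: Optional[int] = None
    model_n: int = 4
    smoothing_alpha: float = 1.0
    rarity_quantile: float = 0.5
    rarity_threshold: float = 0.1
    min_species: int = 9
    cv_folds: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require_reference: bool = True) -> None:
        if not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        if not Path(self.taxonomy_path).is_file():
            raise ValueError(
                f"taxonomy_path does not exist: {self.taxonomy_path}")
        if require_reference and not self.reference_id:
            raise ValueError("reference_id is required for the zipf and "
                             "perplexity stages")
        if any(n < 1 for n in self.n_orders) or self.model_n < 1:
            raise ValueError("n-gram orders must be >= 1")
        if self.smoothing_alpha <= 0:
            raise ValueError("smoothing_alpha must be > 0")


def load_collection(config: RunConfig):
    proteomes = [
        read_proteome(p) for p in sorted(Path(config.input_dir).glob("*.fasta"))
    ] + [
        read_proteome(p) for p in sorted(Path(config.input_dir).glob("*.fa"))
    ]
    if not proteomes:
        raise ValueError(f"no FASTA files found in {config.input_dir}")
    taxonomy = read_taxonomy(config.taxonomy_path)
    return proteomes, taxonomy


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteomes, taxonomy = load_collection(config)
    policy = AlphabetPolicy()
    ids = [p.organism_id for p in proteomes]
    if config.reference_id not in ids:
        raise ValueError(
            f"reference_id {config.reference_id!r} not among input organisms")

    # counts + frequencies per requested order
    freq_by_order = {}
    counts_dir = out / "counts"
    counts_dir.mkdir(exist_ok=True)
    for n in sorted(set(config.n_orders) | {config.model_n}):
        tables = [count_ngrams(p, n, policy) for p in proteomes]
        for t in tables:
            write_count_table(t, counts_dir / f"{t.organism_id}.n{n}.tsv")
        freq_by_order[n] = [to_frequencies(t) for t in tables]

    # zipf profile + signatures + genus correlations at the model order
    n = config.model_n
    freqs = freq_by_order[n]
    ref_fv = next(f for f in freqs if f.organism_id == config.reference_id)
    others = [f for f in freqs if f.organism_id != config.reference_id]
    k = config.top_k or default_top_k(n)
    profile = build_rank_profile(ref_fv, others, k=k)
    profile.to_frame().to_csv(out / "rank_profile.tsv", sep="\t", index=False)
    sig = extract_signatures(profile, config.rarity_quantile,
                             config.rarity_threshold)
    sig.to_frame().to_csv(out / "signatures.tsv", sep="\t", index=False)
    corr = genus_correlations(ref_fv, others, taxonomy, k=k,
                              min_species=config.min_species)
    corr.to_frame().to_csv(out / "genus_correlations.tsv", sep="\t",
                           index=False)

    # perplexity scan
    ref_proteome = next(p for p in proteomes if p.organism_id == config.reference_id)
    model = NgramLanguageModel(
        n=n, policy=policy,
        smoothing=SmoothingPolicy("add_alpha", alpha=config.smoothing_alpha),
    ).fit(ref_proteome)
    scan = perplexity_scan(model, proteomes, taxonomy)
    scan.to_frame().to_csv(out / "perplexity_scan.tsv", sep="\t", index=False)
    if scan.table["branch_distance"].notna().sum() >= 2:
        rep = divergence_report(scan)
        pd.DataFrame([rep["overall"] | {"scope": "overall"}]
                     + ([rep["within_genus"] | {"scope": "within_genus"}]
                        if "within_genus" in rep else [])
                     ).to_csv(out / "divergence_correlations.tsv", sep="\t",
                              index=False)

    # unigram classification
    uni = freq_by_order.get(1)
    if uni is None:
        uni = [to_frequencies(count_ngrams(p, 1, policy)) for p in proteomes]
    freq_matrix = pd.DataFrame(
        {f.organism_id: f.freqs for f in uni}, index=list(policy.alphabet)
    ).T
    try:
        acc = accuracy_table(freq_matrix, taxonomy,
                             min_species=config.min_species,
                             folds=config.cv_folds, seed=config.seed)
        acc.to_csv(out / "cv_accuracy.tsv", sep="\t", index=False)
    except ValueError as exc:
        logger.warning("classification stage skipped: %s", exc)

    manifest = {
        "prolang_version": __version__,
        "seed": config.seed,
        "config": config.__dict__,
        "n_organisms": len(proteomes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
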