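"""FASTA / taxonomy I/O.

One FASTA file is one organism's proteome (one record per protein); the
organism id is the file stem unless overridden.  Taxonomy metadata is a
TSV with one row per organism.  All tabular outputs across the package
are TSV with a header, '.' decimal separator, no thousands separators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_HOST_LABELS = ("animal", "plant", "none")
_REQUIRED_TAXONOMY_COLUMNS = ("organism_id", "genus", "class", "phylum")


@dataclass
class Proteome:
    """An organism's full complement of protein sequences."""

    organism_id: str
    proteins: List[str]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.organism_id:
            raise ValueError("organism_id must be non-empty")
        if any(not p.strip() for p in self.proteins):
            raise ValueError(
                f"{self.organism_id}: empty protein sequence(s) present")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def total_residues(self) -> int:
        return sum(len(p) for p in self.proteins)


@dataclass
class TaxonomyRecord:
    """Taxonomic labels for one organism, plus optional host-pathogenicity
    label and branch distance to a designated reference organism."""

    organism_id: str
    genus: str
    taxon_class: str
    phylum: str
    superkingdom: str = "Bacteria"
    host_label: str = "none"
    branch_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.host_label not in _HOST_LABELS:
            self.host_label = "none"
        if self.branch_distance is not None and self.branch_distance < 0:
            raise ValueError(
                f"{self.organism_id}: branch_distance must be >= 0"
            )


def _clean_sequence(seq: str) -> str:
    """Uppercase and strip gap characters and translation stops.

    '*' is removed anywhere (not just terminally); '-' and '.' always.
    All other characters are retained verbatim — the alphabet policy is
    applied at counting time, not here.
    """
    s = "".join(seq.split()).upper()
    return s.replace("*", "").replace("-", "").replace(".", "")


def read_proteome(path, organism_id: Optional[str] = None) -> Proteome:
    """Read one proteome FASTA file.

    Record order is preserved; records whose sequence is empty after
    cleaning are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    organism_id = organism_id or path.stem
    proteins: List[str] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = _clean_sequence(str(rec.seq))
        if not seq:
            logger.warning("%s: record %r has empty sequence; skipped",
                           path.name, rec.id)
            continue
        proteins.append(seq)
    if n_records == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return Proteome(organism_id=organism_id, proteins=proteins,
                    source_path=str(path))


def write_proteome(proteome: Proteome, path, width: int = 60) -> None:
    """Write a proteome as multi-record FASTA (one record per protein)."""
    records = [
        SeqRecord(Seq(p), id=f"{proteome.organism_id}|p{i:05d}", description="")
        for i, p in enumerate(proteome.proteins, start=1)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_taxonomy(path) -> List[TaxonomyRecord]:
    """Read the taxonomy TSV (columns organism_id, genus, class, phylum;
    optional superkingdom, host, branch_distance)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    dup = df["organism_id"][df["organism_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate organism_id(s): {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        host = str(row.get("host", "none")).strip().lower()
        if host not in _HOST_LABELS:
            host = "none"
        bd = row.get("branch_distance")
        branch = None if bd is None or pd.isna(bd) or bd == "" else float(bd)
        records.append(
            TaxonomyRecord(
                organism_id=str(row["organism_id"]),
                genus=str(row["genus"]),
                taxon_class=str(row["class"]),
                phylum=str(row["phylum"]),
                superkingdom=str(row.get("superkingdom", "Bacteria")),
                host_label=host,
                branch_distance=branch,
            )
        )
    return records


def taxonomy_to_frame(records: List[TaxonomyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "organism_id": [r.organism_id for r in records],
            "genus": [r.genus for r in records],
            "class": [r.taxon_class for r in records],
            "phylum": [r.phylum for r in records],
            "superkingdom": [r.superkingdom for r in records],
            "host": [r.host_label for r in records],
            "branch_distance": [r.branch_distance for r in records],
        }
    )


def write_taxonomy(records: List[TaxonomyRecord], path) -> None:
    taxonomy_to_frame(records).to_csv(path, sep="\t", index=False)
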