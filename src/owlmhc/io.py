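"""File formats and run configuration.

Plain-text interchange between stages: FASTA for allele pools (Biopython),
TSV for variant-depth spectra, CSV for genotypes / divergence / nest
records, YAML for run configuration.  Every table written by a pipeline
stage carries a header comment recording the config hash and seed, so two
runs with equal hashes produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyper import VariantTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variants",
    "write_variants",
    "read_table",
    "write_table",
    "RunConfig",
]


def read_fasta(path, aligned: bool = False) -> dict[str, str]:
    """Read a FASTA file to {id: sequence}; rejects duplicated ids and,
    with ``aligned=True``, length-inconsistent records."""
    records: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seq = str(rec.seq).upper()
        if aligned:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"alignment length mismatch at record {rec.id!r}: "
                    f"{len(seq)} != {length}"
                )
        records[rec.id] = seq
    return records


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_variants(path, tables: list[VariantTable], header: str = "") -> None:
    rows = []
    for t in tables:
        for seq, depth in zip(t.sequences, t.depths):
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "locus": t.locus,
                    "replicate": t.replicate,
                    "sequence": seq,
                    "depth": depth,
                }
            )
    write_table(path, pd.DataFrame(rows), header=header, sep="\t")


def read_variants(path) -> list[VariantTable]:
    df = read_table(path, sep="\t")
    tables = []
    for (sid, locus, rep), sub in df.groupby(
        ["sample_id", "locus", "replicate"], sort=True
    ):
        tables.append(
            VariantTable(
                str(sid), str(locus), int(rep),
                list(sub["sequence"]), list(sub["depth"]),
            )
        )
    return tables


def write_table(path, df: pd.DataFrame, header: str = "", sep: str = ",") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, sep=sep)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


@dataclass
class RunConfig:
    """Single-file configuration of an end-to-end run."""

    seed: int = 1
    outdir: str = "owlmhc_run"
    loci: list[str] = field(default_factory=lambda: ["MHC-Ia", "DAB1", "DAB2"])
    n_individuals: int = 200
    n_nests: int = 250
    crossfoster_plan: str = "study"
    dataset_mode: str = "full"
    response: str = "fledging"
    focal_locus: str = "MHC-Ia"
    random_structure: str = "couple"
    k_method: dict = field(default_factory=lambda: {
        "MHC-Ia": "BIC", "DAB1": "silhouette", "DAB2": "silhouette"})
    noise: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    genotyper: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @property
    def config_hash(self) -> str:
        """Fingerprint of the scientific configuration (paths excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"config_hash={self.config_hash} seed={self.seed}"
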