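"""File formats and run configuration.

TSV outputs carry ``#``-prefixed metadata lines (configuration hash, seeds)
before the header; FASTA/FASTQ are written plain — sequence formats have no
portable comment syntax, so their provenance lives in the run's
``provenance.json`` instead.  Sequence parsing goes through Biopython.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ReadSet, ReferencePanel, decode_seq, encode_seq

__all__ = [
    "SchemaError",
    "RunConfig",
    "config_hash",
    "write_fasta_panel",
    "read_fasta_panel",
    "write_fastq",
    "read_fastq",
    "write_tsv",
    "read_tsv",
]


class SchemaError(ValueError):
    pass


def config_hash(config: Mapping) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """End-to-end run configuration with per-stage blocks.

    Missing blocks fall back to module defaults; see
    :func:`introquant.pipeline.run_all` for the recognized keys.
    """

    seed: int = 0
    outdir: str = "introquant_out"
    simulate: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    contamination: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": self.simulate,
            "mapping": self.mapping,
            "scoring": self.scoring,
            "contamination": self.contamination,
            "networks": self.networks,
            "log_level": self.log_level,
        }

    @property
    def hash(self) -> str:
        # outdir and log level do not affect results, so they are excluded:
        # the hash identifies the scientific configuration
        d = self.to_dict()
        d.pop("outdir")
        d.pop("log_level")
        return config_hash(d)


# ---------------------------------------------------------------- FASTA


def write_fasta_panel(panel: ReferencePanel, path: str | Path) -> None:
    """FASTA with headers `>genus|species|locus_id`."""
    records = (
        SeqRecord(
            Seq(decode_seq(panel.seqs[(sp, loc)])),
            id=f"{panel.genus}|{sp}|{loc}",
            description="",
        )
        for sp in panel.species
        for loc in panel.locus_ids
    )
    SeqIO.write(records, str(path), "fasta")


def read_fasta_panel(path: str | Path) -> ReferencePanel:
    seqs: dict[tuple[str, str], np.ndarray] = {}
    genus = None
    species: list[str] = []
    locus_ids: list[str] = []
    lengths: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise SchemaError(f"record {i + 1} ({rec.id!r}): header is not genus|species|locus")
        g, sp, loc = parts
        if genus is None:
            genus = g
        elif g != genus:
            raise SchemaError(f"record {i + 1}: mixed genera {genus!r} and {g!r} in one panel")
        if sp not in species:
            species.append(sp)
        if loc not in locus_ids:
            locus_ids.append(loc)
            lengths[loc] = len(rec.seq)
        elif lengths[loc] != len(rec.seq):
            raise SchemaError(f"record {i + 1}: locus {loc} length differs between species")
        seqs[(sp, loc)] = encode_seq(str(rec.seq))
    if genus is None:
        raise SchemaError("empty FASTA panel")
    return ReferencePanel(genus, species, locus_ids, [lengths[x] for x in locus_ids], seqs)


# ---------------------------------------------------------------- FASTQ


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    """FASTQ with read names sample:true_species:locus:pos (constant Q40)."""
    qual = "I" * readset.read_length
    with open(path, "w") as fh:
        for name, seq in zip(readset.read_names(), readset.read_strings()):
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> tuple[list[str], list[str]]:
    """Read names and sequences; validates record structure."""
    names, seqs = [], []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
    except ValueError as exc:
        raise SchemaError(f"{path}: malformed FASTQ near record {len(names) + 1}: {exc}") from exc
    return names, seqs


# ---------------------------------------------------------------- TSV


def write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, str] | None = None) -> None:
    """TSV with `#`-prefixed metadata lines before the header."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    return df
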