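"""Readers and writers: FASTA/NEXUS alignments, Newick trees, TSV traces.

Alignments are parsed with Biopython and validated against the IUPAC
nucleotide alphabet; trees are parsed with dendropy.  Traces are written as
tab-separated values with full-precision floats and ``#``-prefixed
provenance comment lines (seed, configuration hash, package version), so a
trace round-trips bit-identically and a run can be reproduced from its own
header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd
from Bio import SeqIO

from . import __version__
from .likelihood import IUPAC_CODES, PhyloTree

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_trace",
    "read_trace",
    "config_hash",
]

PathLike = Union[str, Path]

_FORMAT_BY_SUFFIX = {
    ".fasta": "fasta", ".fa": "fasta", ".fna": "fasta",
    ".nex": "nexus", ".nexus": "nexus", ".nxs": "nexus",
}


def read_alignment(path: PathLike, format: Optional[str] = None) -> Dict[str, str]:
    """Read a nucleotide alignment as an ordered taxon -> sequence map.

    ``format`` is "fasta" or "nexus"; inferred from the file suffix when
    omitted.  Sequences are upper-cased and checked against the IUPAC
    alphabet; duplicate taxon names and ragged rows are rejected.
    """
    path = Path(path)
    if format is None:
        format = _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "fasta")
    if format not in ("fasta", "nexus"):
        raise ValueError(f"unsupported alignment format {format!r}")
    out: Dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), format):
        name = rec.id
        if name in out:
            raise ValueError(f"duplicate taxon name {name!r} in {path}")
        seq = str(rec.seq).upper()
        for col, c in enumerate(seq):
            if c not in IUPAC_CODES:
                raise ValueError(
                    f"illegal symbol {c!r} at column {col + 1} of sequence {name!r} in {path}"
                )
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(f"ragged alignment in {path}: {name!r} has length {len(seq)} != {length}")
        out[name] = seq
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_alignment(alignment: Dict[str, str], path: PathLike) -> None:
    """Write an alignment as FASTA."""
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_tree(path: PathLike) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    return PhyloTree.from_newick(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for provenance headers."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_trace(
    trace: pd.DataFrame,
    path: PathLike,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Write a trace as TSV with provenance comment lines and full precision."""
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    with open(path, "w") as fh:
        fh.write(f"# modeljump {__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        trace.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trace(path: PathLike) -> pd.DataFrame:
    """Read a TSV trace written by :func:`write_trace`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "model" in df.columns:  # model codes are strings, not integers
        df["model"] = df["model"].astype(str)
    return df
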