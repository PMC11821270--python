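"""Readers and writers for the tab-separated interchange tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pair_dataset import PairRecord, ProteinRecord

__all__ = ["read_pairs", "read_proteins", "read_embeddings", "write_report_table"]


def read_pairs(path) -> list:
    """Read a pair table (id1, id2, tm_score, snn_score[, seq_identity])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pair table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"id1", "id2", "tm_score", "snn_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_identity = "seq_identity" in df.columns
    return [
        PairRecord(
            id1=str(row.id1),
            id2=str(row.id2),
            tm_score=float(row.tm_score),
            snn_score=float(row.snn_score),
            seq_identity=float(row.seq_identity) if has_identity else 0.0,
        )
        for row in df.itertuples()
    ]


def read_proteins(path) -> list:
    """Read protein metadata (protein, length, identity_to_reference, plddt, ptm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"protein table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"protein", "length", "identity_to_reference", "plddt", "ptm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    truncated = "truncated" in df.columns
    return [
        ProteinRecord(
            protein=str(row.protein),
            length=int(row.length),
            identity_to_reference=float(row.identity_to_reference),
            plddt=float(row.plddt),
            ptm=float(row.ptm),
            truncated=bool(row.truncated) if truncated else False,
        )
        for row in df.itertuples()
    ]


def read_embeddings(path):
    """Read embeddings as protein-ID followed by tab-separated vector entries."""
    from .predictions import EmbeddingTable

    vectors = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0] == "protein":
                continue
            vectors[parts[0]] = [float(x) for x in parts[1:]]
    if not vectors:
        raise ValueError(f"no embeddings read from {path}")
    return EmbeddingTable(vectors=vectors)


def write_report_table(reports, path) -> pd.DataFrame:
    """Flat per-method summary table (one row per MetricReport)."""
    df = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
    return df
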