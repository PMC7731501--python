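"""Plain-text readers and writers for all pipeline tables.

Counts/lengths/metadata are tab-separated with a header row; soil tables
are CSV; GO input is either an OBO subset or a 2-column child/parent edge
TSV plus a gene/term annotation TSV.  Everything written here re-parses
through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GODag
from .normalization import CountMatrix


def read_counts(counts_tsv: str | Path, lengths_tsv: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0)
    if "length_bp" not in lengths.columns:
        raise ValueError("lengths table needs a length_bp column")
    lengths = lengths["length_bp"].reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"lengths missing for transcripts: {missing}")
    return CountMatrix(
        transcript_ids=list(counts.index.astype(str)),
        sample_ids=list(counts.columns.astype(str)),
        counts=counts.to_numpy(),
        lengths=lengths.to_numpy(),
    )


def write_counts(
    cm: CountMatrix, counts_tsv: str | Path, lengths_tsv: str | Path
) -> None:
    cm.to_frame().rename_axis("transcript").to_csv(counts_tsv, sep="\t")
    pd.DataFrame(
        {"length_bp": cm.lengths}, index=pd.Index(cm.transcript_ids, name="transcript")
    ).to_csv(lengths_tsv, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "taxon", "zone"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_soil(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_soil(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("site").to_csv(path)


def read_go(path: str | Path) -> GODag:
    """Load a GO DAG from an OBO subset or a child/parent edge TSV."""
    path = Path(path)
    if path.suffix == ".obo":
        return GODag.from_obo(str(path))
    edges = pd.read_csv(path, sep="\t")
    if edges.shape[1] < 2:
        raise ValueError("edge table needs child and parent columns")
    return GODag.from_edges(
        list(zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str)))
    )


def write_go_edges(dag: GODag, path: str | Path) -> None:
    pd.DataFrame(dag.graph.edges(), columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    ann = pd.read_csv(path, sep="\t")
    if not {"gene", "term"}.issubset(ann.columns):
        raise ValueError("annotation table needs gene and term columns")
    out: dict[str, set[str]] = {}
    for gene, term in zip(ann["gene"].astype(str), ann["term"].astype(str)):
        out.setdefault(gene, set()).add(term)
    return out


def write_annotations(direct: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"gene": g, "term": t} for g in sorted(direct) for t in sorted(direct[g])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)
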