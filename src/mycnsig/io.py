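"""On-disk formats: expression TSV, sample-annotation TSV, role-annotated
gene-set TSV, SIF interaction files.

All writers emit a canonical dialect (UTF-8, tab separator, ``\\n`` line ends,
no quoting, case-sensitive ids) so that write-then-read round-trips are
byte-identical. Loaders validate on entry and raise :class:`FormatError`
naming the first offending line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleTable",
    "PathwayDB",
    "ALLOWED_ARR_WEIGHTS",
    "SIGN_TOKENS",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_pathway_db",
    "write_pathway_db",
    "read_network",
    "read_sif",
    "write_sif",
]


class FormatError(ValueError):
    """A file failed validation; the message names the location."""


#: legal activator/repressor role weights inside a pathway record
ALLOWED_ARR_WEIGHTS = (-1.0, -0.5, 0.5, 1.0)

#: interaction-sign vocabulary; extensible by passing ``sign_tokens`` to
#: :func:`read_sif` — unknown tokens are rejected, never guessed.
SIGN_TOKENS: dict[str, int] = {"activates": 1, "inhibits": -1}

MYCN_STATUSES = ("amplified", "wild_type", "unknown")
GROUPS = ("tumor", "control")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples of linear-scale intensities.

    ``data`` is a dense DataFrame indexed by gene id with sample-id columns;
    ``platform`` is a free-text tag carried through the pipeline.
    """

    data: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.data.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value for gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )


def _parse_matrix_lines(lines: list[str], path: str) -> pd.DataFrame:
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    n_cols = len(header)
    index, rows = [], []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        index.append(gene)
    return pd.DataFrame(rows, index=index, columns=sample_ids, dtype=float)


def read_expression(path: str | Path, platform: str = "") -> ExpressionMatrix:
    """Load a genes-x-samples TSV (header row = sample ids, first column =
    gene/probe ids, decimal point '.')."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    frame = _parse_matrix_lines(lines, str(path))
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"{path}:1: duplicate sample id {dup!r}")
    return ExpressionMatrix(frame, platform=platform)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
    for gene, row in zip(matrix.gene_ids, matrix.data.to_numpy()):
        buf.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample annotations: MYCN status, tumor/control group, cohort id."""

    data: pd.DataFrame  # columns: sample_id, mycn_status, group, cohort

    REQUIRED = ("sample_id", "mycn_status", "group", "cohort")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample table missing columns {missing}")
        if self.data["sample_id"].duplicated().any():
            dup = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        bad = ~self.data["mycn_status"].isin(MYCN_STATUSES)
        if bad.any():
            row = self.data[bad].iloc[0]
            raise FormatError(
                f"sample {row['sample_id']!r}: unknown mycn_status {row['mycn_status']!r}"
            )
        bad = ~self.data["group"].isin(GROUPS)
        if bad.any():
            row = self.data[bad].iloc[0]
            raise FormatError(
                f"sample {row['sample_id']!r}: unknown group {row['group']!r}"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def tumor_samples(self) -> list[str]:
        return list(self.data.loc[self.data["group"] == "tumor", "sample_id"])

    def control_samples(self, label: str | None = None) -> list[str]:
        mask = self.data["group"] == "control"
        if label is not None:
            mask &= self.data["cohort"] == label
        return list(self.data.loc[mask, "sample_id"])

    def screening_samples(self) -> pd.DataFrame:
        """Tumor samples with established MYCN status; 'unknown' excluded."""
        mask = (self.data["group"] == "tumor") & (self.data["mycn_status"] != "unknown")
        return self.data[mask].reset_index(drop=True)

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        status = self.data.set_index("sample_id")["mycn_status"].reindex(sample_ids)
        if status.isna().any():
            raise FormatError(f"unannotated sample {status.index[status.isna()][0]!r}")
        return (status == "amplified").to_numpy()


def read_samples(path: str | Path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(frame)


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Pathway databases
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """Named gene sets with signed activator/repressor role (ARR) weights.

    One record per (pathway, gene) pair; arr_weight in ``ALLOWED_ARR_WEIGHTS``.
    """

    records: pd.DataFrame  # columns: pathway, gene, arr

    def __post_init__(self) -> None:
        missing = [c for c in ("pathway", "gene", "arr") if c not in self.records.columns]
        if missing:
            raise FormatError(f"pathway db missing columns {missing}")
        self.records = self.records.reset_index(drop=True)
        dup = self.records.duplicated(subset=["pathway", "gene"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise FormatError(
                f"duplicate record ({row['pathway']!r}, {row['gene']!r})"
            )
        bad = ~self.records["arr"].isin(ALLOWED_ARR_WEIGHTS)
        if bad.any():
            row = self.records[bad].iloc[0]
            raise FormatError(
                f"pathway {row['pathway']!r}, gene {row['gene']!r}: "
                f"arr_weight {row['arr']} not in {ALLOWED_ARR_WEIGHTS}"
            )

    @property
    def pathway_names(self) -> list[str]:
        return list(dict.fromkeys(self.records["pathway"]))

    def members(self, pathway: str) -> dict[str, float]:
        """Gene -> ARR weight for one pathway."""
        sub = self.records[self.records["pathway"] == pathway]
        if sub.empty:
            raise KeyError(f"unknown pathway {pathway!r}")
        return dict(zip(sub["gene"], sub["arr"]))

    def gene_sets(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for pathway, sub in self.records.groupby("pathway", sort=False):
            out[pathway] = dict(zip(sub["gene"], sub["arr"]))
        return out


def read_pathway_db(path: str | Path) -> PathwayDB:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].rstrip("\n").split("\t") != ["pathway", "gene", "arr"]:
        raise FormatError(f"{path}:1: expected header 'pathway\\tgene\\tarr'")
    recs = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        try:
            arr = float(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric arr_weight {fields[2]!r}") from None
        if arr not in ALLOWED_ARR_WEIGHTS:
            raise FormatError(
                f"{path}:{lineno}: arr_weight {arr} not in {ALLOWED_ARR_WEIGHTS}"
            )
        recs.append((fields[0], fields[1], arr))
    return PathwayDB(pd.DataFrame(recs, columns=["pathway", "gene", "arr"]))


def write_pathway_db(db: PathwayDB, path: str | Path) -> None:
    buf = ["pathway\tgene\tarr"]
    for _, row in db.records.iterrows():
        buf.append(f"{row['pathway']}\t{row['gene']}\t{row['arr']:g}")
    Path(path).write_text("\n".join(buf) + "\n", encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# Interaction networks (SIF)
# ---------------------------------------------------------------------------

def read_sif(
    path: str | Path,
    name: str | None = None,
    sign_tokens: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Load one SIF-like file (source, sign-token, target) into an undirected
    graph with ``sign`` (+1/-1) and ``provenance`` edge attributes.

    Signs are retained for rendering; path finding treats the graph as
    undirected. Self-loops and unknown sign tokens are rejected.
    """
    tokens = dict(SIGN_TOKENS if sign_tokens is None else sign_tokens)
    name = name if name is not None else Path(path).stem
    graph = nx.Graph(name=name)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        src, token, dst = fields
        if token not in tokens:
            raise FormatError(f"{path}:{lineno}: unknown sign token {token!r}")
        if src == dst:
            raise FormatError(f"{path}:{lineno}: self-loop on {src!r} rejected")
        graph.add_edge(src, dst, sign=tokens[token], provenance=(name,))
    return graph


def read_network(paths: Iterable[str | Path]) -> list[nx.Graph]:
    return [read_sif(p) for p in paths]


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    """Write edges in sorted order; ambiguous signs (0) use token 'interacts'."""
    reverse = {1: "activates", -1: "inhibits", 0: "interacts"}
    lines = []
    for u, v, data in sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        a, b = sorted((u, v))
        lines.append(f"{a}\t{reverse[data.get('sign', 0)]}\t{b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8", newline="")
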