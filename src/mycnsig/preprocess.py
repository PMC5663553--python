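"""Probe-level cleanup and normalization for experimental-style microarray
data: drop non-positive probes, quantile-normalize, collapse replicate probes
to genes by geometric averaging.

The default pipeline order is drop_nonpositive -> quantile_normalize (probe
level) -> collapse_probes; the order of the last two steps is configurable
because replicate averaging before vs after normalization is a genuinely open
choice for on-chip replicate designs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FormatError

__all__ = [
    "drop_nonpositive",
    "collapse_probes",
    "quantile_normalize",
    "read_probe_map",
    "run_preprocess",
]

log = logging.getLogger(__name__)


def drop_nonpositive(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove probe rows containing any value <= 0.

    Strongly under-expressed probes produce unreliable (even negative)
    intensities on subtractive platforms; rows carrying any such value are
    omitted wholesale.
    """
    keep = (matrix.data > 0).all(axis=1)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all rows contain non-positive values; nothing left")
    if n_dropped:
        log.info("drop_nonpositive: removed %d of %d rows", n_dropped, len(keep))
    return ExpressionMatrix(matrix.data.loc[keep], platform=matrix.platform)


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Geometric mean of each gene's probe rows, per sample.

    Every probe id must map to exactly one gene; values must be strictly
    positive (the geometric mean is undefined otherwise).
    """
    missing = [p for p in matrix.gene_ids if p not in probe_map]
    if missing:
        raise KeyError(f"probe ids missing from probe map: {missing[:5]}")
    if (matrix.data.to_numpy() <= 0).any():
        raise ValueError("non-positive value reached collapse_probes; run drop_nonpositive first")
    genes = pd.Index([probe_map[p] for p in matrix.gene_ids], name="gene_id")
    relabelled = matrix.data.set_index(genes)
    logged = np.log(relabelled)
    grouped = logged.groupby(level=0, sort=False)
    collapsed = np.exp(grouped.mean())
    # single-probe genes pass through exactly (no log/exp round-trip error)
    singles = grouped.size() == 1
    if singles.any():
        single_rows = relabelled.loc[singles[singles].index]
        collapsed.loc[singles[singles].index] = single_rows
    return ExpressionMatrix(collapsed, platform=matrix.platform)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common distribution of mean order
    statistics, preserving within-column ranks.

    Tied values within a column receive the mean of the reference values over
    their tied rank span (the standard deterministic tie rule).
    """
    values = matrix.data.to_numpy(dtype=float)
    n_rows, n_cols = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    order = np.argsort(values, axis=0, kind="stable")
    for j in range(n_cols):
        col = values[:, j]
        idx = order[:, j]
        ranked = col[idx]
        assigned = reference.copy()
        # average the reference over each span of tied input values
        start = 0
        for end in range(1, n_rows + 1):
            if end == n_rows or ranked[end] != ranked[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[idx, j] = assigned

    frame = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, platform=matrix.platform)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_id); every probe maps to one gene."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["probe_id", "gene_id"]:
        raise FormatError(f"{path}: expected columns probe_id, gene_id")
    if frame["probe_id"].duplicated().any():
        dup = frame.loc[frame["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: probe {dup!r} maps to more than one gene")
    return dict(zip(frame["probe_id"], frame["gene_id"]))


def run_preprocess(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str] | None = None,
    skip_quantile: bool = False,
    collapse_first: bool = False,
) -> ExpressionMatrix:
    """Full probe-to-gene pipeline; step order configurable."""
    matrix = drop_nonpositive(matrix)
    if collapse_first and probe_map is not None:
        matrix = collapse_probes(matrix, probe_map)
    if not skip_quantile:
        matrix = quantile_normalize(matrix)
    if not collapse_first and probe_map is not None:
        matrix = collapse_probes(matrix, probe_map)
    return matrix
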