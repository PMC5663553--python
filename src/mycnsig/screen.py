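"""ROC-AUC marker screening: score every gene or pathway as a classifier of
MYCN amplification and gate on a single AUC threshold.

The AUC here is the Mann-Whitney probability that a randomly chosen amplified
sample's value exceeds a randomly chosen non-amplified one's (ties count
half). Because markers can move in either direction, gating uses the oriented
AUC max(AUC, 1-AUC) with the winning direction recorded per feature. No
multiple-testing correction is applied at this stage: error control comes
from the cross-cohort intersection and its simulation null.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, SampleTable

__all__ = ["auc_score", "drop_constant_features", "screen"]

log = logging.getLogger(__name__)


def auc_score(values: Sequence[float], labels: Sequence[bool]) -> tuple[float, float, str]:
    """(raw_auc, oriented_auc, direction) for one feature.

    raw_auc = P(random positive value > random negative value) + 0.5 *
    P(equal), computed from midranks. Requires both classes present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    ranks = rankdata(values)  # midranks implement the tie-half convention
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    raw = u / (n_pos * n_neg)
    oriented = max(raw, 1.0 - raw)
    direction = "up_in_amplified" if raw >= 0.5 else "down_in_amplified"
    return float(raw), float(oriented), direction


def drop_constant_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove rows identical across all samples (zero-information features)."""
    values = matrix.to_numpy()
    keep = ~(values == values[:, :1]).all(axis=1) if values.shape[1] else np.ones(len(matrix), bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("drop_constant_features: removed %d constant rows", n_dropped)
    out = matrix.loc[keep]
    if out.empty:
        log.warning("drop_constant_features: no non-constant features remain")
    return out


def screen(
    matrix: pd.DataFrame | ExpressionMatrix,
    samples: SampleTable,
    threshold: float = 0.8,
    level: str = "gene",
) -> pd.DataFrame:
    """Score every non-constant feature row against MYCN status.

    Returns a MarkerTable frame with one record per feature: raw and oriented
    AUC, direction, and whether the oriented AUC passes the gate. Samples
    with unknown MYCN status and control samples are excluded before scoring.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"AUC threshold must lie in (0.5, 1], got {threshold}")
    frame = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix

    screening = samples.screening_samples()
    cols = [s for s in screening["sample_id"] if s in frame.columns]
    labels = samples.labels_for(cols)
    if labels.all() or not labels.any():
        raise ValueError("screening requires both amplified and wild-type samples")

    data = drop_constant_features(frame[cols])
    values = data.to_numpy(dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos

    # vectorised midrank AUC over all rows at once
    ranks = rankdata(values, axis=1)
    u = ranks[:, labels].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    raw = u / (n_pos * n_neg)
    oriented = np.maximum(raw, 1.0 - raw)

    table = pd.DataFrame(
        {
            "feature_id": data.index,
            "level": level,
            "raw_auc": raw,
            "auc": oriented,
            "direction": np.where(raw >= 0.5, "up_in_amplified", "down_in_amplified"),
            "passed": oriented >= threshold,
        }
    ).reset_index(drop=True)
    return table


def passed_features(table: pd.DataFrame) -> list[str]:
    return sorted(table.loc[table["passed"], "feature_id"])
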