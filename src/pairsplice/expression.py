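"""RPKM expression normalization and group-level distribution summaries.

Reads-per-kilobase-per-million (RPKM) for a feature with C mapped reads,
length L nt, out of N total mapped reads is 1e9 * C / (N * L).  Group
summaries compare AS genes, all sense transcripts, and labelled antisense
transcripts on the log2(RPKM + 1) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    mapped_reads: int
    length: int
    rpkm: float


def rpkm(count: float, length: int, total_mapped: float) -> float:
    """Exact RPKM; no pseudocount."""
    if length <= 0:
        raise ValidationError("feature length must be positive")
    if total_mapped <= 0:
        raise ValidationError("total mapped reads must be positive")
    return 1e9 * count / (total_mapped * length)


def rpkm_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rpkm`` column to a (feature_id, mapped_reads, length) table.

    ``total_mapped`` is the column sum of ``mapped_reads``.
    """
    total = float(counts["mapped_reads"].sum())
    out = counts.copy()
    out["rpkm"] = [
        rpkm(c, l, total) for c, l in zip(out["mapped_reads"], out["length"])
    ]
    return out


def group_distribution_summary(
    records: pd.DataFrame,
    groups: dict[str, set[str]],
    log_offset: float = 1.0,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/quartile summary and binned distribution of log2(RPKM+offset).

    ``groups`` maps a label (e.g. AS / all / antisense) to the feature ids
    it contains.  Empty groups are omitted with a logged notice.  Returns
    (summary table, binned distribution table with per-group percentages).
    """
    rec = records.set_index("feature_id")
    logx = {}
    for label, ids in groups.items():
        present = [i for i in ids if i in rec.index]
        if not present:
            logger.info("expression group %r is empty; row omitted", label)
            continue
        logx[label] = np.log2(rec.loc[present, "rpkm"].to_numpy(dtype=float) + log_offset)
    rows = []
    for label, x in logx.items():
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append(
            {
                "group": label,
                "n": x.size,
                "median_log2_rpkm": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
            }
        )
    summary = pd.DataFrame(rows, columns=["group", "n", "median_log2_rpkm", "q1", "q3", "iqr"])

    if logx:
        allx = np.concatenate(list(logx.values()))
        edges = np.linspace(allx.min(), allx.max() + 1e-9, n_bins + 1)
        dist_rows = []
        for label, x in logx.items():
            hist, _ = np.histogram(x, bins=edges)
            for b in range(n_bins):
                dist_rows.append(
                    {
                        "group": label,
                        "bin_lo": edges[b],
                        "bin_hi": edges[b + 1],
                        "count": int(hist[b]),
                        "pct": 100.0 * hist[b] / x.size,
                    }
                )
        dist = pd.DataFrame(dist_rows)
    else:
        dist = pd.DataFrame(columns=["group", "bin_lo", "bin_hi", "count", "pct"])
    return summary, dist
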