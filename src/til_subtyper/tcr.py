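"""TCR repertoire preprocessing and Shannon-entropy diversity.

Clonotype tables are AIRR-like long frames (sample_id, chain, cdr3,
umi_count) covering the four canonical chains TRA/TRB/TRD/TRG.  Clonotype
calls are first filtered on UMI support (default minimum 7, stricter than
the library kit's recommended 5, to suppress false-positive CDR3 calls);
diversity is then the Shannon entropy of the post-filter UMI frequency
distribution per (sample, chain), in nats by default.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MIN_UMI",
    "filter_clonotypes",
    "shannon_entropy",
    "read_airr_tsv",
    "write_airr_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_UMI = 7
_COLUMNS = ["sample_id", "chain", "cdr3", "umi_count"]
VALID_CHAINS = ("TRA", "TRB", "TRD", "TRG")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clonotype table is missing columns: {missing}")
    if len(table) and (table["umi_count"] < 1).any():
        raise ValueError("umi_count must be >= 1 for every clonotype")
    if table.duplicated(subset=["sample_id", "chain", "cdr3"]).any():
        raise ValueError("(sample_id, chain, cdr3) rows must be unique")


def filter_clonotypes(
    table: pd.DataFrame, min_umi: int = DEFAULT_MIN_UMI
) -> pd.DataFrame:
    """Drop clonotypes with UMI support below ``min_umi``.

    The threshold is recorded in ``DataFrame.attrs['min_umi']``.  An empty
    result is allowed.
    """
    if min_umi < 1:
        raise ValueError(f"min_umi must be >= 1, got {min_umi}")
    _check_table(table)
    out = table[table["umi_count"] >= min_umi].reset_index(drop=True)
    out.attrs["min_umi"] = min_umi
    return out


def shannon_entropy(
    table: pd.DataFrame, base: str = "nats", normalized: bool = False
) -> pd.DataFrame:
    """Shannon entropy of UMI frequencies per (sample, chain).

    H = -sum p_i log p_i with p_i = umi_i / sum(umi); natural-log units by
    default (``base='bits'`` for log2).  ``normalized`` divides by
    log(richness) (Pielou evenness; 0 for a single clonotype).  Sample/chain
    combinations absent from the table are simply absent from the output;
    callers treat them as missing.
    """
    _check_table(table)
    log = np.log if base == "nats" else np.log2
    rows = []
    for (sample_id, chain), grp in table.groupby(["sample_id", "chain"], sort=True):
        counts = grp["umi_count"].to_numpy(dtype=float)
        p = counts / counts.sum()
        h = float(-(p * log(p)).sum())
        if normalized:
            h = h / float(log(len(p))) if len(p) > 1 else 0.0
        rows.append((sample_id, chain, h, len(p), int(counts.sum())))
    if not rows:
        logger.warning("no clonotypes left after filtering; entropy table empty")
    return pd.DataFrame(
        rows, columns=["sample_id", "chain", "entropy", "n_clonotypes", "total_umi"]
    )


def read_airr_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _check_table(table)
    return table


def write_airr_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[_COLUMNS].to_csv(path, sep="\t", index=False)
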