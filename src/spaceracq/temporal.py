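"""Expression normalization and early/middle/late temporal classification.

A gene's class follows the sign pattern of two log10 fold changes between
successive timepoints, LogFC_XvsY = log10 A(Y) − log10 A(X) on normalized
abundances A:

* early:  LogFC_30vs50 < 0 (abundance maximum before 30 min, then decline)
* middle: LogFC_30vs50 > 0 and LogFC_50vs70 < 0 (peak between 30 and 50 min)
* late:   LogFC_50vs70 > 0 (still rising after 50 min)

Rules are applied in that order; a gene satisfying none (both LogFC exactly
zero) is left unclassified. Strict inequalities are kept — exact zeros are
not forced into a class.

Normalization is either ``tpm`` (length-aware: count/length rates scaled to
a million) or ``cpm`` (total-count scaling only); both are provided because
"normalized to total counted reads" admits either reading, and the mode is
recorded in every output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_TIMEPOINTS = (30, 50, 70)


def normalize_abundance(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
    mode: str = "tpm",
) -> pd.DataFrame:
    """Per-column normalization of a genes x timepoints count matrix.

    ``tpm``: rate = count/length(kb), A = rate / sum(rate) * 1e6;
    ``cpm``: A = count / sum(count) * 1e6. Columns sum to 1e6 either way.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    zero_cols = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_cols):
        raise ValueError(f"all-zero count column at timepoint {zero_cols[0]}")
    if mode == "tpm":
        if gene_lengths is None:
            raise ValueError("tpm normalization requires gene lengths")
        lengths = gene_lengths.reindex(counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("every gene needs a positive length for tpm")
        rate = counts.div(lengths / 1000.0, axis=0)
    elif mode == "cpm":
        rate = counts.astype(float)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = rate / rate.sum(axis=0) * 1e6
    out.attrs["normalization"] = mode
    return out


def logfc(a_x, a_y, pseudocount: float = 1.0):
    """log10(A_y + c) − log10(A_x + c); antisymmetric in its arguments."""
    a_x, a_y = np.asarray(a_x, dtype=float), np.asarray(a_y, dtype=float)
    if (a_x < 0).any() or (a_y < 0).any():
        raise ValueError("abundances must be non-negative")
    if pseudocount == 0 and ((a_x == 0) | (a_y == 0)).any():
        raise ValueError("zero abundance with pseudocount 0")
    res = np.log10(a_y + pseudocount) - np.log10(a_x + pseudocount)
    return float(res) if res.ndim == 0 else res


def assign_temporal_class(logfc_30vs50: float, logfc_50vs70: float) -> str:
    """Apply the class rules in order early -> middle -> late."""
    if logfc_30vs50 < 0:
        return "early"
    if logfc_30vs50 > 0 and logfc_50vs70 < 0:
        return "middle"
    if logfc_50vs70 > 0:
        return "late"
    return "unclassified"


def classify_genes(
    counts_by_replicate: dict[str, pd.DataFrame],
    gene_lengths: pd.Series | None = None,
    mode: str = "tpm",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Normalize each replicate, average abundances, and classify each gene.

    Replicates are combined by averaging normalized abundances before the
    LogFC computation (per-replicate classes are also reported, one column
    per replicate). Raises if timepoints 30/50/70 are missing.
    """
    if not counts_by_replicate:
        raise ValueError("no replicates given")
    norms = {}
    for rep, counts in counts_by_replicate.items():
        missing = [t for t in REQUIRED_TIMEPOINTS if t not in counts.columns]
        if missing:
            raise ValueError(f"replicate {rep}: missing timepoint(s) {missing}")
        norms[rep] = normalize_abundance(counts, gene_lengths, mode)

    mean_a = sum(norms.values()) / len(norms)
    result = pd.DataFrame(index=mean_a.index)
    for t in mean_a.columns:
        result[f"A_{t}"] = mean_a[t]
    result["logfc_30vs50"] = logfc(mean_a[30], mean_a[50], pseudocount)
    result["logfc_50vs70"] = logfc(mean_a[50], mean_a[70], pseudocount)
    result["temporal_class"] = [
        assign_temporal_class(x, y)
        for x, y in zip(result["logfc_30vs50"], result["logfc_50vs70"])
    ]
    for rep, a in norms.items():
        result[f"class_{rep}"] = [
            assign_temporal_class(
                logfc(a.loc[g, 30], a.loc[g, 50], pseudocount),
                logfc(a.loc[g, 50], a.loc[g, 70], pseudocount),
            )
            for g in a.index
        ]
    result.attrs["normalization"] = mode
    return result


def heatmap_rows(abundance: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Each row scaled by its own maximum (so the max is exactly 1).

    Zero-expression genes come back as all-zero rows and are listed in the
    returned flag list.
    """
    maxima = abundance.max(axis=1)
    flagged = list(abundance.index[maxima == 0])
    safe = maxima.replace(0, 1.0)
    return abundance.div(safe, axis=0), flagged
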