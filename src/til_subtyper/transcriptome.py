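"""Expression-based characterization: signatures, centroids, immunograms.

Three consumers of a TPM matrix (genes x samples):

* **Signature scores** — mean across the gene set of per-gene z-scores of
  log2(TPM + 1) across samples (the package default; the reduction is
  swappable).
* **Molecular-subtype assignment** — log(TPM + 1), per-gene median centering
  across the cohort, then Pearson correlation of each sample against
  nearest-centroid predictor profiles; the centroid with the largest
  correlation wins.  The log base cancels in the correlation after median
  centering, so labels are base-invariant.
* **Immunograms** — eight cancer-immunity-cycle axes scored 0-5 by cohort
  rank percentile of an axis signature.  Axes 1-5 (T-cell immunity, tumor
  antigenicity, priming/activation, trafficking/infiltration, tumor-cell
  recognition) score high when the signature is high; axes 6-8 (inhibitory
  cells, checkpoint expression, inhibitory molecules) are inverted so
  immunosuppressive features score low.  Axis 2 (tumor antigenicity) needs
  neoantigen input and is emitted as not-computed unless a gene set is
  supplied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "signature_score",
    "assign_molecular_subtype",
    "compute_immunogram",
    "DEFAULT_IMMUNOGRAM_AXES",
    "IMMUNOGRAM_AXIS_NAMES",
]


def _check_expr(expr: pd.DataFrame) -> None:
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative entries")
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")


def signature_score(expr: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Mean per-gene z-score of log2(TPM+1) over the gene set, per sample.

    Genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.  Genes constant across samples contribute 0.
    """
    _check_expr(expr)
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score across the cohort")
    present = [g for g in gene_set if g in expr.index]
    missing = [g for g in gene_set if g not in expr.index]
    if not present:
        raise ValueError(
            f"no gene of the set is present in the expression matrix; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(f"genes absent from expression matrix: {missing}",
                      stacklevel=2)
    logx = np.log2(expr.loc[present] + 1.0)
    mu = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=1)
    z = logx.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0).rename("signature_score")


def assign_molecular_subtype(
    expr: pd.DataFrame,
    centroids: pd.DataFrame,
    min_overlap: int = 10,
    log_base: str = "natural",
) -> pd.DataFrame:
    """Nearest-centroid molecular subtype per sample.

    TPM+1 values are log transformed and gene median centered across the
    cohort; each sample is Pearson-correlated with every centroid over the
    shared genes and assigned the argmax.  Ties (including the degenerate
    all-correlations-undefined case) go to the first centroid column with a
    warning.  Returns a frame with a ``label`` column plus one correlation
    column per centroid subtype.
    """
    _check_expr(expr)
    if centroids.shape[1] < 2:
        raise ValueError("need >= 2 centroid subtypes")
    shared = expr.index.intersection(centroids.index)
    if len(shared) < min_overlap:
        raise ValueError(
            f"gene overlap with centroids is {len(shared)} < required "
            f"{min_overlap}"
        )
    log = np.log if log_base == "natural" else np.log2
    x = log(expr.loc[shared] + 1.0)
    centered = x.sub(x.median(axis=1), axis=0)
    C = centroids.loc[shared]
    out = {}
    xc = centered.sub(centered.mean(axis=0), axis=1)
    cc = C.sub(C.mean(axis=0), axis=1)
    xn = np.sqrt((xc**2).sum(axis=0))
    cn = np.sqrt((cc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = xc.T.to_numpy() @ cc.to_numpy() / np.outer(xn, cn)
    corr = pd.DataFrame(corr, index=expr.columns, columns=C.columns)
    undefined = corr.isna().all(axis=1)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} sample(s) have undefined correlations "
            "(flat profile); assigned to the first centroid",
            stacklevel=2,
        )
    filled = corr.fillna(-np.inf)
    ties = filled.eq(filled.max(axis=1), axis=0).sum(axis=1) > 1
    if (ties & ~undefined).any():
        warnings.warn("correlation ties broken by centroid column order",
                      stacklevel=2)
    out = corr.copy()
    out.insert(0, "label", filled.idxmax(axis=1))
    return out


IMMUNOGRAM_AXIS_NAMES = {
    "IGS1": "T-cell immunity",
    "IGS2": "Tumor antigenicity",
    "IGS3": "Priming and activation",
    "IGS4": "Trafficking and infiltration",
    "IGS5": "Recognition of tumor cells",
    "IGS6": "Inhibitory cells",
    "IGS7": "Checkpoint expression",
    "IGS8": "Inhibitory molecules",
}

# Packaged default gene sets are placeholders aligned with the synthetic
# expression generator; users analyzing real cohorts should supply their own
# axis config.  ``inverted`` axes score low when the signature is high.
DEFAULT_IMMUNOGRAM_AXES: dict[str, dict] = {
    "IGS1": {"genes": ["CD8A", "CD3E", "GZMB", "PRF1", "IFNG"], "inverted": False},
    "IGS2": {"genes": None, "inverted": False},  # neoantigen input not modeled
    "IGS3": {"genes": ["IFIT1", "IFIT3", "ISG15", "MX1", "OAS1"], "inverted": False},
    "IGS4": {"genes": ["CCL5", "CXCL9", "CXCL11"], "inverted": False},
    "IGS5": {"genes": ["HLA-A", "B2M", "TAP1", "TAP2"], "inverted": False},
    "IGS6": {"genes": ["CD33", "CD14", "ITGAM", "ARG1"], "inverted": True},
    "IGS7": {"genes": ["PDCD1", "CD274", "HAVCR2", "LAG3", "CTLA4"], "inverted": True},
    "IGS8": {"genes": ["IL10", "TGFB1", "IDO1"], "inverted": True},
}


def compute_immunogram(
    expr: pd.DataFrame,
    axis_config: dict[str, dict] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-sample immunogram vector (samples x IGS1..IGS8, scores in [0, 5]).

    Per axis the signature score is converted to a cohort rank percentile
    (average ranks; min -> 0, max -> 1) and scaled to [0, 5]; inverted axes
    map percentile p to 5 * (1 - p).  Axes without a resolvable gene set are
    emitted as missing (not-computed) unless ``strict``.
    """
    if expr.shape[1] < 3:
        raise ValueError("immunogram scaling needs a cohort of >= 3 samples")
    config = DEFAULT_IMMUNOGRAM_AXES if axis_config is None else axis_config
    out = pd.DataFrame(index=expr.columns, columns=list(config), dtype=float)
    for axis, cfg in config.items():
        genes = cfg.get("genes")
        if not genes:
            if strict:
                raise ValueError(f"axis {axis} has no gene set configured")
            out[axis] = np.nan
            continue
        score = signature_score(expr, genes)
        pct = (score.rank(method="average") - 1.0) / (len(score) - 1.0)
        out[axis] = 5.0 * (1.0 - pct) if cfg.get("inverted") else 5.0 * pct
    return out
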