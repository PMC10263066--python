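"""Dual-representation TIL features: cell density and percent-of-parent.

Two complementary views of the gated counts feed the subtype clustering:

* **cell density** — log10(count / tissue mass in grams + 1) per population,
  capturing absolute infiltration;
* **fractions** — percentages of a parent denominator: %CD45 (per total
  CD45+ leukocytes), %CD4 / %CD8 (per total CD4+ / CD8+ T cells), %myeloid
  (per total myeloid-lineage cells), and percent-of-parent for functional
  overlays (PD-1+, PD-L1+, Ki-67+, CTLA-4+).

The clustering input z-scales the density block and the %CD45 block across
samples (sample standard deviation, n-1) and concatenates them.  Zero
denominators yield missing values, never zeros; constant features z-scale to
0 with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gating import GatingTree, default_gating_tree

__all__ = [
    "cell_density",
    "density_table",
    "fraction_tables",
    "build_feature_matrix",
    "resolve_feature_set",
]


def cell_density(count: int, mass_g: float) -> float:
    """log10(count per gram of tissue + 1)."""
    if mass_g <= 0:
        raise ValueError(f"mass_g must be > 0, got {mass_g}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return float(np.log10(count / mass_g + 1.0))


def density_table(counts: pd.DataFrame, masses: pd.Series) -> pd.DataFrame:
    """Per-sample, per-population cell density (log10 cells/g).

    ``counts`` is the wide samples x populations frame (a ``total_cd45``
    column, if present, is carried through as the total-leukocyte density).
    """
    missing = counts.index.difference(masses.index)
    if len(missing):
        raise ValueError(f"masses missing for samples: {list(missing)}")
    m = masses.loc[counts.index].to_numpy()
    if (m <= 0).any():
        raise ValueError("all masses must be > 0")
    return np.log10(counts.div(m, axis=0) + 1.0)


def _pct(num: pd.DataFrame | pd.Series, denom: pd.Series) -> pd.DataFrame:
    denom = denom.replace(0, np.nan)
    return num.div(denom, axis=0) * 100.0


def fraction_tables(
    counts: pd.DataFrame, tree: GatingTree | None = None
) -> dict[str, pd.DataFrame]:
    """Percent-of-denominator tables from gated counts.

    Returns ``pct_cd45`` (all base populations per total CD45+), ``pct_cd4``,
    ``pct_cd8``, ``pct_myeloid``, ``pct_nkt`` and ``pct_parent`` (functional
    overlays per their parent population).  Samples with a zero denominator
    get missing values for that table.
    """
    tree = tree or default_gating_tree()
    if "total_cd45" not in counts.columns:
        raise ValueError("counts frame must carry a total_cd45 column")
    by_cat: dict[str, list] = {}
    for p in tree.populations:
        by_cat.setdefault(p.category, []).append(p)
    myeloid_tops = [p.population_id for p in tree.populations if p.myeloid]

    base_pops = [
        p.population_id for p in tree.populations if p.category != "overlay"
    ]
    tables: dict[str, pd.DataFrame] = {}
    tables["pct_cd45"] = _pct(counts[base_pops], counts["total_cd45"])
    for name, cat, denom in (
        ("pct_cd4", "cd4_subset", "cd4_t"),
        ("pct_cd8", "cd8_subset", "cd8_t"),
        ("pct_nkt", "nkt_subset", "nkt"),
    ):
        pops = [p.population_id for p in by_cat.get(cat, [])]
        if pops:
            tables[name] = _pct(counts[pops], counts[denom])
    if myeloid_tops:
        tables["pct_myeloid"] = _pct(
            counts[myeloid_tops], counts[myeloid_tops].sum(axis=1)
        )
    overlays = by_cat.get("overlay", [])
    if overlays:
        cols = {}
        for p in overlays:
            cols[p.population_id] = _pct(
                counts[p.population_id], counts[p.parent_population]
            )
        tables["pct_parent"] = pd.DataFrame(cols)
    n_zero = int(counts["total_cd45"].eq(0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} sample(s) have zero CD45+ events; their fractions are "
            "recorded as missing",
            stacklevel=2,
        )
    return tables


def _zscale(df: pd.DataFrame) -> pd.DataFrame:
    mean = df.mean(axis=0, skipna=True)
    sd = df.std(axis=0, ddof=1, skipna=True)
    constant = sd.isna() | (sd == 0)
    if constant.any():
        warnings.warn(
            f"constant feature(s) z-scaled to 0: {list(df.columns[constant])}",
            stacklevel=3,
        )
    z = df.sub(mean, axis=1).div(sd.where(~constant, 1.0), axis=1)
    z.loc[:, constant] = z.loc[:, constant].where(df.loc[:, constant].isna(), 0.0)
    return z


def resolve_feature_set(
    feature_set: str | list[str], tree: GatingTree
) -> list[str]:
    if isinstance(feature_set, str):
        if feature_set not in tree.feature_presets:
            raise ValueError(
                f"unknown feature preset {feature_set!r}; available: "
                f"{sorted(tree.feature_presets)}"
            )
        return list(tree.feature_presets[feature_set])
    return list(feature_set)


def build_feature_matrix(
    counts: pd.DataFrame,
    masses: pd.Series,
    feature_set: str | list[str] = "fig2",
    tree: GatingTree | None = None,
) -> pd.DataFrame:
    """Combined z-scaled density + %CD45 feature matrix for clustering.

    Scaling is computed across exactly the samples present in ``counts``
    (the scaling cohort is whatever is passed in: tumors alone, or tumors
    plus NATs).  Columns are block-prefixed ``dens_<pop>`` / ``pct_<pop>``;
    per-feature means/sds are stored in ``DataFrame.attrs['scaling']``.
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 samples to scale features across patients")
    tree = tree or default_gating_tree()
    pops = resolve_feature_set(feature_set, tree)
    dens = density_table(counts[pops], masses)
    pct = _pct(counts[pops], counts["total_cd45"])
    raw = pd.concat(
        [dens.add_prefix("dens_"), pct.add_prefix("pct_")], axis=1
    )
    scaling = pd.DataFrame(
        {"mean": raw.mean(axis=0, skipna=True), "sd": raw.std(axis=0, ddof=1)}
    )
    z = _zscale(raw)
    z.attrs["scaling"] = scaling
    z.attrs["feature_set"] = feature_set if isinstance(feature_set, str) else "custom"
    return z
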