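"""Synthetic NSCLC TIL cohorts: cytometry events, expression, TCR, clinical.

The study's raw cytometry and sequencing data are access-controlled, so this
module generates cohorts carrying the statistical structure the analysis
assumes, together with a ground-truth channel that the analysis stages never
read:

* **Cytometry** — per-sample event tables drawn population-by-population from
  independent lognormal marker-intensity mixtures matched to the packaged
  gating thresholds ("positive" modes sit >= 3 sd above the positive
  threshold, "lo" modes between the two thresholds).  Subtype templates plant
  the qualitative composition structure of the three immune subtypes: Cold
  samples carry few CD45+ events (low infiltration), Myeloid samples are
  macrophage / CD14+ monocyte / mMDSC dominant, CD8 samples are T-cell
  dominant; histologically normal adjacent tissue (NAT) has its own
  naive/NK-rich template.
* **Expression** — lognormal TPM with planted CD8-subtype up-shifts for
  effector/chemokine genes (CCL5, CXCL9, CXCL11, IFNG, GZMB, ...) and
  Myeloid-subtype up-shifts for suppressive myeloid genes.
* **TCR repertoires** — symmetric-Dirichlet clonotype abundances per chain
  (TRA/TRB/TRD/TRG); the concentration parameter controls diversity and has a
  closed-form expected Shannon entropy, with CD8 subtypes planted most
  diverse.
* **Clinical outcomes** — exponential event-free survival times with
  independent censoring and per-subtype hazard multipliers (Myeloid worst,
  CD8 best), plus categorical clinicopathologic factors with planted subtype
  associations.

All generators are deterministic given a seed; one cohort seed fans out to
per-sample child streams via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma

from .gating import GatingTree, default_gating_tree

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "SyntheticTruth",
    "Cohort",
    "CompositionProfile",
    "PROFILES",
    "TEMPLATES",
    "default_cohort_spec",
    "profile_population_specs",
    "simulate_fcm_sample",
    "simulate_cohort",
    "simulate_expression",
    "simulate_tcr",
    "simulate_clinical",
    "expected_clone_entropy",
    "write_cohort",
    "DEFAULT_GENE_EFFECTS",
    "DEFAULT_RICHNESS",
    "DEFAULT_HAZARDS",
]

# ---------------------------------------------------------------------------
# intensity scale shared with the packaged gating config (log10 a.u.)

_LEVEL_MEANS = {"neg": 1.0, "lo": 2.0, "pos": 3.0}
_MARKER_SD = 0.12
_SSC_BASE, _SSC_HI, _SSC_SD = 4.0, 4.5, 0.07
_FSC_MEAN, _FSC_SD = 4.6, 0.08
_VIAB_LIVE, _VIAB_DEAD = 1.0, 3.0


@dataclass(frozen=True)
class PopulationSpec:
    """One lognormal mixture component: marker means/sds and mixture weight."""

    population_id: str
    mean_log_intensity: dict[str, float]
    sd_log_intensity: dict[str, float]
    expected_fraction_of_events: float


@dataclass
class CohortSpec:
    """Cohort layout: (histology, subtype, n) groups plus acquisition scale."""

    groups: list[tuple[str, str, int]]
    events_per_sample: int = 12000
    mass_mean_g: float = 0.5
    mass_sd_g: float = 0.2
    dead_fraction: float = 0.08
    epithelial_fraction: float = 0.2  # floor; low infiltration adds more
    composition_concentration: float = 150.0
    split_concentration: float = 300.0
    immune_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for histology, subtype, n in self.groups:
            if n < 1:
                raise ValueError(
                    f"group ({histology}, {subtype}) needs n_samples >= 1, got {n}"
                )
        if not 0 <= self.dead_fraction < 1 or not 0 <= self.epithelial_fraction < 1:
            raise ValueError("contamination fractions must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, n in self.groups)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a cohort; never read by analysis stages."""

    labels: pd.DataFrame  # sample_id, histology, subtype
    population_counts: pd.DataFrame  # samples x (30 populations + total_cd45)
    expected_fractions: pd.DataFrame  # planted per-sample %CD45-scale fractions
    masses: pd.Series
    signature_effects: dict | None = None
    tcr_config: dict | None = None
    hazard_multipliers: dict | None = None


# ---------------------------------------------------------------------------
# composition templates


@dataclass
class CompositionProfile:
    """Planted composition for one sample group (fractions of CD45+ events)."""

    name: str
    immune_fraction: float
    top: dict[str, float]
    nkt_split: dict[str, float]
    cd4_split: dict[str, float]
    cd8_split: dict[str, float]
    overlays: dict[str, float]


_TUMOR_NKT = {"dn": 0.40, "cd4": 0.25, "cd8": 0.35}
_TUMOR_CD4 = {
    "naive": 0.11, "cm": 0.21, "em": 0.34, "emra": 0.09,
    "fr1": 0.05, "fr2": 0.12, "fr3": 0.08,
}
_NAT_CD4 = {
    "naive": 0.35, "cm": 0.22, "em": 0.15, "emra": 0.12,
    "fr1": 0.06, "fr2": 0.04, "fr3": 0.06,
}
_TUMOR_CD8 = {"naive": 0.10, "cm": 0.20, "em": 0.55, "emra": 0.15}
_NAT_CD8 = {"naive": 0.40, "cm": 0.20, "em": 0.25, "emra": 0.15}

_BASE_OVERLAYS = {
    "ki67_t": 0.15, "ki67_b": 0.10, "ki67_nk": 0.10, "ki67_mmdsc": 0.20,
    "pd1_cd4": 0.25, "pd1_cd8": 0.30, "pdl1_cd8": 0.10, "pdl1_mmdsc": 0.30,
    "ctla4_etreg": 0.50,
}

PROFILES: dict[str, CompositionProfile] = {
    "Cold": CompositionProfile(
        name="Cold",
        immune_fraction=0.08,
        top={
            "cd4_t": 0.24, "cd8_t": 0.16, "nkt": 0.04, "b_cells": 0.06,
            "nk_cells": 0.07, "cdc": 0.03, "pdc": 0.01, "macrophage": 0.22,
            "mmdsc": 0.06, "cd14_monocyte": 0.11,
        },
        nkt_split=_TUMOR_NKT, cd4_split=_TUMOR_CD4, cd8_split=_TUMOR_CD8,
        overlays={**_BASE_OVERLAYS, "pd1_cd8": 0.20},
    ),
    "Myeloid": CompositionProfile(
        name="Myeloid",
        immune_fraction=0.45,
        top={
            "cd4_t": 0.13, "cd8_t": 0.09, "nkt": 0.03, "b_cells": 0.04,
            "nk_cells": 0.05, "cdc": 0.04, "pdc": 0.015, "macrophage": 0.33,
            "mmdsc": 0.135, "cd14_monocyte": 0.17,
        },
        nkt_split=_TUMOR_NKT, cd4_split=_TUMOR_CD4, cd8_split=_TUMOR_CD8,
        overlays={**_BASE_OVERLAYS, "pdl1_mmdsc": 0.35},
    ),
    "CD8": CompositionProfile(
        name="CD8",
        immune_fraction=0.42,
        top={
            "cd4_t": 0.27, "cd8_t": 0.30, "nkt": 0.04, "b_cells": 0.10,
            "nk_cells": 0.07, "cdc": 0.03, "pdc": 0.01, "macrophage": 0.10,
            "mmdsc": 0.02, "cd14_monocyte": 0.06,
        },
        nkt_split=_TUMOR_NKT, cd4_split=_TUMOR_CD4,
        cd8_split={"naive": 0.08, "cm": 0.22, "em": 0.58, "emra": 0.12},
        overlays={**_BASE_OVERLAYS, "pd1_cd8": 0.45, "ki67_t": 0.20},
    ),
    "NAT": CompositionProfile(
        name="NAT",
        immune_fraction=0.30,
        top={
            "cd4_t": 0.28, "cd8_t": 0.22, "nkt": 0.05, "b_cells": 0.09,
            "nk_cells": 0.14, "cdc": 0.03, "pdc": 0.015, "macrophage": 0.10,
            "mmdsc": 0.005, "cd14_monocyte": 0.07,
        },
        nkt_split=_TUMOR_NKT, cd4_split=_NAT_CD4, cd8_split=_NAT_CD8,
        overlays={**_BASE_OVERLAYS, "pd1_cd8": 0.12, "pd1_cd4": 0.12},
    ),
}


# leaf table: (leaf id, member populations of the 30-list, positive/low marker
# levels, applicable overlays as (overlay profile key, marker, overlay
# population or None))
_LEAVES: list[tuple[str, list[str], dict[str, str], list[tuple[str, str, str | None]]]] = [
    ("nkt_dn", ["nkt"], {"CD3": "pos", "CD56": "pos"},
     [("ki67_t", "Ki-67", None)]),
    ("nkt_cd4", ["nkt", "nkt_cd4"], {"CD3": "pos", "CD56": "pos", "CD4": "pos"},
     [("ki67_t", "Ki-67", None)]),
    ("nkt_cd8", ["nkt", "nkt_cd8"], {"CD3": "pos", "CD56": "pos", "CD8": "pos"},
     [("ki67_t", "Ki-67", None)]),
    ("b", ["b_cells"], {"CD19": "pos", "HLA-DR": "pos"},
     [("ki67_b", "Ki-67", None)]),
    ("nk", ["nk_cells"], {"CD56": "pos", "CD16": "pos"},
     [("ki67_nk", "Ki-67", None)]),
    ("cdc", ["cdc"], {"HLA-DR": "pos", "CD11c": "pos", "CD11b": "pos"}, []),
    ("pdc", ["pdc"], {"HLA-DR": "pos", "CD123": "pos"}, []),
    ("macrophage", ["macrophage"],
     {"CD68": "pos", "HLA-DR": "pos", "CD14": "pos", "CD11b": "pos",
      "CD33": "pos", "SSC-A": "hi"}, []),
    ("mmdsc", ["mmdsc"],
     {"HLA-DR": "lo", "CD14": "pos", "CD11b": "pos", "CD33": "pos"},
     [("ki67_mmdsc", "Ki-67", None),
      ("pdl1_mmdsc", "PD-L1", "pdl1_mmdsc")]),
    ("mono", ["cd14_monocyte"],
     {"HLA-DR": "pos", "CD14": "pos", "CD11b": "pos", "CD33": "pos"}, []),
]
# T-cell memory quadrants
_RA_CCR7 = {
    "naive": {"CD45RA": "pos", "CD197": "pos"},
    "cm": {"CD45RA": "neg", "CD197": "pos"},
    "em": {"CD45RA": "neg", "CD197": "neg"},
    "emra": {"CD45RA": "pos", "CD197": "neg"},
}
for _sub, _lv in _RA_CCR7.items():
    _LEAVES.append((
        f"cd4_{_sub}", ["cd4_t", f"cd4_{_sub}"],
        {"CD3": "pos", "CD4": "pos", **_lv},
        [("ki67_t", "Ki-67", "ki67_cd4_t"), ("pd1_cd4", "PD-1", "pd1_cd4_t")],
    ))
    _LEAVES.append((
        f"cd8_{_sub}", ["cd8_t", f"cd8_{_sub}"],
        {"CD3": "pos", "CD8": "pos", **_lv},
        [("ki67_t", "Ki-67", "ki67_cd8_t"), ("pd1_cd8", "PD-1", "pd1_cd8_t"),
         ("pdl1_cd8", "PD-L1", "pdl1_cd8_t")],
    ))
# Treg fractions (FOXP3 three-level gates; each also falls in one memory quadrant)
_LEAVES += [
    ("treg_fr1", ["cd4_t", "cd4_naive", "treg_naive"],
     {"CD3": "pos", "CD4": "pos", "CD45RA": "pos", "CD197": "pos",
      "FOXP3": "lo", "CD25": "pos"},
     [("ki67_t", "Ki-67", "ki67_cd4_t"), ("pd1_cd4", "PD-1", "pd1_cd4_t")]),
    ("treg_fr2", ["cd4_t", "cd4_em", "treg_eff"],
     {"CD3": "pos", "CD4": "pos", "CD45RA": "neg", "CD197": "neg",
      "FOXP3": "pos", "CD25": "pos"},
     [("ki67_t", "Ki-67", "ki67_cd4_t"), ("pd1_cd4", "PD-1", "pd1_cd4_t"),
      ("ctla4_etreg", "CTLA-4", "ctla4_etreg")]),
    ("treg_fr3", ["cd4_t", "cd4_cm", "treg_nonsup"],
     {"CD3": "pos", "CD4": "pos", "CD45RA": "neg", "CD197": "pos",
      "FOXP3": "lo"},
     [("ki67_t", "Ki-67", "ki67_cd4_t"), ("pd1_cd4", "PD-1", "pd1_cd4_t")]),
]


def _leaf_fraction(profile: CompositionProfile, leaf_id: str) -> float:
    if leaf_id.startswith("nkt_"):
        return profile.top["nkt"] * profile.nkt_split[leaf_id.split("_", 1)[1]]
    if leaf_id.startswith("cd4_"):
        return profile.top["cd4_t"] * profile.cd4_split[leaf_id.split("_", 1)[1]]
    if leaf_id.startswith("cd8_"):
        return profile.top["cd8_t"] * profile.cd8_split[leaf_id.split("_", 1)[1]]
    if leaf_id.startswith("treg_"):
        return profile.top["cd4_t"] * profile.cd4_split[leaf_id.split("_")[1]]
    pop = {"b": "b_cells", "nk": "nk_cells", "mono": "cd14_monocyte"}.get(leaf_id, leaf_id)
    return profile.top[pop]


def _marker_profile(
    levels: dict[str, str], channels: list[str], dead: bool = False
) -> tuple[dict[str, float], dict[str, float]]:
    means, sds = {}, {}
    for ch in channels:
        if ch == "SSC-A":
            means[ch] = _SSC_HI if levels.get(ch) == "hi" else _SSC_BASE
            sds[ch] = _SSC_SD
        elif ch == "FSC-A":
            means[ch], sds[ch] = _FSC_MEAN, _FSC_SD
        elif ch == "Viability":
            means[ch] = _VIAB_DEAD if dead else _VIAB_LIVE
            sds[ch] = _MARKER_SD
        else:
            means[ch] = _LEVEL_MEANS[levels.get(ch, "neg")]
            sds[ch] = _MARKER_SD
    return means, sds


def profile_population_specs(
    profile: CompositionProfile, tree: GatingTree | None = None
) -> tuple[list[PopulationSpec], dict[str, list[str]]]:
    """Expand a composition profile into lognormal mixture components.

    Returns the component list (fractions summing to 1 over CD45+ events) and
    a map from each component to the populations of the 30-list it belongs to.
    """
    tree = tree or default_gating_tree()
    channels = tree.channels
    specs: list[PopulationSpec] = []
    membership: dict[str, list[str]] = {}
    for leaf_id, pops, levels, overlays in _LEAVES:
        base_frac = _leaf_fraction(profile, leaf_id)
        if base_frac <= 0:
            continue
        levels = {**{"CD45": "pos"}, **levels}
        combos = [((), 1.0)]
        for okey, marker, opop in overlays:
            f = profile.overlays.get(okey, 0.0)
            combos = [
                (flags + ((marker, opop, on),), w * (f if on else 1.0 - f))
                for flags, w in combos
                for on in (False, True)
                if (f if on else 1.0 - f) > 0
            ]
        for flags, weight in combos:
            lv = dict(levels)
            extra_pops: list[str] = []
            suffix = ""
            for marker, opop, on in flags:
                if on:
                    lv[marker] = "pos"
                    suffix += f"|{marker}+"
                    if opop is not None:
                        extra_pops.append(opop)
            means, sds = _marker_profile(lv, channels)
            spec_id = leaf_id + suffix
            specs.append(
                PopulationSpec(spec_id, means, sds, base_frac * weight)
            )
            membership[spec_id] = pops + extra_pops
    total = sum(s.expected_fraction_of_events for s in specs)
    specs = [
        dataclasses.replace(s, expected_fraction_of_events=s.expected_fraction_of_events / total)
        for s in specs
    ]
    return specs, membership


# ---------------------------------------------------------------------------
# event synthesis


def _contaminant_specs(channels: list[str]) -> dict[str, PopulationSpec]:
    dead_means, dead_sds = _marker_profile({"CD45": "pos", "CD3": "pos"}, channels, dead=True)
    epi_means, epi_sds = _marker_profile({"CD326": "pos"}, channels)
    return {
        "dead": PopulationSpec("dead", dead_means, dead_sds, 0.0),
        "epithelial": PopulationSpec("epithelial", epi_means, epi_sds, 0.0),
    }


def _draw_events(
    rng: np.random.Generator,
    blocks: list[tuple[PopulationSpec, int]],
    channels: list[str],
) -> pd.DataFrame:
    parts = []
    for spec, n in blocks:
        if n == 0:
            continue
        mean = np.array([spec.mean_log_intensity[c] for c in channels])
        sd = np.array([spec.sd_log_intensity[c] for c in channels])
        parts.append(rng.normal(mean, sd, size=(n, len(channels))))
    if not parts:
        return pd.DataFrame(columns=channels, dtype=float)
    data = np.vstack(parts)
    data = data[rng.permutation(len(data))]
    return pd.DataFrame(data, columns=channels)


def _validate_specs(populations: list[PopulationSpec], channels: list[str]) -> None:
    chset = set(channels)
    total = 0.0
    for spec in populations:
        keys = set(spec.mean_log_intensity)
        if keys != chset:
            unknown = sorted(keys - chset) or sorted(chset - keys)
            raise ValueError(
                f"population {spec.population_id!r} marker set does not match "
                f"the panel (mismatch: {unknown})"
            )
        if any(s <= 0 for s in spec.sd_log_intensity.values()):
            raise ValueError(f"population {spec.population_id!r} has sd <= 0")
        total += spec.expected_fraction_of_events
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {total}, expected 1")


def simulate_fcm_sample(
    populations: list[PopulationSpec],
    n_events: int,
    mass_g: float,
    seed: int | np.random.SeedSequence,
    *,
    dead_fraction: float = 0.0,
    epithelial_fraction: float = 0.0,
    tree: GatingTree | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Draw one event table from a lognormal mixture.

    Returns the event table and the true per-component event counts
    (contaminants excluded from the returned truth).
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    if mass_g <= 0:
        raise ValueError(f"mass_g must be > 0, got {mass_g}")
    tree = tree or default_gating_tree()
    channels = tree.channels
    _validate_specs(populations, channels)
    rng = np.random.default_rng(seed)
    n_dead = int(round(n_events * dead_fraction))
    n_epi = int(round(n_events * epithelial_fraction))
    n_immune = n_events - n_dead - n_epi
    fracs = np.array([s.expected_fraction_of_events for s in populations])
    counts = rng.multinomial(n_immune, fracs)
    contams = _contaminant_specs(channels)
    blocks = list(zip(populations, counts))
    blocks += [(contams["dead"], n_dead), (contams["epithelial"], n_epi)]
    events = _draw_events(rng, blocks, channels)
    truth = {s.population_id: int(c) for s, c in zip(populations, counts)}
    return events, truth


# ---------------------------------------------------------------------------
# cohort simulation


TEMPLATES = ("study_luad", "study_lusq", "study_full", "mini")

_LUAD_GROUPS = [("LUAD", "Cold", 19), ("LUAD", "Myeloid", 36), ("LUAD", "CD8", 30)]
_LUSQ_GROUPS = [("LUSQ", "Cold", 14), ("LUSQ", "Myeloid", 19), ("LUSQ", "CD8", 17)]


def default_cohort_spec(template_name: str) -> CohortSpec:
    """Packaged cohort layouts.

    ``study_luad`` — 85 LUAD tumors (Cold 19 / Myeloid 36 / CD8 30);
    ``study_lusq`` — 50 LUSQ tumors (14 / 19 / 17); ``study_full`` — both
    tumor cohorts plus 157 NAT samples; ``mini`` — a 20-sample fast template
    with all three subtypes and NATs.
    """
    if template_name == "study_luad":
        return CohortSpec(groups=list(_LUAD_GROUPS), seed=0)
    if template_name == "study_lusq":
        return CohortSpec(groups=list(_LUSQ_GROUPS), seed=0)
    if template_name == "study_full":
        return CohortSpec(
            groups=list(_LUAD_GROUPS) + list(_LUSQ_GROUPS) + [("NAT", "none", 157)],
            seed=0,
        )
    if template_name == "mini":
        return CohortSpec(
            groups=[("LUAD", "Cold", 4), ("LUAD", "Myeloid", 5), ("LUAD", "CD8", 5),
                    ("NAT", "none", 6)],
            events_per_sample=5000,
            seed=0,
        )
    raise ValueError(
        f"unknown template {template_name!r}; available templates: {TEMPLATES}"
    )


@dataclass
class _SampleRecord:
    sample_id: str
    histology: str
    subtype: str
    mass_g: float
    n_events: int
    n_dead: int
    n_epithelial: int
    specs: list[PopulationSpec]
    membership: dict[str, list[str]]
    leaf_counts: np.ndarray
    event_seq: np.random.SeedSequence


@dataclass
class Cohort:
    """A simulated cohort with lazily materialized event tables.

    Per-sample composition and true counts are fixed at construction; the
    event-level tables are regenerated deterministically on demand from each
    sample's child seed, so large cohorts never hold all events in memory.
    """

    spec: CohortSpec
    samples: list[_SampleRecord]
    truth: SyntheticTruth
    tree: GatingTree

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def masses(self) -> pd.Series:
        return self.truth.masses

    def events(self, sample_id: str) -> pd.DataFrame:
        rec = next(s for s in self.samples if s.sample_id == sample_id)
        return self._events_for(rec)

    def _events_for(self, rec: _SampleRecord) -> pd.DataFrame:
        rng = np.random.default_rng(rec.event_seq)
        contams = _contaminant_specs(self.tree.channels)
        blocks = list(zip(rec.specs, rec.leaf_counts))
        blocks += [(contams["dead"], rec.n_dead),
                   (contams["epithelial"], rec.n_epithelial)]
        return _draw_events(rng, blocks, self.tree.channels)

    def iter_events(self):
        """Yield (sample record, event table) pairs one sample at a time."""
        for rec in self.samples:
            yield rec, self._events_for(rec)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a lognormal to the requested mean/sd on the natural scale
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _jitter_profile(
    profile: CompositionProfile, rng: np.random.Generator, spec: CohortSpec
) -> CompositionProfile:
    def dirichlet_jitter(d: dict[str, float], conc: float) -> dict[str, float]:
        keys = list(d)
        alpha = np.array([d[k] for k in keys]) * conc
        vals = rng.dirichlet(alpha)
        return dict(zip(keys, vals))

    return dataclasses.replace(
        profile,
        top=dirichlet_jitter(profile.top, spec.composition_concentration),
        cd4_split=dirichlet_jitter(profile.cd4_split, spec.split_concentration),
        cd8_split=dirichlet_jitter(profile.cd8_split, spec.split_concentration),
        nkt_split=dirichlet_jitter(profile.nkt_split, spec.split_concentration),
    )


def simulate_cohort(
    spec: CohortSpec, tree: GatingTree | None = None
) -> tuple[Cohort, SyntheticTruth]:
    """Simulate a full cytometry cohort under the planted subtype templates."""
    tree = tree or default_gating_tree()
    root = np.random.SeedSequence(spec.seed)
    sample_seqs = root.spawn(spec.n_samples)
    mu, sigma = _lognormal_params(spec.mass_mean_g, spec.mass_sd_g)

    samples: list[_SampleRecord] = []
    truth_rows, frac_rows, label_rows, masses = [], [], [], {}
    idx = 0
    all_pops = [p.population_id for p in tree.populations]
    for histology, subtype, n in spec.groups:
        profile = PROFILES["NAT" if subtype == "none" else subtype]
        for i in range(n):
            seq = sample_seqs[idx]
            idx += 1
            struct_seq, event_seq = seq.spawn(2)
            rng = np.random.default_rng(struct_seq)
            sample_id = f"{histology}_{subtype}_{i:03d}"
            mass = float(np.exp(rng.normal(mu, sigma)))
            jit = _jitter_profile(profile, rng, spec)
            immune_frac = profile.immune_fraction * float(
                np.exp(rng.normal(0.0, spec.immune_noise_sd))
            )
            immune_frac = min(immune_frac, 1.0 - spec.dead_fraction - 0.05)
            specs, membership = profile_population_specs(jit, tree)
            n_dead = int(round(spec.events_per_sample * spec.dead_fraction))
            n_immune = int(round(spec.events_per_sample * immune_frac))
            n_epi = spec.events_per_sample - n_dead - n_immune
            fracs = np.array([s.expected_fraction_of_events for s in specs])
            leaf_counts = rng.multinomial(n_immune, fracs)

            pop_counts = dict.fromkeys(all_pops, 0)
            exp_frac = dict.fromkeys(all_pops, 0.0)
            for s, c, f in zip(specs, leaf_counts, fracs):
                for pop in membership[s.population_id]:
                    pop_counts[pop] += int(c)
                    exp_frac[pop] += float(f)
            truth_rows.append(
                pd.Series({**pop_counts, "total_cd45": int(leaf_counts.sum())},
                          name=sample_id)
            )
            frac_rows.append(pd.Series(exp_frac, name=sample_id))
            label_rows.append((sample_id, histology,
                               "none" if subtype == "none" else subtype))
            masses[sample_id] = mass
            samples.append(_SampleRecord(
                sample_id=sample_id, histology=histology, subtype=subtype,
                mass_g=mass, n_events=spec.events_per_sample, n_dead=n_dead,
                n_epithelial=n_epi, specs=specs, membership=membership,
                leaf_counts=leaf_counts, event_seq=event_seq,
            ))

    labels = pd.DataFrame(label_rows, columns=["sample_id", "histology", "subtype"])
    truth = SyntheticTruth(
        labels=labels.set_index("sample_id"),
        population_counts=pd.DataFrame(truth_rows),
        expected_fractions=pd.DataFrame(frac_rows),
        masses=pd.Series(masses, name="mass_g"),
    )
    cohort = Cohort(spec=spec, samples=samples, truth=truth, tree=tree)
    return cohort, truth


# ---------------------------------------------------------------------------
# expression

# per-gene log2 shifts by subtype (unlisted subtypes shift by 0)
DEFAULT_GENE_EFFECTS: dict[str, dict[str, float]] = {}
for _g in ("CCL5", "CXCL9", "CXCL11", "IFNG", "GZMB", "PRF1", "CD8A", "CD3E"):
    DEFAULT_GENE_EFFECTS[_g] = {"CD8": 1.5, "Cold": -0.5}
for _g in ("IFIT1", "IFIT3", "ISG15", "MX1", "OAS1"):
    DEFAULT_GENE_EFFECTS[_g] = {"CD8": 1.0, "Cold": -0.3}
for _g in ("PDCD1", "CD274", "HAVCR2", "LAG3", "CTLA4", "IDO1"):
    DEFAULT_GENE_EFFECTS[_g] = {"CD8": 1.0}
for _g in ("HLA-A", "B2M", "TAP1", "TAP2"):
    DEFAULT_GENE_EFFECTS[_g] = {"CD8": 0.8, "Cold": -0.3}
for _g in ("CD33", "CD14", "ITGAM", "ARG1", "IL10", "TGFB1", "CD68", "MRC1"):
    DEFAULT_GENE_EFFECTS[_g] = {"Myeloid": 1.2}

_KNOWN_SUBTYPES = {"Cold", "Myeloid", "CD8", "NAT", "none"}


def simulate_expression(
    labels: pd.Series | dict[str, str],
    gene_config: dict[str, dict[str, float]] | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    n_background: int = 200,
    noise_sd_log2: float = 0.8,
) -> pd.DataFrame:
    """Lognormal TPM (genes x samples) with planted subtype effects."""
    labels = pd.Series(labels)
    if labels.empty:
        raise ValueError("labels must be nonempty")
    unknown = set(labels) - _KNOWN_SUBTYPES
    if unknown:
        raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
    effects = DEFAULT_GENE_EFFECTS if gene_config is None else gene_config
    genes = list(effects) + [f"BG{i:04d}" for i in range(n_background)]
    rng = np.random.default_rng(seed)
    base = rng.uniform(2.0, 8.0, size=len(genes))  # per-gene baseline log2 TPM
    shift = np.zeros((len(genes), len(labels)))
    for gi, g in enumerate(genes):
        eff = effects.get(g, {})
        shift[gi] = [eff.get(sub, 0.0) for sub in labels]
    log2tpm = base[:, None] + shift + rng.normal(0.0, noise_sd_log2, shift.shape)
    tpm = np.power(2.0, log2tpm)
    return pd.DataFrame(tpm, index=genes, columns=list(labels.index))


# ---------------------------------------------------------------------------
# TCR repertoires

CHAINS = ("TRA", "TRB", "TRD", "TRG")

# (richness, Dirichlet concentration) per subtype; gamma/delta chains use a
# reduced richness (rare lineages)
DEFAULT_RICHNESS: dict[str, tuple[int, float]] = {
    "CD8": (600, 1.0),
    "Cold": (600, 0.45),
    "Myeloid": (600, 0.25),
    "NAT": (600, 0.7),
    "none": (600, 0.7),
}
_GD_RICHNESS_SCALE = 0.2


def expected_clone_entropy(richness: int, concentration: float) -> float:
    """Closed-form E[Shannon entropy] of symmetric-Dirichlet clone frequencies.

    For p ~ Dirichlet(alpha * 1_R), E[-sum p_i ln p_i] = psi(R*alpha + 1) -
    psi(alpha + 1) nats.
    """
    return float(digamma(richness * concentration + 1) - digamma(concentration + 1))


def simulate_tcr(
    labels: pd.Series | dict[str, str],
    richness_config: dict[str, tuple[int, float]] | None = None,
    umi_depth: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Clonotype UMI-count tables per chain per sample (AIRR-like long form)."""
    if umi_depth < 1:
        raise ValueError(f"umi_depth must be >= 1, got {umi_depth}")
    labels = pd.Series(labels)
    config = DEFAULT_RICHNESS if richness_config is None else richness_config
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, subtype in labels.items():
        if subtype not in config:
            raise ValueError(f"no richness config for subtype {subtype!r}")
        richness, conc = config[subtype]
        for chain in CHAINS:
            r = richness
            if chain in ("TRD", "TRG"):
                r = max(1, int(round(richness * _GD_RICHNESS_SCALE)))
            if r == 1:
                counts = np.array([umi_depth])
            else:
                p = rng.dirichlet(np.full(r, conc))
                counts = rng.multinomial(umi_depth, p)
            for i in np.nonzero(counts)[0]:
                rows.append((sample_id, chain, f"C{chain}{i:06d}F", int(counts[i])))
    return pd.DataFrame(rows, columns=["sample_id", "chain", "cdr3", "umi_count"])


# ---------------------------------------------------------------------------
# clinical outcomes

DEFAULT_HAZARDS = {"Myeloid": 3.0, "Cold": 1.8, "CD8": 1.0}
_BASELINE_RATE = np.log(2) / 80.0  # per-month hazard; CD8-arm median 80 months

# name -> (levels, P(level) per subtype, per-level hazard multiplier)
_FACTOR_DEFS: list[tuple[str, list[str], dict[str, list[float]], list[float]]] = [
    ("Age", ["<65", ">=65"],
     {"Cold": [0.5, 0.5], "Myeloid": [0.5, 0.5], "CD8": [0.5, 0.5]}, [1.0, 1.0]),
    ("Gender", ["female", "male"],
     {"Cold": [0.45, 0.55], "Myeloid": [0.45, 0.55], "CD8": [0.45, 0.55]}, [1.0, 1.0]),
    ("pT", ["1-2", "3-4"],
     {"Cold": [0.85, 0.15], "Myeloid": [0.60, 0.40], "CD8": [0.80, 0.20]}, [1.0, 1.6]),
    ("ly", ["ly0", "ly1"],
     {"Cold": [0.70, 0.30], "Myeloid": [0.55, 0.45], "CD8": [0.70, 0.30]}, [1.0, 1.5]),
    ("N", ["0", "1-3"],
     {"Cold": [0.80, 0.20], "Myeloid": [0.55, 0.45], "CD8": [0.75, 0.25]}, [1.0, 2.0]),
    ("STAS", ["0", "1"],
     {"Cold": [0.70, 0.30], "Myeloid": [0.50, 0.50], "CD8": [0.70, 0.30]}, [1.0, 1.3]),
    ("Stage", ["I-II", "III-IV"],
     {"Cold": [0.80, 0.20], "Myeloid": [0.55, 0.45], "CD8": [0.80, 0.20]}, [1.0, 2.0]),
    ("Differentiation", ["well-moderate", "poor"],
     {"Cold": [0.90, 0.10], "Myeloid": [0.55, 0.45], "CD8": [0.65, 0.35]}, [1.0, 1.0]),
    ("TLS_grade", ["0", "1", "2"],
     {"Cold": [0.50, 0.35, 0.15], "Myeloid": [0.45, 0.40, 0.15],
      "CD8": [0.20, 0.40, 0.40]}, [1.0, 1.0, 1.0]),
    ("Surgical_margin", ["negative", "positive"],
     {"Cold": [0.95, 0.05], "Myeloid": [0.88, 0.12], "CD8": [0.95, 0.05]}, [1.0, 2.0]),
]


def simulate_clinical(
    labels: pd.Series | dict[str, str],
    hazard_config: dict[str, float] | None = None,
    censor_config: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
    factor_hazards: bool = True,
) -> pd.DataFrame:
    """Exponential EFS times with per-subtype hazards and planted factors.

    ``factor_hazards=False`` drops the clinicopathologic factors' own hazard
    contributions (they keep their subtype associations), giving an exact
    exchangeable null when all subtype multipliers are equal.

    ``censor_config`` keys: ``hazard`` (independent exponential censoring
    rate per month), ``admin_months`` (administrative cutoff), ``prob``
    (optional: censor each subject with this probability at a uniform time
    before the event; ``prob=1`` censors everyone).
    """
    labels = pd.Series(labels)
    hazards = DEFAULT_HAZARDS if hazard_config is None else hazard_config
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazard multipliers must be positive")
    cens = {"hazard": np.log(2) / 120.0, "admin_months": 60.0, "prob": None}
    if censor_config:
        cens.update(censor_config)
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, subtype in labels.items():
        if subtype not in hazards:
            raise ValueError(f"no hazard multiplier for subtype {subtype!r}")
        rate = _BASELINE_RATE * hazards[subtype]
        factors = {}
        for name, levels, probs, mults in _FACTOR_DEFS:
            p = probs.get(subtype, [1.0 / len(levels)] * len(levels))
            li = rng.choice(len(levels), p=np.asarray(p) / np.sum(p))
            factors[name] = levels[li]
            if factor_hazards:
                rate *= mults[li]
        t_event = rng.exponential(1.0 / rate)
        if cens["prob"] is not None and rng.uniform() < cens["prob"]:
            time, event = rng.uniform(0.0, t_event), 0
        else:
            t_cens = rng.exponential(1.0 / cens["hazard"]) if cens["hazard"] > 0 else np.inf
            cutoff = min(t_cens, cens["admin_months"])
            time, event = min(t_event, cutoff), int(t_event <= cutoff)
        rows.append({"sample_id": sample_id, "efs_months": max(time, 1e-6),
                     "event": event, "subtype": subtype, **factors})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# persistence


def write_cohort(
    cohort: Cohort, outdir: str | Path, include_events: bool = True
) -> None:
    """Write a cohort to disk: per-sample event CSVs, masses, truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = cohort.truth
    truth.masses.rename_axis("sample_id").to_csv(outdir / "masses.csv")
    truth.labels.to_csv(outdir / "truth_labels.csv")
    truth.population_counts.rename_axis("sample_id").to_csv(
        outdir / "truth_counts.csv"
    )
    if include_events:
        events_dir = outdir / "events"
        events_dir.mkdir(exist_ok=True)
        for rec, events in cohort.iter_events():
            events.to_csv(events_dir / f"{rec.sample_id}.csv", index=False)
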