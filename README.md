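# til-subtyper

Immune subtyping of non–small cell lung cancer (NSCLC) from
tumor-infiltrating leukocyte (TIL) profiles, for tumor immunologists and
computational biologists working with event-level cytometry, bulk expression,
TCR repertoires and clinical outcome data.

The tumor microenvironment of NSCLC falls into three recurrent immune
configurations with different prognoses and therapeutic implications:

* **Cold** — scant immune infiltration;
* **Myeloid** — leukocyte-rich but dominated by immunosuppressive myeloid
  cells (macrophages, CD14+ monocytes, monocytic MDSCs);
* **CD8** — T-cell-dominant, chemokine-high (CCL5/CXCL9/CXCL11), with higher
  TCR repertoire diversity and longer event-free survival.

`til-subtyper` implements the full analysis that recovers these subtypes:

1. **Gating** — a declarative hierarchy of per-channel threshold gates
   classifies cytometry events through a 26-marker panel into 30 immune
   populations (23 base cell types plus Ki-67+/PD-1+/PD-L1+/CTLA-4+
   functional overlays).
2. **Features** — each population is represented two ways and the blocks are
   concatenated after z-scaling across patients:
   density `log10(count / mass_g + 1)` and fraction `%CD45 = 100 ·
   count / total CD45+`.
3. **Subtyping** — samples are clustered on Spearman correlation distance
   `d(i, j) = 1 − ρ_s(x_i, x_j)` with the Ward.D2 criterion (Lance–Williams
   recurrence on squared dissimilarities, heights on the unsquared scale),
   implemented natively with deterministic tie-breaking. Cutting at k = 3
   and applying a composition rule (lowest total CD45+ density → Cold;
   higher myeloid %CD45 of the remainder → Myeloid; other → CD8) yields the
   labels; cutting a combined tumor + normal-adjacent-tissue (NAT) tree at
   k = 2 separates the two tissue clades.
4. **Characterization** — gene-set signature scores (mean z of
   log2(TPM + 1)), nearest-centroid molecular-subtype assignment (Pearson
   correlation after log transform and gene median centering), 8-axis
   immunogram scores in [0, 5] (axes 6–8 inverted; axis 2 requires
   neoantigen input and is not computed by default), Shannon entropy
   `H = −Σ p_i ln p_i` of TCR clonotype UMI frequencies after a minimum-UMI
   support filter (default 7), Kaplan–Meier/log-rank EFS comparisons,
   univariate Cox z-score scans, univariate→multivariate Cox factor tables
   (exp(−coef) orientation), and Fisher-exact/Holm association scans with
   dual flagging (raw p ≤ 0.05, Holm-adjusted p ≤ 0.2).

Because the raw study data are access-controlled, the package ships a
first-class synthetic cohort generator (`til_subtyper.synthetic_data`) that
plants this exact structure — lognormal marker mixtures matched to the
gating thresholds, subtype-conditional compositions, expression/TCR/survival
effects — alongside a ground-truth channel that the analysis never reads.

## Worked example

Simulate the LUAD-sized cohort (85 tumors planted as 19 Cold / 36 Myeloid /
30 CD8), gate it, cluster it, and label the clusters:

```python
from til_subtyper import (default_cohort_spec, simulate_cohort, gate_events,
                          build_feature_matrix, spearman_distance,
                          ward_d2_linkage, cut_clusters, label_subtypes,
                          adjusted_rand_index)
from til_subtyper.gating import default_gating_tree, counts_wide

tree = default_gating_tree()
spec = default_cohort_spec("study_luad")
spec.seed = 1
cohort, truth = simulate_cohort(spec, tree)
counts = counts_wide([gate_events(ev, tree, rec.sample_id)
                      for rec, ev in cohort.iter_events()])
fm = build_feature_matrix(counts, cohort.masses, "fig2", tree)
groups = cut_clusters(ward_d2_linkage(spearman_distance(fm)), 3)
labels = label_subtypes(groups, counts, cohort.masses, tree)
print(labels.value_counts().to_string())
print(f"ARI vs planted truth: "
      f"{adjusted_rand_index(truth.labels['subtype'], labels):.3f}")
```

prints

```
subtype
Myeloid    36
CD8        29
Cold       20
ARI vs planted truth: 0.970
```

i.e. the recovered subtype sizes match the planted 19/36/30 split up to one
boundary sample, and the partition agrees with the planted truth at adjusted
Rand index 0.97.

The same flow is available from the shell:

```bash
til-subtyper run --template study_luad --seed 1 --out runs/luad
til-subtyper simulate --template mini --seed 7 --out sim/
til-subtyper gate --events sim/events --out counts.csv
```

A full run directory contains gated counts, feature matrices, subtype
labels (and tumor/NAT clades when NATs are present), signature scores,
immunograms, TCR entropies, survival/association reports, and a
`manifest.json` with the seed, config hash and per-file checksums; rerunning
with the same config reproduces identical files.

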