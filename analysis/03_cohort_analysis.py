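#!/usr/bin/env python
"""Biomarker statistics on the packaged serum cohort table.

Analyzes the quantified serum amounts of seven ganglioside classes
(d36:1 species) in 36 controls, two Tay-Sachs patients and one Sandhoff
patient: group comparison with BH-adjusted pooled t-tests (with and
without Grubbs outlier screening), per-sample GM2/GM3 ratios, PCA of the
GM1/GM2/GM3 sub-panel, and heatmap-ready z-scores.
"""

import json
from pathlib import Path

from gslmrm.cohort import (
    gm2_gm3_ratio,
    group_compare,
    heatmap_zscores,
    load_cohort_table,
    pca,
    stats_to_frame,
)

OUT = Path(__file__).resolve().parents[1] / "results"
GM = ["GM1 d36:1", "GM2 d36:1", "GM3 d36:1"]


def main():
    OUT.mkdir(exist_ok=True)
    table = load_cohort_table()
    n_ctrl = (table["group"] == "control").sum()
    print(f"cohort: {len(table)} samples ({n_ctrl} controls, "
          f"{len(table) - n_ctrl} GM2-gangliosidosis patients)")

    res = group_compare(table)
    stats_to_frame(res).to_csv(OUT / "group_stats.csv", index=False)
    print("\nspecies          ctrl mean   FC(mean)  FC(median)  adj. p")
    for r in res:
        print(f"{r.species_id:<16} {r.control_mean:>8.1f} {r.fold_change_mean:>9.2f} "
              f"{r.fold_change_median:>10.2f}  {r.p_adjusted:.2e}")

    res_g = group_compare(table, grubbs_alpha=0.05)
    stats_to_frame(res_g).to_csv(OUT / "group_stats_grubbs.csv", index=False)
    removed = {r.species_id: r.outliers_removed for r in res_g if r.outliers_removed}
    print(f"\nGrubbs screening (alpha 0.05) removed: "
          f"{ {k: list(v) for k, v in removed.items()} }")

    ratios, summary = gm2_gm3_ratio(table)
    ratios.to_csv(OUT / "gm2_gm3_ratios.csv", index=False)
    (OUT / "gm2_gm3_summary.json").write_text(json.dumps(summary, indent=2))
    tsd01 = ratios.set_index("sample_id").loc["TSD01", "gm2_gm3_ratio"]
    print(f"\nGM2/GM3 ratio: patient/control fold-change "
          f"{summary['fold_change_mean']:.1f} (mean-based), "
          f"{summary['fold_change_median']:.1f} (median-based); "
          f"e.g. TSD01 ratio {tsd01:.2f}")

    p = pca(table, species=GM)
    p.scores.to_csv(OUT / "pca_scores.csv")
    p.loadings.to_csv(OUT / "pca_loadings.csv")
    pat = table["group"] != "control"
    pc1 = p.scores["PC1"].to_numpy()
    sep = pc1[pat.to_numpy()].min() - pc1[(~pat).to_numpy()].max()
    print(f"\nPCA on GM1/GM2/GM3: PC1 explains "
          f"{100 * p.explained_variance_ratio[0]:.1f}% of variance; patients "
          f"separate from all controls on PC1 (margin {sep:.2f} score units)")

    z = heatmap_zscores(table)
    z.to_csv(OUT / "heatmap_zscores.csv")
    print(f"z-score matrix written; most extreme GM2 sample: {z['GM2 d36:1'].idxmax()}")


if __name__ == "__main__":
    main()
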