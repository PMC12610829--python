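"""Head-to-head comparison of threshold vs cluster severity bands.

Runs both classification schemes on one simulated cohort, builds the
full separation report for each (descriptives, MANOVA, discriminant
contributions, homogeneity, Mahalanobis distances), and prints the
pairwise Mahalanobis comparison: larger distances mean more cleanly
separated severity bands.
"""

from mariabands import (
    ANALYSIS_VARIABLES,
    LITERATURE_THRESHOLDS,
    build_separation_report,
    classify_cohort,
    cluster_index,
    compare_schemes,
    filter_pathological,
    generate_cohort,
    index_cohort,
    preset_configs,
    severity_labels,
)

cohort, _ = generate_cohort(preset_configs("maria_clusters", seed=7))
analysis = index_cohort(filter_pathological(cohort))
scores = analysis["maria"].to_numpy()

th_labels, th_counts = classify_cohort(scores, LITERATURE_THRESHOLDS["maria"])
cl_labels = severity_labels(cluster_index(scores, k=3))
print("threshold bands:", {c.label: n for c, n in th_counts.items()})
print("cluster bands:  ", {name: int((cl_labels == i).sum())
                           for i, name in enumerate(("inactive", "active",
                                                     "severe"))})

rep_th = build_separation_report(analysis, th_labels, "threshold", "maria")
rep_cl = build_separation_report(analysis, cl_labels, "cluster", "maria")

comparison = compare_schemes(rep_th, rep_cl)
print(f"\nMahalanobis distances on {', '.join(ANALYSIS_VARIABLES)}:")
for row in comparison["pairs"]:
    print(f"  {row['pair']:<22} threshold {row['threshold']:6.2f}  "
          f"cluster {row['cluster']:6.2f}  ratio {row['ratio']:4.1f}x")
print("cluster wider in all pairs:", comparison["b_larger_in_all_pairs"])
print("\nThe cluster-derived bands separate severalfold more widely than")
print("the literature-threshold bands on the same segments - the fixed")
print("cut-offs split the low-activity component instead of the gaps.")
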