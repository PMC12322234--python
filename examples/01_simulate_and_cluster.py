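"""Simulate a cell-line panel and recover its planted metabolic clusters.

Generates a ~60-cell-line targeted metabolomics panel (triplicates over 6
batches with anchor cell lines), runs log10 -> RUV-III -> pathway ratio
transform -> consensus correlation K-means, and compares the recovered
partition with the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

import metaboratio as mr

cfg = mr.SyntheticConfig(seed=1)
abundance, meta, truth = mr.generate_panel(cfg)
print(f"panel: {abundance.shape[0]} samples x {abundance.shape[1]} metabolites, "
      f"{truth.cluster_labels.nunique()} planted clusters")

logged = mr.log10_transform(abundance)
design = mr.build_replicate_design(meta, logged.sample_ids)
model = mr.ruv3_correct(logged, design, k=9)
aggregated = mr.aggregate_replicates(model.corrected, meta)

feats = mr.build_ratio_features(cfg.pathway_set, aggregated.metabolite_ids)
ratios = mr.compute_ratio_matrix(aggregated, feats)
scaled = mr.zscore_features(ratios)
print(f"ratio matrix: {scaled.data.shape[0]} cell lines x {scaled.data.shape[1]} "
      "pathway ratio features")

diag = mr.k_diagnostics(scaled, seed=1)
print(f"cluster number: gap={diag.gap_k}, elbow={diag.elbow_k}, "
      f"silhouette={diag.silhouette_k} -> combined k={diag.combined_k}")

result = mr.consensus_cluster(scaled, diag.combined_k, n_reps=200, seed=1)
ari = adjusted_rand_score(truth.cluster_labels.loc[result.labels.index], result.labels)
print(f"consensus clustering (200 reps): ARI vs planted truth = {ari:.3f}")
print("An ARI of 1.0 means the pathway-ratio pipeline recovered the planted")
print("cluster structure exactly despite batch effects and per-sample scaling.")
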