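"""Cluster relative-expression profiles and scan 3'UTRs for TTP sites.

Transcripts overexpressed on Dusp1 deletion separate into TTP-independent
and TTP-dependent clusters; direct TTP targets typically carry UAUUUAU
AU-rich elements in their 3'UTRs.
"""

from episttp import (
    SimulationParams,
    cluster_genes,
    log2_transform,
    relative_tracks,
    scan_are,
    simulate_experiment,
    simulate_utr,
    summarize_clusters,
)

matrix, design, truth = simulate_experiment(
    SimulationParams(n_genes=500, frac_induced=1.0, frac_dusp1_responsive=0.8, seed=5)
)
tracks = relative_tracks(log2_transform(matrix), design)
# the LPS tracks carry the genotype signal; untreated tracks mostly encode
# induction strength and would swamp the correlation structure
lps_tracks = tracks[["WT_LPS", "Dusp1KO_LPS", "Zfp36aa_LPS", "DoubleMut_LPS"]]

overexpressed = truth.index[truth["dusp1_effect_log2"] > 0.5]
result = cluster_genes(lps_tracks.loc[overexpressed], k=4)
print("cluster sizes:")
print(result.cluster_sizes().to_string())
summary = summarize_clusters(result, lps_tracks.loc[overexpressed])
print("\nmedian relative log2 expression per cluster (DoubleMut under LPS):")
print(
    summary[summary.track == "DoubleMut_LPS"][["cluster", "n", "median"]]
    .to_string(index=False)
)

utr = simulate_utr(300, 4, seed=9)
hits = scan_are(utr)
print(f"\nsynthetic 3'UTR of {len(utr)} nt: {hits.count} UAUUUAU matches at {hits.positions}")
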