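{
  "artifacts": {
    "dendrogram_labels_tsv": "dendrogram_labels.tsv",
    "dendrogram_nwk": "dendrogram.nwk",
    "disintegration_curve_tsv": "disintegration_curve.tsv",
    "enrichment_tsv": "enrichment.tsv",
    "network_graphml": "network.graphml",
    "network_sif": "network.sif",
    "node_attributes_tsv": "node_attributes.tsv",
    "permutation_null_tsv": "permutation_null.tsv"
  },
  "config": {
    "adaptive": false,
    "aliases": "toy_string_aliases.tsv",
    "allowed_levels": [
      "High",
      "Low",
      "Medium"
    ],
    "allowed_reliability": [
      "Approved",
      "Enhanced",
      "Supported"
    ],
    "alpha": 0.05,
    "expression": "toy_hpa.tsv",
    "gmt": "toy_reactome.gmt",
    "k": null,
    "linkage": "average",
    "links": "toy_links.txt",
    "min_key_genes": 3,
    "min_score": 900,
    "mirna_id": "hsa-miR-375",
    "n_clusters": 2,
    "n_perm": 1000,
    "out_dir": "out",
    "seed": 42,
    "targets": "toy_mirtarbase.tsv",
    "tissue": "heart muscle",
    "use_adjusted": false
  },
  "counts": {
    "component_sizes": [
      7
    ],
    "lcc_size": 7,
    "links_skip_summary": {
      "no_alias": 0,
      "self_loops": 1
    },
    "n_clusters": 2,
    "n_connected_genes": 7,
    "n_edges": 8,
    "n_expressed_genes": 18,
    "n_expressed_targets": 9,
    "n_isolated_targets": 2,
    "n_key_genes": 4,
    "n_min": 4,
    "n_pathways_filtered": 4,
    "n_pathways_significant": 4,
    "n_pathways_tested": 12,
    "n_targets": 12,
    "permutation": {
      "empirical_p": "5/1001",
      "empirical_p_float": 0.004995004995004995,
      "exceedances": 4,
      "formatted": "0.004995",
      "k": 9,
      "n_perm": 1000,
      "observed_lcc": 7
    }
  },
  "key_genes": [
    "CDC42",
    "CTNNB1",
    "ERBB2",
    "MAPK3"
  ],
  "partial_stages": []
}
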