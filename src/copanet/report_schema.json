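{
  "title": "copanet pipeline report",
  "type": "object",
  "required": [
    "seed",
    "dataset",
    "positive_network",
    "negative_network",
    "criteria_network",
    "hierarchy",
    "comparison"
  ],
  "properties": {
    "seed": {"type": "integer"},
    "dataset": {
      "type": "object",
      "required": ["total_posts", "unique_users", "mean_posts_per_user",
                   "multi_community_users", "multi_community_pct",
                   "n_disorders"],
      "properties": {
        "total_posts": {"type": "integer"},
        "unique_users": {"type": "integer"},
        "mean_posts_per_user": {"type": "number"},
        "multi_community_users": {"type": "integer"},
        "multi_community_pct": {"type": "number"},
        "n_disorders": {"type": "integer"}
      }
    },
    "positive_network": {"$ref": "#/definitions/network_summary"},
    "negative_network": {"$ref": "#/definitions/network_summary"},
    "criteria_network": {"$ref": "#/definitions/network_summary"},
    "hierarchy": {
      "type": "object",
      "required": ["coposting", "criteria"],
      "properties": {
        "coposting": {"$ref": "#/definitions/modularity_summary"},
        "criteria": {"$ref": "#/definitions/modularity_summary"}
      }
    },
    "comparison": {
      "type": "object",
      "required": ["ari", "nmi", "edge_jaccard", "shared_edge_fraction"],
      "properties": {
        "ari": {"type": "number"},
        "nmi": {"type": "number"},
        "edge_jaccard": {"type": "number"},
        "shared_edge_fraction": {"type": "array"}
      }
    }
  },
  "definitions": {
    "network_summary": {
      "type": "object",
      "required": ["n_nodes", "n_edges", "density"],
      "properties": {
        "n_nodes": {"type": "integer"},
        "n_edges": {"type": "integer"},
        "density": {"type": "number"},
        "giant_component_size": {"type": "integer"},
        "n_isolated": {"type": "integer"},
        "intra_category_edges": {"type": "integer"},
        "inter_category_edges": {"type": "integer"}
      }
    },
    "modularity_summary": {
      "type": "object",
      "required": ["q_w", "expected_q_null", "delta_q", "n_clusters",
                   "unclustered"],
      "properties": {
        "q_w": {"type": "number"},
        "expected_q_null": {"type": "number"},
        "delta_q": {"type": "number"},
        "n_clusters": {"type": "integer"},
        "unclustered": {"type": "array"}
      }
    }
  }
}
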