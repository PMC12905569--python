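"""Run the complete pipeline from files on disk and print the JSON report.

Equivalent to `copanet simulate ... && copanet run-all ...` from a shell.
"""
import json
import tempfile
from pathlib import Path

from copanet import synth
from copanet.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    config = synth.demo_config(n_users=1500, n_disorders=12, n_blocks=3,
                               n_isolated=1, seed=21)
    posts, mapping, truth = synth.generate_posts(config)
    paths = synth.write_outputs(posts, mapping, truth, data)
    crit = synth.generate_criteria(config.codes(), config.planted_clusters,
                                   n_criteria_per_disorder=10,
                                   shared_within_block=5, seed=21)
    crit.to_csv(data / "criteria.csv", index=False)

    report = run_pipeline(PipelineConfig(
        posts_path=str(paths["posts"]),
        mapping_path=str(paths["mapping"]),
        criteria_path=str(data / "criteria.csv"),
        out_dir=str(Path(tmp) / "out"),
        n_reps=2000, n_null=500, seed=21))

print(json.dumps(report, indent=2, sort_keys=True))
# hierarchy.*.delta_q: clustering strength beyond the degree/weight-matched
# chance level; comparison.ari/nmi: agreement between the coposting and
# criteria partitions; comparison.edge_jaccard: fraction of shared edges.
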