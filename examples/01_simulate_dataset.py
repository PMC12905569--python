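"""Generate a synthetic coposting dataset with planted structure.

Builds posts for 2,000 users over 12 disorders arranged in 3 planted blocks
plus one isolated disorder, then prints the dataset summary after applying
the study filters (posts from 2022 only; users with >365 posts or on a bot
list removed wholesale).
"""
from copanet import ingest, synth

config = synth.demo_config(n_users=2000, n_disorders=12, n_blocks=3,
                           n_isolated=1, seed=7, bot_fraction=0.01)
posts, mapping, truth = synth.generate_posts(config)
filtered = ingest.filter_posts(posts)
graph = ingest.build_bipartite(filtered, mapping)
summary = ingest.dataset_summary(filtered, graph, mapping)

print(f"raw posts:            {len(posts):>7}")
for key, value in summary.items():
    print(f"{key:<22}{value:>7}")
print(f"planted blocks:       {[len(b) for b in truth.blocks]} disorders")
print(f"isolated disorders:   {truth.isolated}")
# mean_posts_per_user is the average activity after bot removal; the
# multi_community share is the fraction of users whose coposting carries any
# association signal at all.
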