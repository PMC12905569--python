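"""Synthetic coposting data with planted association structure.

The generator emulates the statistical shape of posting in condition-specific
communities: a heavy-tailed posts-per-user distribution, a membership-first
user model (a user's set of disorders is drawn before posts are allocated,
because downstream inference operates on the binary user-disorder layer),
planted positive/negative co-membership between chosen disorder pairs,
block-structured clusters, isolated disorders, and a configurable fraction of
bot-like accounts posting more than once per day on average.

Membership model: each user draws a primary disorder from the baseline
participation vector, then joins each other disorder d independently with
probability ``secondary_rate × baseline[d] × factor(primary, d)``, where the
factor is a planted boost (> 1), a planted suppression (in [0, 1)), or 1.
With no planted structure the membership law is exchangeable across disorders
up to the baseline vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

YEAR_START = pd.Timestamp("2022-01-01T00:00:00Z")
YEAR_END = pd.Timestamp("2023-01-01T00:00:00Z")

# toy sentences for the self-reference validator; self-dominant first
_SELF_TEMPLATES = [
    "I feel like I cannot get out of bed and I hate myself for it",
    "me and myself again, I keep spiraling",
    "I think I finally understand what I have been going through",
]
_OTHER_TEMPLATES = [
    "you should talk to them about what they said",
    "her doctor told them it was fine, you know",
    "they keep asking about him and his family",
]


@dataclass
class DisorderSpec:
    """One synthetic disorder: its code, F-category, and community count."""

    code: str
    category: str
    n_communities: int = 1
    label: str = ""


@dataclass
class SynthConfig:
    n_users: int = 1000
    disorders: list[DisorderSpec] = field(default_factory=list)
    activity_exponent: float = 2.5
    activity_min: int = 1
    activity_cap: int = 1000
    baseline_participation: list[float] | None = None  # default: uniform
    secondary_rate: float = 0.18
    planted_positive: list[tuple[str, str, float]] = field(default_factory=list)
    planted_negative: list[tuple[str, str, float]] = field(default_factory=list)
    planted_clusters: list[list[str]] | None = None
    cluster_boost: float = 8.0
    isolated_disorders: list[str] = field(default_factory=list)
    bot_fraction: float = 0.0
    text_fraction: float = 0.0
    self_dominant_share: float = 0.7
    seed: int = 0

    def codes(self) -> list[str]:
        return [d.code for d in self.disorders]

    @staticmethod
    def _check_pair(a: str, b: str, codes: list[str], where: str) -> None:
        if a == b or a not in codes or b not in codes:
            raise ConfigError(f"{where} pair ({a},{b}) must name two distinct "
                              "known disorders")

    def validate(self) -> None:
        if self.n_users <= 0:
            raise ConfigError("n_users must be positive")
        if not self.disorders:
            raise ConfigError("disorders must be non-empty")
        codes = self.codes()
        if len(set(codes)) != len(codes):
            raise ConfigError("disorders contains duplicate codes")
        if any(d.n_communities < 1 for d in self.disorders):
            raise ConfigError("n_communities must be >= 1 for every disorder")
        if self.baseline_participation is not None:
            p = np.asarray(self.baseline_participation, dtype=float)
            if len(p) != len(codes):
                raise ConfigError("baseline_participation length mismatch")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError("baseline_participation must be a probability "
                                  "vector summing to 1")
        if not 0 <= self.secondary_rate <= 1:
            raise ConfigError("secondary_rate must be in [0, 1]")
        if self.activity_exponent <= 1:
            raise ConfigError("activity_exponent must exceed 1")
        if not 1 <= self.activity_min <= self.activity_cap:
            raise ConfigError("activity_min must be in [1, activity_cap]")
        for a, b, boost in self.planted_positive:
            if boost <= 1:
                raise ConfigError(f"planted_positive boost for ({a},{b}) must be > 1")
            self._check_pair(a, b, codes, "planted_positive")
        for a, b, fac in self.planted_negative:
            if not 0 <= fac < 1:
                raise ConfigError(f"planted_negative factor for ({a},{b}) must be "
                                  "in [0, 1)")
            self._check_pair(a, b, codes, "planted_negative")
        if self.planted_clusters is not None:
            flat = [c for block in self.planted_clusters for c in block]
            if len(set(flat)) != len(flat) or not set(flat) <= set(codes):
                raise ConfigError("planted_clusters must be disjoint blocks of "
                                  "known codes")
            if self.cluster_boost <= 1:
                raise ConfigError("cluster_boost must be > 1")
        if not set(self.isolated_disorders) <= set(codes):
            raise ConfigError("isolated_disorders contains unknown codes")
        iso = set(self.isolated_disorders)
        for a, b, _ in self.planted_positive + self.planted_negative:
            if a in iso or b in iso:
                raise ConfigError("isolated_disorders cannot appear in planted "
                                  "pairs")
        if self.planted_clusters:
            for block in self.planted_clusters:
                if len(block) > 1 and iso & set(block):
                    raise ConfigError("isolated_disorders cannot share a planted "
                                      "block")
        if not 0 <= self.bot_fraction < 1:
            raise ConfigError("bot_fraction must be in [0, 1)")
        if not 0 <= self.text_fraction <= 1:
            raise ConfigError("text_fraction must be in [0, 1]")
        if not 0 <= self.self_dominant_share <= 1:
            raise ConfigError("self_dominant_share must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure as emitted alongside the synthetic tables."""

    pairs: pd.DataFrame          # pair_a, pair_b, sign, factor
    blocks: list[list[str]] | None
    isolated: list[str]

    def block_partition(self) -> dict[str, int]:
        """Planted block labels; unblocked codes get their own cluster."""
        labels: dict[str, int] = {}
        for k, block in enumerate(self.blocks or []):
            for c in block:
                labels[c] = k
        return labels


def _factor_matrix(config: SynthConfig) -> np.ndarray:
    codes = config.codes()
    idx = {c: i for i, c in enumerate(codes)}
    n = len(codes)
    fac = np.ones((n, n))
    for block in config.planted_clusters or []:
        for a in block:
            for b in block:
                if a != b:
                    fac[idx[a], idx[b]] = config.cluster_boost
    for a, b, boost in config.planted_positive:
        fac[idx[a], idx[b]] = fac[idx[b], idx[a]] = boost
    for a, b, f in config.planted_negative:
        fac[idx[a], idx[b]] = fac[idx[b], idx[a]] = f
    for c in config.isolated_disorders:
        fac[idx[c], :] = 0.0
        fac[:, idx[c]] = 0.0
    return fac


def _sample_activity(rng: np.random.Generator, n: int, exponent: float,
                     lo: int, hi: int) -> np.ndarray:
    """Discrete power law on {lo..hi}: P(k) ∝ k^(-exponent)."""
    ks = np.arange(lo, hi + 1, dtype=float)
    p = ks ** (-exponent)
    p /= p.sum()
    return rng.choice(np.arange(lo, hi + 1), size=n, p=p)


def sample_memberships(config: SynthConfig, rng: np.random.Generator
                       ) -> np.ndarray:
    """Boolean user × disorder membership matrix under the planted model."""
    codes = config.codes()
    n_d = len(codes)
    baseline = (np.full(n_d, 1.0 / n_d)
                if config.baseline_participation is None
                else np.asarray(config.baseline_participation, dtype=float))
    primary = rng.choice(n_d, size=config.n_users, p=baseline)
    fac = _factor_matrix(config)
    q = np.clip(config.secondary_rate * baseline[None, :] * fac[primary], 0, 1)
    member = rng.random((config.n_users, n_d)) < q
    member[np.arange(config.n_users), primary] = True
    return member


def generate_posts(config: SynthConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Synthetic post table, community mapping table, and planted ground truth.

    Deterministic given ``config.seed``.  Every membership is realized by at
    least one post, so the bipartite graph built downstream recovers the
    sampled membership matrix exactly (before any activity filtering).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes = config.codes()
    member = sample_memberships(config, rng)

    n_posts = _sample_activity(rng, config.n_users, config.activity_exponent,
                               config.activity_min, config.activity_cap)
    is_bot = rng.random(config.n_users) < config.bot_fraction
    bot_hi = max(config.activity_cap, 730)
    n_posts = np.where(is_bot, rng.integers(366, bot_hi + 1, config.n_users),
                       n_posts)
    n_members = member.sum(axis=1)
    n_posts = np.maximum(n_posts, n_members)  # every membership gets a post

    communities = {c: [f"r_{c}_{k}" for k in range(d.n_communities)]
                   for c, d in zip(codes, config.disorders)}

    users, comms = [], []
    for u in range(config.n_users):
        uid = f"u{u:06d}"
        mine = np.nonzero(member[u])[0]
        # one post per member disorder, remainder spread uniformly
        alloc = np.ones(len(mine), dtype=np.int64)
        extra = int(n_posts[u]) - len(mine)
        if extra > 0:
            alloc += rng.multinomial(extra, np.full(len(mine), 1 / len(mine)))
        for di, cnt in zip(mine, alloc):
            opts = communities[codes[di]]
            picks = rng.integers(0, len(opts), cnt)
            for pick in picks:
                users.append(uid)
                comms.append(opts[pick])
    total = len(users)
    offsets = rng.integers(0, int((YEAR_END - YEAR_START).total_seconds()),
                           total)
    created = (YEAR_START + pd.to_timedelta(offsets, unit="s"))
    posts = pd.DataFrame({
        "user_id": users,
        "community": comms,
        "created_utc": created,
        "post_id": [f"p{k:08d}" for k in range(total)],
    })
    if config.text_fraction > 0:
        has_text = rng.random(total) < config.text_fraction
        self_dom = rng.random(total) < config.self_dominant_share
        texts = np.full(total, None, dtype=object)
        for k in np.nonzero(has_text)[0]:
            pool = _SELF_TEMPLATES if self_dom[k] else _OTHER_TEMPLATES
            texts[k] = pool[rng.integers(0, len(pool))]
        posts["text"] = texts
    posts = posts.sample(frac=1.0, random_state=config.seed).reset_index(drop=True)

    mapping = pd.DataFrame([
        {
            "community": comm,
            "icd10_l4": d.code,
            "icd10_l3": d.code.split(".")[0],
            "icd10_l2": d.category,
            "label": d.label or d.code,
            "icd11": "",
        }
        for d in config.disorders for comm in communities[d.code]
    ])

    rows = [{"pair_a": min(a, b), "pair_b": max(a, b), "sign": "positive",
             "factor": boost} for a, b, boost in config.planted_positive]
    rows += [{"pair_a": min(a, b), "pair_b": max(a, b), "sign": "negative",
              "factor": f} for a, b, f in config.planted_negative]
    for block in config.planted_clusters or []:
        for i, a in enumerate(sorted(block)):
            for b in sorted(block)[i + 1:]:
                rows.append({"pair_a": a, "pair_b": b, "sign": "positive",
                             "factor": config.cluster_boost})
    truth = GroundTruth(
        pairs=pd.DataFrame(rows, columns=["pair_a", "pair_b", "sign", "factor"]),
        blocks=config.planted_clusters,
        isolated=list(config.isolated_disorders),
    )
    return posts, mapping, truth


def demo_config(n_users: int = 2000, n_disorders: int = 12, n_blocks: int = 3,
                n_isolated: int = 1, seed: int = 0,
                bridge_boost: float | None = None, **overrides) -> SynthConfig:
    """A ready-made configuration with planted block structure.

    Disorders get ICD-style codes spread over the F0–F8 categories; the first
    ``n_disorders − n_isolated`` disorders are split into ``n_blocks``
    contiguous blocks (so blocks cut across categories, as transdiagnostic
    clusters do), and the last ``n_isolated`` disorders share no users with
    anything else.  With ``bridge_boost`` set, one weak positive pair links
    each pair of consecutive blocks, so the association layer forms a single
    giant component spanning the blocks while the blocks stay resolvable.
    """
    if n_disorders - n_isolated < n_blocks:
        raise ConfigError("n_disorders minus n_isolated must be >= n_blocks")
    disorders = [
        DisorderSpec(code=f"F{i % 9}{i // 9}.0", category=f"F{i % 9}",
                     n_communities=1 + (i % 2))
        for i in range(n_disorders)
    ]
    codes = [d.code for d in disorders]
    clusterable = codes[:n_disorders - n_isolated] if n_isolated else codes
    blocks = [list(b) for b in np.array_split(np.array(clusterable), n_blocks)]
    bridges = []
    if bridge_boost is not None:
        bridges = [(blocks[k][-1], blocks[k + 1][0], bridge_boost)
                   for k in range(n_blocks - 1)]
    config = SynthConfig(
        planted_positive=bridges,
        n_users=n_users,
        disorders=disorders,
        planted_clusters=blocks,
        isolated_disorders=codes[n_disorders - n_isolated:] if n_isolated else [],
        seed=seed,
        **overrides,
    )
    config.validate()
    return config


def generate_criteria(disorders: list[str], blocks: list[list[str]],
                      n_criteria_per_disorder: int, shared_within_block: int,
                      seed: int = 0) -> pd.DataFrame:
    """Disorder → criterion table where same-block disorders share exactly
    ``shared_within_block`` criterion ids and cross-block sharing is zero."""
    if not disorders:
        raise ConfigError("disorders must be non-empty")
    if shared_within_block > n_criteria_per_disorder:
        raise ConfigError("shared_within_block cannot exceed "
                          "n_criteria_per_disorder")
    flat = [c for b in blocks for c in b]
    if len(set(flat)) != len(flat) or set(flat) - set(disorders):
        raise ConfigError("blocks must be disjoint subsets of disorders")
    block_of = {c: k for k, b in enumerate(blocks) for c in b}
    rows = []
    for code in disorders:
        k = block_of.get(code)
        n_shared = shared_within_block if k is not None and len(blocks[k]) > 1 else 0
        for j in range(n_shared):
            rows.append({"icd10_code": code, "criterion_id": f"blk{k}_c{j}"})
        for j in range(n_criteria_per_disorder - n_shared):
            rows.append({"icd10_code": code, "criterion_id": f"{code}_c{j}"})
    return pd.DataFrame(rows, columns=["icd10_code", "criterion_id"])


def block_similarity_network(seed: int | np.random.Generator = 0,
                             n_blocks: int = 3, block_size: int = 4,
                             w_in: float = 0.5, w_out: float = 0.05,
                             p_in: float = 1.0, p_out: float = 0.3,
                             noise: float = 0.15):
    """Planted-block weighted similarity network over disorder codes.

    Within-block pairs are linked with probability ``p_in`` at weights around
    ``w_in``; between-block pairs with probability ``p_out`` around ``w_out``;
    multiplicative log-normal noise keeps weights positive.  Returns
    (DisorderNetwork, ground-truth blocks).  Sparse between-block linking
    keeps the topology non-rigid, so degree-preserving rewiring can actually
    randomize it.
    """
    import networkx as nx

    from .networks import DisorderNetwork

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    codes = [f"F{b}{i}.0" for b in range(n_blocks) for i in range(block_size)]
    blocks = [codes[b * block_size:(b + 1) * block_size]
              for b in range(n_blocks)]
    block_of = {c: b for b, blk in enumerate(blocks) for c in blk}
    g = nx.Graph()
    g.add_nodes_from(codes)
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            same = block_of[a] == block_of[b]
            if rng.random() < (p_in if same else p_out):
                base = w_in if same else w_out
                g.add_edge(a, b, weight=base * float(
                    np.exp(noise * rng.standard_normal())))
    return DisorderNetwork(g), blocks


def write_outputs(posts: pd.DataFrame, mapping: pd.DataFrame,
                  truth: GroundTruth, out_dir, fmt: str = "csv") -> dict:
    """Write the synthetic tables to ``out_dir``; returns the path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    posts_out = posts.copy()
    posts_out["created_utc"] = posts_out["created_utc"].dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    if fmt == "jsonl":
        paths["posts"] = out / "posts.jsonl"
        posts_out.to_json(paths["posts"], orient="records", lines=True)
    else:
        paths["posts"] = out / "posts.csv"
        posts_out.to_csv(paths["posts"], index=False)
    paths["mapping"] = out / "mapping.csv"
    mapping.to_csv(paths["mapping"], index=False)
    paths["ground_truth"] = out / "ground_truth.csv"
    truth.pairs.to_csv(paths["ground_truth"], index=False)
    return paths
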