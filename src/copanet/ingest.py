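"""Reading and filtering post data; building the user-disorder bipartite graph.

Exclusion rules applied here, in order: restrict to the study-year window,
then drop every post of any user with more than ``max_posts`` retained posts
(a rate of more than one post per day over a year) or whose id is on the
supplied bot list.  Removal is user-level: an excluded user contributes no
posts at all.
"""
from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyGraphError, EmptyInputError, UndefinedMetricError
from .networks import UserDisorderGraph

log = logging.getLogger(__name__)

REQUIRED_POST_FIELDS = ("user_id", "community", "created_utc", "post_id")

DEFAULT_SELF_LEXICON = frozenset({"i", "me", "myself"})
DEFAULT_OTHER_LEXICON = frozenset({
    "you", "your", "yours", "yourself", "he", "him", "his",
    "she", "her", "hers", "they", "them", "their", "theirs",
})


def _parse_row(row: dict) -> dict | None:
    for f in REQUIRED_POST_FIELDS:
        v = row.get(f)
        if v is None or (isinstance(v, str) and not v.strip()):
            return None
    ts = pd.to_datetime(row["created_utc"], utc=True, errors="coerce")
    if pd.isna(ts):
        return None
    out = {f: str(row[f]) for f in ("user_id", "community", "post_id")}
    out["created_utc"] = ts
    text = row.get("text")
    out["text"] = text if isinstance(text, str) and text != "" else None
    return out


def load_posts(path, fmt: str | None = None) -> tuple[pd.DataFrame, int]:
    """Read a post table from CSV or JSONL; returns (table, rejected rows).

    Malformed rows (missing required field, unparseable timestamp, invalid
    JSON line) are counted and skipped rather than aborting the load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in (".jsonl", ".json") else "csv"
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"unsupported format {fmt!r}")
    rows, rejects = [], 0
    with open(path, encoding="utf-8") as fh:
        if fmt == "csv":
            raw_iter = csv.DictReader(fh)
        else:
            def _jsonl(f):
                for line in f:
                    line = line.strip()
                    if not line:
                        continue
                    try:
                        yield json.loads(line)
                    except json.JSONDecodeError:
                        yield None
            raw_iter = _jsonl(fh)
        for raw in raw_iter:
            parsed = _parse_row(raw) if isinstance(raw, dict) else None
            if parsed is None:
                rejects += 1
            else:
                rows.append(parsed)
    if not rows:
        raise EmptyInputError(f"no valid post rows in {path}")
    if rejects:
        log.warning("skipped %d malformed rows in %s", rejects, path)
    table = pd.DataFrame(rows)
    if table["post_id"].duplicated().any():
        raise ValueError("post_id values are not unique")
    return table, rejects


def load_mapping(path) -> pd.DataFrame:
    """Community → ICD-10 mapping table; validates the one-to-one constraints."""
    mapping = pd.read_csv(path, dtype=str).fillna("")
    needed = {"community", "icd10_l4", "icd10_l2"}
    if missing := needed - set(mapping.columns):
        raise ValueError(f"mapping table missing columns: {sorted(missing)}")
    if mapping["community"].duplicated().any():
        raise ValueError("a community maps to more than one disorder")
    cats = mapping.groupby("icd10_l4")["icd10_l2"].nunique()
    if (cats > 1).any():
        bad = cats[cats > 1].index.tolist()
        raise ValueError(f"disorders mapped to multiple categories: {bad}")
    return mapping


def load_criteria(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype=str)
    if missing := {"icd10_code", "criterion_id"} - set(table.columns):
        raise ValueError(f"criteria table missing columns: {sorted(missing)}")
    return table


def load_bot_list(path) -> set[str]:
    """Plain-text bot list, one user id per line; exact-match semantics."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def filter_posts(posts: pd.DataFrame,
                 window: tuple = ("2022-01-01", "2023-01-01"),
                 max_posts: int = 365,
                 bot_list: set[str] | None = None) -> pd.DataFrame:
    """Apply the study filters; idempotent.

    Posts outside the half-open UTC window [start, end) are dropped first;
    the activity threshold is then evaluated on the retained posts so it acts
    as a within-window rate.  A user with more than ``max_posts`` retained
    posts (strictly more; exactly ``max_posts`` is kept) or on the bot list is
    removed wholesale.
    """
    start = pd.Timestamp(window[0], tz="UTC")
    end = pd.Timestamp(window[1], tz="UTC")
    if start >= end:
        raise ValueError("window start must precede end")
    kept = posts[(posts["created_utc"] >= start) & (posts["created_utc"] < end)]
    counts = kept["user_id"].value_counts()
    heavy = set(counts[counts > max_posts].index)
    drop = heavy | (bot_list or set())
    out = kept[~kept["user_id"].isin(drop)].reset_index(drop=True)
    if drop & set(counts.index):
        log.info("removed %d users (activity > %d or bot-listed)",
                 len(drop & set(counts.index)), max_posts)
    if out.empty:
        log.warning("all posts removed by filtering")
    return out


def build_bipartite(posts: pd.DataFrame, mapping: pd.DataFrame
                    ) -> UserDisorderGraph:
    """Binary user-disorder graph: edge (u, d) iff u posted in a community
    mapped to d.  Posts in unmapped communities are dropped with a log line."""
    comm_to_dis = dict(zip(mapping["community"], mapping["icd10_l4"]))
    dis = posts["community"].map(comm_to_dis)
    unmapped = int(dis.isna().sum())
    if unmapped:
        log.warning("dropped %d posts in unmapped communities", unmapped)
    pairs = pd.DataFrame({"user_id": posts["user_id"], "disorder": dis}).dropna()
    if pairs.empty:
        raise EmptyGraphError("no posts in mapped communities")
    pairs = pairs.drop_duplicates()
    users = np.array(sorted(pairs["user_id"].unique()), dtype=object)
    disorders = np.array(sorted(pairs["disorder"].unique()), dtype=object)
    uidx = {u: i for i, u in enumerate(users)}
    didx = {d: i for i, d in enumerate(disorders)}
    eu = pairs["user_id"].map(uidx).to_numpy(dtype=np.int64)
    ed = pairs["disorder"].map(didx).to_numpy(dtype=np.int64)
    order = np.lexsort((ed, eu))
    return UserDisorderGraph(users, disorders, eu[order], ed[order])


def dataset_summary(posts: pd.DataFrame, graph: UserDisorderGraph,
                    mapping: pd.DataFrame | None = None) -> dict:
    """Headline dataset statistics (means and shares to 2 decimals)."""
    if posts.empty or graph.n_edges == 0:
        raise EmptyInputError("summary needs non-empty posts and graph")
    n_posts = len(posts)
    n_users = posts["user_id"].nunique()
    per_user_comms = posts.groupby("user_id")["community"].nunique()
    n_multi = int((per_user_comms >= 2).sum())
    out = {
        "total_posts": int(n_posts),
        "unique_users": int(n_users),
        "mean_posts_per_user": round(n_posts / n_users, 2),
        "multi_community_users": n_multi,
        "multi_community_pct": round(100.0 * n_multi / n_users, 2),
        "n_disorders": graph.n_disorders,
    }
    if mapping is not None:
        out["n_categories"] = int(mapping["icd10_l2"].nunique())
        out["n_communities"] = int(mapping["community"].nunique())
    return out


def _token_count(text: str, lexicon: frozenset[str] | set[str]) -> int:
    tokens = re.findall(r"[a-z']+", text.lower())
    return sum(t in lexicon for t in tokens)


def pronoun_self_ratio(texts,
                       self_lexicon=DEFAULT_SELF_LEXICON,
                       other_lexicon=DEFAULT_OTHER_LEXICON) -> float:
    """Fraction of texts whose self-referential pronoun count strictly exceeds
    the other-referential count (ties do not qualify).

    Accepts an iterable of strings or a post table with a ``text`` column;
    entries without text are excluded from the denominator.
    """
    if not self_lexicon or not other_lexicon:
        raise ValueError("lexicons must be non-empty")
    if isinstance(texts, pd.DataFrame):
        if "text" not in texts.columns:
            raise UndefinedMetricError("post table has no text column")
        texts = texts["text"]
    usable = [t for t in texts if isinstance(t, str) and t.strip()]
    if not usable:
        raise UndefinedMetricError("no posts with text")
    self_lex = frozenset(w.lower() for w in self_lexicon)
    other_lex = frozenset(w.lower() for w in other_lexicon)
    wins = sum(_token_count(t, self_lex) > _token_count(t, other_lex)
               for t in usable)
    return wins / len(usable)
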