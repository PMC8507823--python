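"""Synthetic social-media corpus generator with planted ground truth.

Generates Reddit-like post/comment events over four communities (one general
teen community, three mental-health communities) and two latent cohorts:
MH users participate in the teen community and at least one mental-health
community; NMH users only in the teen community. Weekly per-user item counts
are Poisson with a per-user gamma activity multiplier (negative binomial
marginally), whose weekly mean follows a segmented linear trend with a
level/slope break at the interruption week. Texts are bag-of-words mixtures
of emotion-lexicon words and neutral words, so downstream scoring has an
analytic ground truth.

Every planted parameter (cohort labels, multipliers, rate parameters, the
implied segmented-regression coefficients) is written to a separate
ground-truth ledger, never embedded in the records themselves.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .aggregate import _year_epoch_bounds
from .config import (
    DELETED_MARKER,
    EMOTIONS,
    MH,
    MH_COMMUNITIES,
    MIX_CLASSES,
    NMH,
    SimConfig,
    TEEN_COMMUNITY,
)
from .emotion import Lexicon, load_lexicon

__all__ = [
    "PostRecord",
    "UserEntry",
    "simulate_weekly_counts",
    "render_text",
    "generate_corpus",
    "write_ndjson",
    "write_csv",
    "write_ledger",
    "load_neutral_words",
]

WEEK_SECONDS = 7 * 86400


class PostRecord(BaseModel):
    """One post or comment event."""

    model_config = ConfigDict(frozen=True)

    id: str
    author: str
    community: str
    created_utc: float
    title: str = ""
    body: str
    kind: str


@dataclass(frozen=True)
class UserEntry:
    """Roster entry: planted cohort label and activity multiplier."""

    username: str
    cohort: str
    multiplier: float
    mh_homes: Tuple[str, ...] = ()


def load_neutral_words() -> List[str]:
    text = resources.files("emotrend.resources").joinpath("neutral_words.txt").read_text("utf-8")
    return [w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")]


def class_vocabularies(lexicon: Optional[Lexicon] = None) -> Dict[str, List[str]]:
    """Token-class -> word list used by the renderer: the five emotion
    classes from the lexicon plus the neutral vocabulary."""
    lexicon = lexicon or load_lexicon()
    vocab = {e: lexicon.words_for(e) for e in EMOTIONS}
    vocab["neutral"] = load_neutral_words()
    return vocab


def _intensities(config: SimConfig, cohort: str) -> np.ndarray:
    t = np.arange(1, config.n_weeks + 1)
    lam = config.rate_params[cohort].intensity(t, config.interruption_week)
    lam = np.maximum(lam, config.intensity_floor)
    if np.any(lam <= 0):
        raise ValueError(f"non-positive weekly intensity for cohort {cohort}")
    return lam


def simulate_weekly_counts(config: SimConfig, user: UserEntry, rng: np.random.Generator) -> np.ndarray:
    """Per-week item counts for one user in the teen community: Poisson draws
    with weekly mean ``multiplier * segmented intensity`` (floored at a small
    positive value)."""
    lam = user.multiplier * _intensities(config, user.cohort)
    return rng.poisson(lam)


def render_text(
    mixture: Dict[str, float],
    length: int,
    vocab: Dict[str, Sequence[str]],
    rng: np.random.Generator,
) -> str:
    """Draw ``length`` tokens, each from the vocabulary of an emotion class
    (or the neutral vocabulary) chosen with the mixture proportions."""
    classes = [c for c in MIX_CLASSES if mixture.get(c, 0.0) > 0]
    probs = np.array([mixture[c] for c in classes])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {probs.sum()}, not 1")
    for c in classes:
        if not vocab.get(c):
            raise ValueError(f"empty vocabulary for class {c!r} with positive weight")
    draws = rng.choice(len(classes), size=length, p=probs)
    words = []
    for i in draws:
        wl = vocab[classes[i]]
        words.append(wl[rng.integers(len(wl))])
    return " ".join(words)


def _draw_roster(config: SimConfig, rng: np.random.Generator) -> List[UserEntry]:
    n = config.n_users
    is_mh = rng.random(n) < config.fraction_mh
    if config.user_heterogeneity > 0:
        h2 = config.user_heterogeneity**2
        mult = rng.gamma(shape=1.0 / h2, scale=h2, size=n)
    else:
        mult = np.ones(n)
    roster = []
    for i in range(n):
        homes: Tuple[str, ...] = ()
        if is_mh[i]:
            mask = rng.random(len(MH_COMMUNITIES)) < 0.4
            if not mask.any():
                mask[rng.integers(len(MH_COMMUNITIES))] = True
            homes = tuple(c for c, m in zip(MH_COMMUNITIES, mask) if m)
        roster.append(
            UserEntry(
                username=f"u{i:06d}",
                cohort=MH if is_mh[i] else NMH,
                multiplier=float(mult[i]),
                mh_homes=homes,
            )
        )
    return roster


def _expand_events(
    counts: np.ndarray, user_idx: np.ndarray, community: str, week_starts: np.ndarray, rng
) -> pd.DataFrame:
    """Turn a (users x weeks) count matrix into one row per event."""
    u, w = np.nonzero(counts)
    reps = counts[u, w]
    users = np.repeat(user_idx[u], reps)
    weeks = np.repeat(w + 1, reps)
    ts = np.repeat(week_starts[w], reps) + rng.uniform(0, WEEK_SECONDS, size=reps.sum())
    return pd.DataFrame(
        {"user_idx": users, "week": weeks, "community": community, "created_utc": np.floor(ts)}
    )


def generate_corpus(
    config: SimConfig,
    with_text: bool = True,
    lexicon: Optional[Lexicon] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Generate the full event corpus plus its ground-truth ledger.

    Returns ``(records, ledger)`` where records has the PostRecord fields in
    deterministic order (same seed -> identical corpus) and the ledger holds
    every planted parameter, the per-user cohort labels and multipliers, and
    the implied stacked segmented-regression coefficients.
    """
    rng = np.random.default_rng(config.seed)
    id_prefix = f"{rng.integers(16**6):06x}"
    roster = _draw_roster(config, rng)
    cohorts = np.array([u.cohort for u in roster])
    mult = np.array([u.multiplier for u in roster])

    _, first_week_epoch, n_complete = _year_epoch_bounds(config.year)
    if config.n_weeks > n_complete:
        raise ValueError(f"n_weeks={config.n_weeks} exceeds the {n_complete} complete weeks of {config.year}")
    week_starts = first_week_epoch + WEEK_SECONDS * np.arange(config.n_weeks)

    frames = []
    # teen community: segmented trend per cohort
    lam = np.empty((config.n_users, config.n_weeks))
    for cohort in (NMH, MH):
        sel = cohorts == cohort
        lam[sel] = mult[sel, None] * _intensities(config, cohort)[None, :]
    counts = rng.poisson(lam)
    # guarantee every rostered user appears in the teen community
    silent = counts.sum(axis=1) == 0
    if silent.any():
        counts[np.nonzero(silent)[0], rng.integers(config.n_weeks, size=int(silent.sum()))] += 1
    frames.append(_expand_events(counts, np.arange(config.n_users), TEEN_COMMUNITY, week_starts, rng))

    # mental-health communities: constant low rate for MH users' home communities
    mh_idx = np.nonzero(cohorts == MH)[0]
    for community in MH_COMMUNITIES:
        members = np.array([i for i in mh_idx if community in roster[i].mh_homes], dtype=int)
        if members.size == 0:
            continue
        c = rng.poisson(
            config.mh_community_rate * mult[members, None],
            size=(members.size, config.n_weeks),
        )
        frames.append(_expand_events(c, members, community, week_starts, rng))
    # guarantee every MH user has at least one mental-health item
    seen = set()
    for f in frames[1:]:
        seen.update(f["user_idx"].unique())
    missing = [i for i in mh_idx if i not in seen]
    if missing:
        extra = pd.DataFrame(
            {
                "user_idx": missing,
                "week": rng.integers(1, config.n_weeks + 1, size=len(missing)),
                "community": [roster[i].mh_homes[0] for i in missing],
                "created_utc": np.nan,
            }
        )
        extra["created_utc"] = np.floor(
            week_starts[extra["week"].to_numpy() - 1] + rng.uniform(0, WEEK_SECONDS, len(missing))
        )
        frames.append(extra)

    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["created_utc", "community", "user_idx"], kind="stable").reset_index(drop=True)

    n = len(events)
    events["id"] = [f"{id_prefix}{i:08x}" for i in range(n)]
    events["author"] = np.array([u.username for u in roster])[events["user_idx"]]
    events["kind"] = np.where(rng.random(n) < config.post_fraction, "post", "comment")

    n_deleted = 0
    if config.deleted_fraction > 0:
        deleted = rng.random(n) < config.deleted_fraction
        n_deleted = int(deleted.sum())
        events.loc[deleted, "author"] = DELETED_MARKER

    if with_text:
        _attach_texts(events, cohorts, config, lexicon, rng)
    else:
        events["title"] = ""
        events["body"] = ""

    records = events[["id", "author", "community", "created_utc", "title", "body", "kind"]].copy()
    ledger = {
        "config": json.loads(config.model_dump_json()),
        "id_prefix": id_prefix,
        "n_records": n,
        "n_deleted_marked": n_deleted,
        "planted_coefficients": planted_coefficients(config),
        "week_start_epochs": [int(s) for s in week_starts],
        "users": {
            u.username: {
                "cohort": u.cohort,
                "multiplier": u.multiplier,
                "mh_homes": list(u.mh_homes),
            }
            for u in roster
        },
    }
    return records, ledger


def _attach_texts(events, cohorts, config, lexicon, rng) -> None:
    vocab = class_vocabularies(lexicon)
    user_cohort = cohorts[events["user_idx"].to_numpy()]
    lo, hi = config.text_length_range
    lengths = rng.integers(lo, hi + 1, size=len(events))
    is_post = (events["kind"] == "post").to_numpy()
    title_len = np.where(is_post, 3, 0)

    bodies = np.empty(len(events), dtype=object)
    titles = np.empty(len(events), dtype=object)
    group_key = pd.Series(
        [f"{c}|{coh}" for c, coh in zip(events["community"], user_cohort)], index=events.index
    )
    for key, idx in group_key.groupby(group_key).groups.items():
        community, cohort = key.split("|")
        mix = config.mix_for(community, cohort)
        classes = [c for c in MIX_CLASSES if mix.get(c, 0.0) > 0]
        probs = np.array([mix[c] for c in classes])
        probs = probs / probs.sum()
        pos = events.index.get_indexer(idx)
        total = int(lengths[pos].sum() + title_len[pos].sum())
        class_draws = rng.choice(len(classes), size=total, p=probs)
        words = np.empty(total, dtype=object)
        for ci, cname in enumerate(classes):
            wl = vocab[cname]
            if not wl:
                raise ValueError(f"empty vocabulary for class {cname!r} with positive weight")
            sel = class_draws == ci
            words[sel] = np.array(wl, dtype=object)[rng.integers(len(wl), size=int(sel.sum()))]
        offset = 0
        for p in pos:
            tl, bl = int(title_len[p]), int(lengths[p])
            titles[p] = " ".join(words[offset : offset + tl])
            offset += tl
            bodies[p] = " ".join(words[offset : offset + bl])
            offset += bl
    events["title"] = titles
    events["body"] = bodies


def planted_coefficients(config: SimConfig) -> Dict[str, float]:
    """The stacked two-group segmented-regression coefficients implied by the
    planted rate parameters (NMH is the reference group)."""
    nmh, mh = config.rate_params[NMH], config.rate_params[MH]
    return {
        "b0": nmh.level,
        "b1": nmh.slope,
        "b2": nmh.level_change,
        "b3": nmh.slope_change,
        "b4": mh.level - nmh.level,
        "b5": mh.slope - nmh.slope,
        "b6": mh.level_change - nmh.level_change,
        "b7": mh.slope_change - nmh.slope_change,
    }


# ---------------------------------------------------------------------------
# writers


def write_ndjson(records: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in records.itertuples(index=False):
            fh.write(json.dumps(row._asdict(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def write_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_ledger(ledger: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
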