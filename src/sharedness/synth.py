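"""Synthetic daily-report studies with known ground truth.

The generator emulates a two-month workplace diary study: teams of 4-7
members rate their own well-being and the team's atmosphere on an 11-point
(0-10) grid each day and write a short diary. The statistical structure
mirrors what the sharedness analysis assumes:

* each team-week carries a latent atmosphere level mu_{t,w} and a latent
  spread s_{t,w} >= 0 (the *disagreement* of that team that week);
* a member's atmosphere rating is Normal(mu, s), clipped to [0, 10] and
  (by default) rounded back to the 11-point grid;
* a member's well-being is base + beta * (-s) + gamma * mu + noise, so the
  coupling between within-team agreement and well-being is a dial
  (coupling_beta = 0 is an exact null);
* diary tokens come from the team's shared topic with probability
  lambda(s) (a decreasing function, default exp(-s)) and otherwise from
  the member's idiosyncratic topic, so textual convergence tracks the
  same latent spread;
* one nine-item harmony questionnaire per member, whose team-level trait
  correlates with the team's average agreement via ihs_coupling.

Participation is intermittent: members are active with some probability,
active members submit on a member-specific Bernoulli rate (Beta-distributed
across members when ``participation_concentration`` is set), and weekends
see a reduced rate. Everything is driven by one integer seed.
"""

from __future__ import annotations

import datetime as dt
import math
import string
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .embeddings import EmbeddingTable
from .records import DailyReport, IHSRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "SpreadDist",
    "generate_embeddings",
    "generate_study",
    "EMOTIONS",
    "EMOTION_LEXICON",
]

EMOTIONS = ("sadness", "anxiety", "anger", "disgust", "trust", "surprise", "fun")

#: Deterministic stand-in lexicon: planted marker tokens per emotion
#: (tokenizer-safe: no punctuation, survives the default word split).
EMOTION_LEXICON: Mapping[str, tuple[str, ...]] = {
    emo: tuple(f"em{emo}{k}" for k in range(4)) for emo in EMOTIONS
}

_POSITIVE = {"trust", "fun"}
_NEGATIVE = {"sadness", "anxiety", "anger", "disgust"}


class SpreadDist(BaseModel):
    """Distribution of the latent per-team-week atmosphere spread s >= 0.

    kind 'gamma' uses (shape, scale); 'uniform' uses (low, high); 'fixed'
    uses value. Defaults follow typical daily atmosphere SDs of roughly
    0.7-2.2 on the 11-point grid.
    """

    kind: str = "gamma"
    shape: float = 2.5
    scale: float = 0.55
    low: float = 0.0
    high: float = 2.5
    value: float = 1.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.scale, size=size)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=size)
        if self.kind == "fixed":
            return np.full(size, float(self.value))
        raise ValueError(f"unknown spread distribution kind {self.kind!r}")

    @model_validator(mode="after")
    def _nonneg(self) -> "SpreadDist":
        if self.kind == "fixed" and self.value < 0:
            raise ValueError("spread must be >= 0")
        if self.kind == "uniform" and (self.low < 0 or self.high < self.low):
            raise ValueError("uniform spread needs 0 <= low <= high")
        return self


class GeneratorConfig(BaseModel):
    """All dials of the synthetic study; the seed fully determines output."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_teams: int = Field(default=23, ge=1)
    members_per_team: tuple[int, int] = (4, 7)
    anchor_date: dt.date = dt.date(2022, 9, 1)
    end_date: dt.date = dt.date(2022, 10, 31)

    member_active_prob: float = Field(default=0.75, ge=0, le=1)
    participation_prob: float = Field(default=0.25, ge=0, le=1)
    participation_concentration: float | None = 1.5
    weekend_factor: float = Field(default=0.25, ge=0, le=1)
    resubmit_prob: float = Field(default=0.05, ge=0, le=1)

    agreement_spread: SpreadDist = SpreadDist()
    atmosphere_mean: float = 6.4
    atmosphere_between_sd: float = Field(default=1.0, ge=0)
    coupling_beta: float = 0.65
    wellbeing_atmosphere_gamma: float = 0.3
    base_wellbeing: float = 5.65
    noise_sd: float = Field(default=1.8, ge=0)
    round_scores: bool = True

    with_text: bool = True
    vocab_size: int | None = None
    n_topics: int | None = None
    tokens_per_diary: tuple[int, int] = (6, 14)
    shared_token_prob_fn: Callable[[float], float] | None = None
    embedding_dim: int = Field(default=16, ge=2)
    topic_jitter: float = Field(default=0.5, ge=0)

    plant_emotions: bool = False
    n_emotion_tokens: int = Field(default=3, ge=1)

    ihs_coupling: float = Field(default=0.8, ge=-1, le=1)
    ihs_scale: tuple[float, float] = (1.0, 5.0)
    ihs_item_noise: float = Field(default=0.5, ge=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        lo, hi = self.members_per_team
        if not 1 <= lo <= hi:
            raise ValueError("members_per_team must be an increasing range of positive ints")
        if self.anchor_date > self.end_date:
            raise ValueError("empty study window")
        lo, hi = self.tokens_per_diary
        if not 0 <= lo <= hi:
            raise ValueError("tokens_per_diary must be a nondecreasing range")
        return self

    def lam(self, s: float) -> float:
        """Shared-topic probability lambda(s); decreasing in the spread."""
        fn = self.shared_token_prob_fn or (lambda x: math.exp(-x))
        val = float(fn(s))
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"shared_token_prob_fn must map into [0,1], got {val}")
        return val


@dataclass
class SyntheticGroundTruth:
    """Latents behind one generated study, keyed like the analysis units."""

    config: GeneratorConfig
    mu: dict[tuple[str, int], float]
    spread: dict[tuple[str, int], float]
    team_harmony: dict[str, float]
    team_members: dict[str, list[str]]
    active_members: dict[str, list[str]]
    member_topic: dict[str, int] = field(default_factory=dict)
    team_topic: dict[str, int] = field(default_factory=dict)
    embeddings: EmbeddingTable | None = None
    token_topics: dict[str, int] = field(default_factory=dict)
    report_emotions: dict[tuple[str, str], str] = field(default_factory=dict)


def _team_ids(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — letter-coded team ids."""
    ids = []
    letters = string.ascii_uppercase
    for i in range(n):
        name = ""
        k = i
        while True:
            name = letters[k % 26] + name
            k = k // 26 - 1
            if k < 0:
                break
        ids.append(name)
    return ids


def generate_embeddings(
    vocab_size: int,
    n_topics: int,
    embedding_dim: int,
    seed: int,
    topic_jitter: float = 0.5,
) -> tuple[EmbeddingTable, dict[str, int]]:
    """Topic-structured token vectors: centroid per topic plus isotropic jitter.

    Topic centroids are mutually separated by at least 4x the jitter scale
    (centroids are rescaled outward until the bound holds), every token
    belongs to exactly one topic, and the token -> topic map is returned
    alongside the table.
    """
    if embedding_dim < 2:
        raise ValueError("embedding_dim must be >= 2")
    if not vocab_size >= n_topics >= 1:
        raise ValueError("need vocab_size >= n_topics >= 1")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(size=(n_topics, embedding_dim))
    if n_topics > 1:
        diffs = centroids[:, None, :] - centroids[None, :, :]
        dists = np.sqrt((diffs**2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        min_sep = dists.min()
        target = 4.0 * topic_jitter if topic_jitter > 0 else 1e-6
        if min_sep < target:
            centroids *= target / min_sep if min_sep > 0 else 1.0
            # resample any exact duplicates (probability ~0) rather than loop
    vectors: dict[str, np.ndarray] = {}
    token_topics: dict[str, int] = {}
    for k in range(vocab_size):
        topic = k % n_topics
        tok = f"w{k:04d}"
        vectors[tok] = centroids[topic] + rng.normal(scale=topic_jitter, size=embedding_dim)
        token_topics[tok] = topic
    return EmbeddingTable(vectors), token_topics


def _draw_diary(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    topic_tokens: list[list[str]],
    team_topic: int,
    own_topic: int,
    lam: float,
) -> list[str]:
    lo, hi = cfg.tokens_per_diary
    n_tok = int(rng.integers(lo, hi + 1))
    shared = rng.random(n_tok) < lam
    toks = []
    for sh in shared:
        pool = topic_tokens[team_topic if sh else own_topic]
        toks.append(pool[int(rng.integers(len(pool)))])
    return toks


def _emotion_for(rng: np.random.Generator, wellbeing: float) -> str:
    """Latent emotion tied to well-being: positive labels more likely when high."""
    z = (wellbeing - 5.0) / 2.5
    p_pos = 1.0 / (1.0 + math.exp(-2.0 * z))
    if rng.random() < p_pos:
        pool = sorted(_POSITIVE)
    elif rng.random() < 0.85:
        pool = sorted(_NEGATIVE)
    else:
        pool = ["surprise"]
    return pool[int(rng.integers(len(pool)))]


def generate_study(
    config: GeneratorConfig,
) -> tuple[list[DailyReport], list[IHSRecord], SyntheticGroundTruth]:
    """Draw one full study: daily reports, nine-item scale responses, latents."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_days = (cfg.end_date - cfg.anchor_date).days + 1
    if n_days < 1 or cfg.n_teams < 1:
        raise ValueError("empty study window or zero teams")
    n_weeks = math.ceil(n_days / 7)
    teams = _team_ids(cfg.n_teams)

    lo, hi = cfg.members_per_team
    team_members: dict[str, list[str]] = {}
    pid = 0
    for t in teams:
        size = int(rng.integers(lo, hi + 1))
        team_members[t] = [f"P{pid + k:03d}" for k in range(size)]
        pid += size

    # every team keeps at least one reporter, as in small-team field studies
    active_members = {}
    for t, ms in team_members.items():
        act = [m for m in ms if rng.random() < cfg.member_active_prob]
        if not act:
            act = [ms[int(rng.integers(len(ms)))]]
        active_members[t] = act

    all_members = [m for ms in team_members.values() for m in ms]
    if cfg.participation_concentration is None:
        part_rate = {m: cfg.participation_prob for m in all_members}
    else:
        kappa = cfg.participation_concentration
        a = cfg.participation_prob * kappa
        b = (1 - cfg.participation_prob) * kappa
        part_rate = {m: float(rng.beta(a, b)) for m in all_members}

    # latent team-week atmosphere level and spread
    mu: dict[tuple[str, int], float] = {}
    spread: dict[tuple[str, int], float] = {}
    for t in teams:
        mus = rng.normal(cfg.atmosphere_mean, cfg.atmosphere_between_sd, size=n_weeks)
        ss = cfg.agreement_spread.draw(rng, n_weeks)
        for w in range(1, n_weeks + 1):
            mu[(t, w)] = float(mus[w - 1])
            spread[(t, w)] = float(max(ss[w - 1], 0.0))

    # text machinery
    truth = SyntheticGroundTruth(
        config=cfg,
        mu=mu,
        spread=spread,
        team_harmony={},
        team_members=team_members,
        active_members=active_members,
    )
    topic_tokens: list[list[str]] = []
    if cfg.with_text:
        n_topics = cfg.n_topics or (cfg.n_teams + len(all_members))
        vocab_size = cfg.vocab_size or 5 * n_topics
        emb, token_topics = generate_embeddings(
            vocab_size, n_topics, cfg.embedding_dim, seed=int(rng.integers(2**31)),
            topic_jitter=cfg.topic_jitter,
        )
        topic_tokens = [[] for _ in range(n_topics)]
        for tok, topic in token_topics.items():
            topic_tokens[topic].append(tok)
        # disjoint topic assignment: teams first, then members, wrapping if scarce
        for i, t in enumerate(teams):
            truth.team_topic[t] = i % n_topics
        for j, m in enumerate(all_members):
            truth.member_topic[m] = (cfg.n_teams + j) % n_topics
        truth.embeddings = emb
        truth.token_topics = token_topics

    def grid(x: float) -> float:
        x = min(max(x, 0.0), 10.0)
        return float(round(x)) if cfg.round_scores else x

    reports: list[DailyReport] = []
    for t in teams:
        t_topic = truth.team_topic.get(t, 0)
        n_before = len(reports)
        for m in active_members[t]:
            rate = part_rate[m]
            forced_day = -1
            if m is active_members[t][-1] and len(reports) == n_before:
                # every team contributed at least one report in the field study
                forced_day = int(rng.integers(n_days))
            for d in range(n_days):
                date = cfg.anchor_date + dt.timedelta(days=d)
                p = rate * (cfg.weekend_factor if date.weekday() >= 5 else 1.0)
                if rng.random() >= p and d != forced_day:
                    continue
                w = d // 7 + 1
                s = spread[(t, w)]
                n_sub = 2 if rng.random() < cfg.resubmit_prob else 1
                planted: str | None = None
                if cfg.with_text and cfg.plant_emotions:
                    planted = None  # set after the first submission's well-being draw
                for sub in range(n_sub):
                    m_atm = rng.normal(mu[(t, w)], s) if s > 0 else mu[(t, w)]
                    wb = (
                        cfg.base_wellbeing
                        + cfg.coupling_beta * (-s)
                        + cfg.wellbeing_atmosphere_gamma * mu[(t, w)]
                        + rng.normal(0.0, cfg.noise_sd)
                    )
                    wb = grid(wb)
                    diary = ""
                    if cfg.with_text:
                        toks = _draw_diary(
                            rng, cfg, topic_tokens, t_topic, truth.member_topic[m], cfg.lam(s)
                        )
                        if cfg.plant_emotions:
                            if planted is None:
                                planted = _emotion_for(rng, wb)
                                truth.report_emotions[(m, date.isoformat())] = planted
                            pool = EMOTION_LEXICON[planted]
                            toks += [
                                pool[int(rng.integers(len(pool)))]
                                for _ in range(cfg.n_emotion_tokens)
                            ]
                        diary = " ".join(toks)
                    reports.append(
                        DailyReport(
                            participant_id=m,
                            team_id=t,
                            date=date,
                            wellbeing=wb,
                            atmosphere=grid(m_atm),
                            diary=diary,
                        )
                    )

    # team harmony trait: correlated with mean weekly agreement via ihs_coupling
    agree = np.array([-np.mean([spread[(t, w)] for w in range(1, n_weeks + 1)]) for t in teams])
    z = (agree - agree.mean()) / agree.std() if agree.std() > 0 else np.zeros_like(agree)
    c = cfg.ihs_coupling
    h = c * z + math.sqrt(max(1 - c * c, 0.0)) * rng.normal(size=len(teams))
    truth.team_harmony = {t: float(h[i]) for i, t in enumerate(teams)}

    lo_s, hi_s = cfg.ihs_scale
    mid = (lo_s + hi_s) / 2.0
    span = (hi_s - lo_s) / 4.0
    ihs: list[IHSRecord] = []
    for i, t in enumerate(teams):
        for m in active_members[t]:
            indiv = h[i] + rng.normal(0.0, 0.3)
            items = np.clip(
                np.round(mid + span * indiv + rng.normal(0.0, cfg.ihs_item_noise, size=9)),
                lo_s,
                hi_s,
            )
            ihs.append(IHSRecord(participant_id=m, team_id=t, items=[float(x) for x in items]))

    return reports, ihs, truth
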