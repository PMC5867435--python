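"""Synthetic organisations, inspections, feedback streams and labelled corpora.

The generator emulates the statistical structure of multi-source patient
feedback for English acute hospitals and their trusts:

* a latent care-quality ``q`` per organisation (standard-normal scale), with
  hospitals sharing a trust-level component plus an independent deviation;
* three feedback sources with per-source volumes and mean star ratings
  (calibrated to observed per-source means of 3.85 / 4.13 / 4.28), where
  higher-quality organisations attract better stars through ``quality_effect``;
* microblog posts that are mostly *not* care-quality feedback (~9% relevance),
  include reposts and organisation-authored posts, and carry free text rather
  than stars;
* one inspection per organisation whose ordinal rating is drawn from a
  cumulative-logit model on ``q``, with marginal class frequencies matching a
  heavily imbalanced base distribution (default 10% Inadequate, 61% Requires
  improvement, 26% Good, 3% Outstanding).

Star ratings are drawn from a discretised latent-logistic distribution — the
same family the downstream cumulative-logit model assumes — so parameter
recovery is a well-posed exercise.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .types import (
    RATING_LEVELS,
    FeedbackItem,
    Inspection,
    Organisation,
    OrgKind,
    Registry,
    Source,
    ValidationError,
)

# Cutpoints between adjacent star categories on the latent scale.
_STAR_CUTS = np.array([1.5, 2.5, 3.5, 4.5])

#: The five-class microblog taxonomy: four care-quality feedback classes plus
#: the (dominant) not-care-quality class.
TAXONOMY = (
    "patient_experience_effectiveness",
    "environment_facilities",
    "timeliness_access",
    "safety",
    "not_care_quality",
)

#: Class proportions observed in a double-coded microblog sample
#: (348, 67, 90, 13, 5351 of 5869).
DEFAULT_CLASS_PROBS = (348 / 5869, 67 / 5869, 90 / 5869, 13 / 5869, 5351 / 5869)

_N_CLASS_TOKENS = 30
_N_SHARED_TOKENS = 60
_N_STAR_TOKENS = 12


# ---------------------------------------------------------------------------
# Discretised latent-logistic star distribution

def star_mean(mu: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Mean of the discretised logistic star distribution at location mu.

    With latent L ~ Logistic(mu, scale) and stars = 1 + #{cutpoints below L},
    E[stars] = 1 + sum_j sigmoid((mu - c_j)/scale), strictly increasing in mu.
    """
    mu = np.asarray(mu, dtype=float)
    return 1.0 + expit((mu[..., None] - _STAR_CUTS) / scale).sum(axis=-1)


_LOCATION_GRID_CACHE: dict = {}


def star_location_for_mean(target: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Invert :func:`star_mean`: latent location giving each target mean in (1,5).

    Monotone-grid inversion followed by a few Newton steps (the derivative is
    a sum of logistic densities, strictly positive, so Newton from a nearby
    start converges fast without overshoot).
    """
    target = np.clip(np.asarray(target, dtype=float), 1.0 + 1e-9, 5.0 - 1e-9)
    key = round(float(scale), 12)
    if key not in _LOCATION_GRID_CACHE:
        mu_grid = np.linspace(-30.0 * scale - 5.0, 35.0 * scale + 10.0, 4001)
        _LOCATION_GRID_CACHE[key] = (star_mean(mu_grid, scale), mu_grid)
    mean_grid, mu_grid = _LOCATION_GRID_CACHE[key]
    mu = np.interp(target, mean_grid, mu_grid)
    for _ in range(4):
        p = expit((mu[..., None] - _STAR_CUTS) / scale)
        f = 1.0 + p.sum(axis=-1) - target
        fprime = (p * (1.0 - p)).sum(axis=-1) / scale
        mu = np.clip(mu - f / np.maximum(fprime, 1e-300), mu_grid[0], mu_grid[-1])
    return mu


def draw_stars(target_mean: np.ndarray, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """Draw integer stars 1-5 with the given per-item expected values."""
    mu = star_location_for_mean(target_mean, scale)
    latent = mu + scale * _logit(rng.uniform(size=np.shape(mu)))
    return 1 + (latent[..., None] > _STAR_CUTS).sum(axis=-1)


def _logit(u):
    return np.log(u) - np.log1p(-u)


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class SourceProfile:
    """Per-source generation parameters.

    daily_rate is expected eligible-item volume per organisation per day;
    mean_stars the marginal mean star rating for an average (q=0) organisation;
    relevance_fraction (microblog only) the probability that a post is
    care-quality feedback rather than noise.
    """

    daily_rate: float
    mean_stars: float
    relevance_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.daily_rate < 0:
            raise ValidationError("daily_rate must be nonnegative")
        if not 1.0 <= self.mean_stars <= 5.0:
            raise ValidationError("mean_stars must lie in [1, 5]")
        if self.relevance_fraction is not None and not 0.0 <= self.relevance_fraction <= 1.0:
            raise ValidationError("relevance_fraction must lie in [0, 1]")


@dataclass
class Changepoint:
    """Optional step drop in mean stars for selected organisations (emulates a
    sudden deterioration visible in smoothed score trajectories)."""

    org_ids: tuple[str, ...]
    date: _dt.date
    star_drop: float


def _default_profiles() -> dict:
    return {
        Source.rating_site: SourceProfile(daily_rate=0.22, mean_stars=3.85),
        Source.social_review: SourceProfile(daily_rate=0.21, mean_stars=4.13),
        Source.microblog: SourceProfile(daily_rate=0.50, mean_stars=4.28, relevance_fraction=518 / 5869),
    }


@dataclass
class GeneratorConfig:
    n_trusts: int = 140
    hospitals_per_trust: int | tuple[int, int] = (1, 3)
    period: tuple[_dt.date, _dt.date] = (_dt.date(2016, 3, 1), _dt.date(2017, 2, 28))
    source_profiles: dict = field(default_factory=_default_profiles)
    quality_effect: float = 0.3
    rating_base_probs: tuple[float, float, float, float] = (0.10, 0.61, 0.26, 0.03)
    rating_quality_slope: float = 2.0
    trust_quality_share: float = 0.5
    star_scale: float = 1.0
    microblog_repost_fraction: float = 0.30
    microblog_org_author_fraction: float = 0.05
    unrated_fraction: float = 0.05
    changepoint: Optional[Changepoint] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trusts <= 0:
            raise ValidationError("n_trusts must be positive")
        probs = np.asarray(self.rating_base_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("rating_base_probs must be a 4-vector summing to 1")
        start, end = self.period
        if isinstance(start, str):
            self.period = (_dt.date.fromisoformat(start), _dt.date.fromisoformat(str(end)))
        if not 0.0 <= self.trust_quality_share <= 1.0:
            raise ValidationError("trust_quality_share must lie in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        profiles = data.pop("source_profiles", None)
        cfg = cls(**data)
        if profiles is not None:
            cfg.source_profiles = {
                Source(name): SourceProfile(**prof) for name, prof in profiles.items()
            }
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class LatentQuality:
    org_id: str
    q: float


# ---------------------------------------------------------------------------
# Organisations and latent quality

def generate_organisations(config: GeneratorConfig) -> tuple[Registry, dict[str, float]]:
    """Generate trusts with their hospitals and latent qualities.

    Each trust draws a quality component; each hospital's quality is the
    trust component plus an independent deviation, with the variance split
    set by ``trust_quality_share`` so that hospital q is standard normal.
    """
    rng = np.random.default_rng(config.seed)
    share = config.trust_quality_share
    orgs: list[Organisation] = []
    quality: dict[str, float] = {}
    hpt = config.hospitals_per_trust
    for t in range(config.n_trusts):
        trust_id = f"T{t + 1:04d}"
        q_trust = float(rng.normal(0.0, np.sqrt(share))) if share > 0 else 0.0
        orgs.append(Organisation(trust_id, OrgKind.trust, name=f"Trust {t + 1}"))
        quality[trust_id] = q_trust
        n_h = hpt if isinstance(hpt, int) else int(rng.integers(hpt[0], hpt[1] + 1))
        for h in range(n_h):
            hosp_id = f"{trust_id}H{h + 1:02d}"
            q_h = q_trust + float(rng.normal(0.0, np.sqrt(1.0 - share)))
            orgs.append(
                Organisation(hosp_id, OrgKind.hospital, name=f"Hospital {t + 1}.{h + 1}", parent_trust_id=trust_id)
            )
            quality[hosp_id] = q_h
    return Registry(orgs), quality


# ---------------------------------------------------------------------------
# Vocabulary for synthetic microblog text

def _class_tokens(label: str) -> list[str]:
    return [f"{label}_w{i}" for i in range(_N_CLASS_TOKENS)]


def _shared_tokens() -> list[str]:
    return [f"common_w{i}" for i in range(_N_SHARED_TOKENS)]


def _star_tokens(star: int) -> list[str]:
    return [f"tone{star}_w{i}" for i in range(_N_STAR_TOKENS)]


def _shared_tone_tokens() -> list[str]:
    return [f"tone_any_w{i}" for i in range(_N_STAR_TOKENS)]


def _make_text(label: str, star: Optional[int], separation: float, rng: np.random.Generator) -> str:
    """Compose a synthetic post: topic tokens for the class, tone tokens for
    the star level.  ``separation`` interpolates between disjoint per-class
    vocabularies (1: perfectly learnable) and a single shared vocabulary (0).

    The leading tokens of each group are the pool's anchor (index 0), so at
    full separation every post carries a dominant class/tone marker and even
    very rare classes stay learnable from a handful of examples.
    """
    shared = _shared_tokens()
    own = _class_tokens(label)
    n_topic = int(rng.integers(4, 9))
    tokens = []
    for j in range(n_topic):
        pool = own if rng.uniform() < separation else shared
        tokens.append(pool[0] if j <= 1 else pool[int(rng.integers(len(pool)))])
    # every post carries a tone block (star-specific for starred posts,
    # generic otherwise), so at separation 0 the class-conditional token
    # distributions really are identical
    tone_shared = _shared_tone_tokens()
    tone_own = _star_tokens(star) if star is not None else tone_shared
    for j in range(int(rng.integers(3, 6))):
        pool = tone_own if rng.uniform() < separation else tone_shared
        tokens.append(pool[0] if j == 0 else pool[int(rng.integers(len(pool)))])
    return " ".join(tokens)


# ---------------------------------------------------------------------------
# Feedback streams

def generate_feedback(
    registry: Registry,
    qualities: dict[str, float],
    config: GeneratorConfig,
    text_separation: float = 0.9,
) -> list[FeedbackItem]:
    """Generate the full multi-source feedback stream for every organisation.

    Item counts per organisation, source and day follow a Poisson process at
    the source's daily rate.  Stars follow the discretised-logistic ordinal
    distribution with mean ``mean_stars + quality_effect * q`` (clamped to
    [1, 5]).  Microblog items carry text instead of stars: care-quality posts
    (probability ``relevance_fraction``) encode a latent star level in their
    tone tokens; the rest are noise.  Repost and organisation-authored flags
    are set on microblog items only.
    """
    start, end = config.period
    n_days = (end - start).days + 1
    if n_days <= 0:
        raise ValidationError("period is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    items: list[FeedbackItem] = []
    counter = 0
    cq_classes = TAXONOMY[:4]
    cq_probs = np.asarray(DEFAULT_CLASS_PROBS[:4])
    cq_probs = cq_probs / cq_probs.sum()

    for org in registry:
        q = qualities[org.org_id]
        for source, profile in config.source_profiles.items():
            n = int(rng.poisson(profile.daily_rate * n_days))
            if n == 0:
                continue
            day_offsets = rng.integers(0, n_days, size=n)
            dates = [start + _dt.timedelta(days=int(d)) for d in day_offsets]
            base_mean = np.full(n, profile.mean_stars + config.quality_effect * q)
            if config.changepoint is not None and org.org_id in config.changepoint.org_ids:
                after = np.array([d >= config.changepoint.date for d in dates])
                base_mean = base_mean - config.changepoint.star_drop * after
            target = np.clip(base_mean, 1.0, 5.0)
            stars = draw_stars(target, rng, config.star_scale)
            if source is Source.microblog:
                relevant = rng.uniform(size=n) < (profile.relevance_fraction or 0.0)
                reposts = rng.uniform(size=n) < config.microblog_repost_fraction
                org_auth = rng.uniform(size=n) < config.microblog_org_author_fraction
                labels = rng.choice(len(cq_classes), size=n, p=cq_probs)
                for i in range(n):
                    counter += 1
                    if relevant[i]:
                        label = cq_classes[int(labels[i])]
                        text = _make_text(label, int(stars[i]), text_separation, rng)
                    else:
                        text = _make_text("not_care_quality", None, text_separation, rng)
                    items.append(
                        FeedbackItem(
                            item_id=f"fb{counter:07d}",
                            org_id=org.org_id,
                            source=source,
                            date=dates[i],
                            stars=None,
                            text=text,
                            is_repost=bool(reposts[i]),
                            author_is_org=bool(org_auth[i]),
                        )
                    )
            else:
                # star reviews carry brief free text in the star's tone
                for i in range(n):
                    counter += 1
                    items.append(
                        FeedbackItem(
                            item_id=f"fb{counter:07d}",
                            org_id=org.org_id,
                            source=source,
                            date=dates[i],
                            stars=int(stars[i]),
                            text=_make_text("review", int(stars[i]), text_separation, rng),
                        )
                    )
    return items


# ---------------------------------------------------------------------------
# Inspections

def rating_thresholds(base_probs: Sequence[float], quality_slope: float) -> np.ndarray:
    """Cumulative-logit thresholds on latent quality reproducing the marginals.

    Solves E_q[sigmoid(theta_k - slope * q)] = cumulative base prob for
    q ~ N(0, 1), by Gauss-Hermite quadrature and root finding.
    """
    cum = np.cumsum(np.asarray(base_probs, dtype=float))[:3]
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def marginal(theta):
        return float(np.sum(weights * expit(theta - quality_slope * nodes)))

    lim = 60.0 + 10.0 * abs(quality_slope)
    return np.array([brentq(lambda t, c=c: marginal(t) - c, -lim, lim, xtol=1e-10) for c in cum])


def generate_inspections(
    registry: Registry, qualities: dict[str, float], config: GeneratorConfig
) -> list[Inspection]:
    """One inspection per organisation at a uniform date in the period.

    Ratings follow P(rating <= k | q) = sigmoid(theta_k - slope*q): better
    latent quality shifts mass toward better categories, while the marginal
    class frequencies match ``rating_base_probs``.  A small fraction of
    inspections is left unrated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    start, end = config.period
    n_days = (end - start).days + 1
    thetas = rating_thresholds(config.rating_base_probs, config.rating_quality_slope)
    inspections = []
    for org in registry:
        q = qualities[org.org_id]
        day = int(rng.integers(0, n_days))
        cum = expit(thetas - config.rating_quality_slope * q)
        u = rng.uniform()
        k = int(np.sum(u > cum))  # 0..3
        rating = None if rng.uniform() < config.unrated_fraction else RATING_LEVELS[k]
        inspections.append(Inspection(org.org_id, start + _dt.timedelta(days=day), rating))
    return inspections


# ---------------------------------------------------------------------------
# Labelled corpora

@dataclass
class CorpusItem:
    text: str
    label: str
    stars: Optional[int] = None


def generate_labelled_corpus(
    n: int,
    class_probs: Sequence[float] = DEFAULT_CLASS_PROBS,
    separation: float = 0.9,
    seed: int = 0,
    mean_stars: float = 4.0,
    star_scale: float = 1.0,
) -> list[CorpusItem]:
    """Generate a labelled text corpus mirroring the microblog coding exercise.

    Texts come from class-conditional token distributions; care-quality items
    additionally carry a 1-5 star label encoded in tone tokens, so sentiment
    is learnable from text.  ``separation=1`` gives disjoint vocabularies
    (zero Bayes error); ``separation=0`` gives identical ones (no signal).
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (len(TAXONOMY),) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"class_probs must be a {len(TAXONOMY)}-vector summing to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(TAXONOMY), size=n, p=probs)
    out: list[CorpusItem] = []
    for idx in labels:
        label = TAXONOMY[int(idx)]
        if label == "not_care_quality":
            star = None
        else:
            star = int(draw_stars(np.array(mean_stars), rng, star_scale))
        out.append(CorpusItem(text=_make_text(label, star, separation, rng), label=label, stars=star))
    return out
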