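"""Welfare indicator schemes, scored records, and prevalence estimation.

Three scoring schemes are supported:

* ``aviary_transect`` — 12 binary whole-flock indicators counted while walking
  each transect (feather loss on head/back/breast/tail, wounds on
  head/back/tail/feet, dirty plumage, enlarged crop, sick, dead).  A hen may be
  counted under several indicators at once, so counts are not disjoint.
* ``assurewel`` — graded 0/1/2 scores for feather loss on head and back and
  for dirtiness on a fixed sample of birds (default 50), plus whole-flock
  descriptive items (beak trimming, antagonistic incidents, flightiness,
  birds needing further care, producer-reported mortality).
* ``norwel`` — graded 0/1/2 scores for feather loss on head/back/breast/tail
  and dirtiness, and binary 0/1 wound scores for head/back/tail, on a fixed
  sample of birds with the in-house location (transect and vertical level)
  recorded per bird.

Prevalence is always expressed in percent.  For the transect scheme the
denominator is the estimated number of birds apportioned to the transect; for
the graded schemes it is the number of birds sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geometry import TransectLayout

__all__ = [
    "Indicator",
    "IndicatorScheme",
    "SchemeError",
    "AVIARY_TRANSECT",
    "ASSUREWEL",
    "NORWEL",
    "SCHEMES",
    "FLIGHTINESS_LEVELS",
    "TransectCountRecord",
    "BirdScoreRecord",
    "PrevalenceEstimate",
    "transect_prevalence",
    "sample_prevalence",
    "aggregate_by",
    "descriptive_flock_summary",
]


class SchemeError(ValueError):
    """Raised when a record is inconsistent with its scoring scheme."""


@dataclass(frozen=True)
class Indicator:
    """One scoreable welfare indicator.

    ``levels`` lists the legal scores: ``(0, 1)`` for binary indicators
    (1 = affected) and ``(0, 1, 2)`` for graded ones (severity ordered).
    """

    code: str
    body_site: str
    levels: tuple[int, ...]
    definition: str


@dataclass(frozen=True)
class IndicatorScheme:
    """A named scoring scheme: ordered indicators plus whole-flock items."""

    name: str
    indicators: tuple[Indicator, ...]
    whole_flock_items: tuple[str, ...] = ()

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(i.code for i in self.indicators)

    def __getitem__(self, code: str) -> Indicator:
        for i in self.indicators:
            if i.code == code:
                return i
        raise KeyError(f"scheme {self.name!r} has no indicator {code!r}")

    def __contains__(self, code: str) -> bool:
        return any(i.code == code for i in self.indicators)

    def validate_scores(self, scores: Mapping[str, int]) -> None:
        """Raise :class:`SchemeError` on any unknown code or illegal level."""
        for code, level in scores.items():
            if code not in self:
                raise SchemeError(f"indicator {code!r} not in scheme {self.name!r}")
            if level not in self[code].levels:
                raise SchemeError(
                    f"score {level!r} not a legal level for {code!r} in scheme "
                    f"{self.name!r} (levels {self[code].levels})"
                )


def _binary(code: str, site: str, definition: str) -> Indicator:
    return Indicator(code, site, (0, 1), definition)


def _graded(code: str, site: str, definition: str) -> Indicator:
    return Indicator(code, site, (0, 1, 2), definition)


#: Whole-flock transect scheme: 12 binary indicators, severe cases only.
AVIARY_TRANSECT = IndicatorScheme(
    "aviary_transect",
    (
        _binary("fl_head", "head/neck", "bare patch on head or neck at least 5 cm across"),
        _binary("fl_back", "back/wings", "at least half the back or wings bare"),
        _binary("fl_breast", "breast", "bare patch on breast at least 5 cm across"),
        _binary("fl_tail", "tail", "tail feathers missing or reduced to shafts"),
        _binary("wounds_head", "head/neck", "visible fresh or healed wound on head or neck"),
        _binary("wounds_back", "back/wings", "visible fresh or healed wound on back or wings"),
        _binary("wounds_tail", "tail", "visible fresh or healed wound on tail"),
        _binary("wounds_feet", "feet", "foot-pad lesion (incl. bumblefoot) or foot wound"),
        _binary("dirty", "plumage", "dark soiling over a quarter or more of the body"),
        _binary("enlarged_crop", "crop", "pendulous crop hanging in front of the breast"),
        _binary("sick", "whole bird", "clear signs of impaired health, typically resting"),
        _binary("dead", "whole bird", "dead bird found on the transect"),
    ),
)

#: Graded fixed-sample scheme with whole-flock descriptive items.
ASSUREWEL = IndicatorScheme(
    "assurewel",
    (
        _graded("fl_head", "head/neck", "feather loss: 0 none, 1 under 5 cm, 2 over 5 cm"),
        _graded("fl_back", "back/vent", "feather loss: 0 none, 1 under 5 cm, 2 over 5 cm"),
        _graded("dirty", "plumage", "soiling: 0 clean, 1 small areas, 2 area over 5 cm"),
    ),
    whole_flock_items=(
        "beak_trimmed",
        "antagonistic_incidents",
        "flightiness",
        "birds_needing_care",
        "mortality_previous_flock_pct",
        "mortality_to_date_pct",
    ),
)

#: Graded fixed-sample scheme with per-bird location and binary wound scores.
NORWEL = IndicatorScheme(
    "norwel",
    (
        _graded("fl_head", "head", "feather loss: 0 none, 1 under 5 cm, 2 over 5 cm"),
        _graded("fl_back", "back/wings", "feather loss: 0 none, 1 under 5 cm, 2 over 5 cm"),
        _graded("fl_breast", "breast", "feather loss: 0 none, 1 under 5 cm, 2 over 5 cm"),
        _graded("fl_tail", "tail", "wear: 0 none, 1 some, 2 substantial (shafts only)"),
        _graded("dirty", "plumage", "dirt: 0 clean, 1 some, 2 over half of plumage"),
        _binary("wounds_head", "head", "clearly visible fresh or older wound"),
        _binary("wounds_back", "back/wings", "clearly visible fresh or older wound"),
        _binary("wounds_tail", "tail", "clearly visible fresh or older wound"),
    ),
)

SCHEMES: dict[str, IndicatorScheme] = {
    s.name: s for s in (AVIARY_TRANSECT, ASSUREWEL, NORWEL)
}

FLIGHTINESS_LEVELS = ("calm", "cautious", "flighty")


@dataclass(frozen=True)
class TransectCountRecord:
    """One observer's binary-indicator counts for one transect walk."""

    house_id: str
    observer_id: str
    transect_index: int
    transect_kind: str
    counts: Mapping[str, int]

    def validate(self, scheme: IndicatorScheme = AVIARY_TRANSECT) -> None:
        for code, count in self.counts.items():
            if code not in scheme:
                raise SchemeError(f"indicator {code!r} not in scheme {scheme.name!r}")
            if not isinstance(count, (int,)) or count < 0:
                raise SchemeError(
                    f"count for {code!r} must be a non-negative integer, got {count!r}"
                )


@dataclass(frozen=True)
class BirdScoreRecord:
    """Graded scores for one sampled bird, with optional in-house location.

    Location (transect and vertical level) is required for the ``norwel``
    scheme, which records where each scored bird was found; it is optional
    for ``assurewel``.
    """

    house_id: str
    scheme_name: str
    bird_ordinal: int
    scores: Mapping[str, int]
    transect_index: int | None = None
    transect_kind: str | None = None
    vertical_level: int | None = None

    def validate(self) -> None:
        scheme = SCHEMES[self.scheme_name]
        scheme.validate_scores(self.scores)
        if self.scheme_name == "norwel":
            if self.transect_index is None or self.vertical_level is None:
                raise SchemeError(
                    "norwel records require transect_index and vertical_level "
                    f"(bird {self.bird_ordinal} of house {self.house_id!r})"
                )
        if self.vertical_level is not None and not 1 <= self.vertical_level <= 4:
            raise SchemeError(
                f"vertical_level must be 1..4 (litter, tiers 1-3), got {self.vertical_level}"
            )


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Prevalence of one indicator (at one score level) with its basis.

    ``p`` and ``se`` are percentages; ``n_basis`` is the denominator
    (estimated birds in a transect, or birds sampled).
    """

    indicator: str
    score_level: int
    p: float
    se: float
    n_basis: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 100.0:
            raise ValueError(f"prevalence must be in [0, 100], got {self.p}")
        if self.se < 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")


def _binomial_se_pct(k: int, n: int) -> float:
    """SE of a percentage from k affected of n, with the n-1 denominator.

    ``100 * sqrt(phat * (1 - phat) / (n - 1))`` — the sample-standard-
    deviation form, which matches the reporting convention of the graded
    fixed-sample schemes.  Zero when the prevalence is 0 or 100 %.
    """
    phat = k / n
    return 100.0 * math.sqrt(phat * (1.0 - phat) / (n - 1))


def transect_prevalence(
    counts: TransectCountRecord, layout: TransectLayout
) -> list[PrevalenceEstimate]:
    """Whole-flock prevalences from one transect walk.

    For each indicator, ``p = 100 * count / estimated_birds`` where
    ``estimated_birds`` is the width-proportional apportionment of the flock
    to this transect.  Counts exceeding the apportionment are rejected.
    """
    counts.validate()
    transect = layout.by_index(counts.transect_index)
    n = transect.estimated_birds
    if n is None:
        raise ValueError(
            f"layout for house {layout.house_id!r} carries no bird apportionment; "
            "use estimate_birds_per_transect"
        )
    out = []
    for code, k in counts.counts.items():
        if k > n:
            raise SchemeError(
                f"count {k} for {code!r} exceeds the {n} birds apportioned to "
                f"transect {counts.transect_index} of house {counts.house_id!r}"
            )
        out.append(
            PrevalenceEstimate(
                indicator=code,
                score_level=1,
                p=100.0 * k / n,
                se=_binomial_se_pct(k, n),
                n_basis=n,
            )
        )
    return out


def sample_prevalence(
    records: Sequence[BirdScoreRecord], indicator: str, score_level: int
) -> PrevalenceEstimate:
    """Prevalence of one score level of one indicator in a fixed bird sample.

    ``p = 100 * k / n`` for the ``k`` of ``n`` sampled birds scored exactly
    ``score_level``; ``se = 100 * sqrt(phat * (1 - phat) / (n - 1))``.
    All records must come from the same house and scheme; n >= 2 (the SE is
    undefined for a single bird).
    """
    if not records:
        raise ValueError("no records given")
    houses = {r.house_id for r in records}
    schemes = {r.scheme_name for r in records}
    if len(houses) > 1 or len(schemes) > 1:
        raise ValueError(
            f"records span houses {sorted(houses)} / schemes {sorted(schemes)}; "
            "sample_prevalence expects one house and one scheme"
        )
    scheme = SCHEMES[next(iter(schemes))]
    if indicator not in scheme:
        raise SchemeError(f"indicator {indicator!r} not in scheme {scheme.name!r}")
    if score_level not in scheme[indicator].levels:
        raise SchemeError(
            f"score level {score_level} not legal for {indicator!r} in {scheme.name!r}"
        )
    n = len(records)
    if n < 2:
        raise ValueError(f"need at least 2 scored birds for a standard error, got {n}")
    k = sum(1 for r in records if r.scores.get(indicator) == score_level)
    return PrevalenceEstimate(
        indicator=indicator,
        score_level=score_level,
        p=100.0 * k / n,
        se=_binomial_se_pct(k, n),
        n_basis=n,
    )


def aggregate_by(
    subunits: pd.DataFrame, grouping: str | Sequence[str]
) -> pd.DataFrame:
    """Mean and SE-of-mean of subunit prevalences per group.

    ``subunits`` holds one row per subunit prevalence with at least the
    columns named by ``grouping``, plus ``indicator``, ``score_level`` and
    ``p``.  Returns one row per (group, indicator, score_level) with columns
    ``mean_p``, ``se_p`` (standard error of the mean across subunits, ddof=1),
    ``n_subunits`` and ``se_defined`` (False when a group has a single
    subunit, in which case ``se_p`` is reported as 0).

    Empty groups cannot occur by construction (groupby over observed rows);
    groups present in the index but with no rows are simply absent.
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    required = list(grouping) + ["indicator", "score_level", "p"]
    missing = [c for c in required if c not in subunits.columns]
    if missing:
        raise KeyError(f"subunit table lacks columns {missing}")

    keys = list(grouping) + ["indicator", "score_level"]
    rows = []
    for key, grp in subunits.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        mean_p = float(grp["p"].mean())
        if n >= 2:
            se_p = float(grp["p"].std(ddof=1) / math.sqrt(n))
            se_defined = True
        else:
            se_p, se_defined = 0.0, False
        rows.append(dict(zip(keys, key)) | {
            "mean_p": mean_p,
            "se_p": se_p,
            "n_subunits": n,
            "se_defined": se_defined,
        })
    return pd.DataFrame(rows, columns=keys + ["mean_p", "se_p", "n_subunits", "se_defined"])


def descriptive_flock_summary(fields: Mapping[str, object]) -> dict[str, object]:
    """Validate and echo the whole-flock descriptive items of the graded scheme.

    No statistics are computed: beak trimming, antagonistic incidents,
    flightiness, birds needing further care and producer-reported mortality
    are type-checked and returned verbatim.  ``"unknown"`` is a legal value
    for mortality (producers do not always have the figure) and is preserved
    as a string, never coerced to a number.  Unset items are omitted.
    """
    out: dict[str, object] = {}
    for key in ASSUREWEL.whole_flock_items:
        if key not in fields or fields[key] is None:
            continue
        value = fields[key]
        if key == "flightiness":
            if value not in FLIGHTINESS_LEVELS:
                raise SchemeError(
                    f"flightiness must be one of {FLIGHTINESS_LEVELS}, got {value!r}"
                )
        elif key == "beak_trimmed":
            if value not in ("yes", "no"):
                raise SchemeError(f"beak_trimmed must be 'yes' or 'no', got {value!r}")
        elif key in ("antagonistic_incidents", "birds_needing_care"):
            if not isinstance(value, int) or value < 0:
                raise SchemeError(f"{key} must be a non-negative integer, got {value!r}")
        else:  # mortality fields: number or the literal "unknown"
            if isinstance(value, str):
                if value.lower() != "unknown":
                    raise SchemeError(
                        f"{key} must be a percentage or 'unknown', got {value!r}"
                    )
                value = "unknown"
            elif not isinstance(value, (int, float)) or not 0 <= float(value) <= 100:
                raise SchemeError(f"{key} must be a percentage in [0, 100], got {value!r}")
        out[key] = value
    unknown = set(fields) - set(ASSUREWEL.whole_flock_items)
    if unknown:
        raise SchemeError(f"unknown whole-flock items: {sorted(unknown)}")
    return out
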