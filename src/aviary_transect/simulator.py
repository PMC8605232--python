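"""Synthetic flocks and observation processes for sampling-design evaluation.

The generator emulates the study conditions the transect scheme was developed
under: flocks of roughly 7,500 white-strain hens in houses with 2-4 transects
and 4 vertical levels (litter + 3 tiers), per-indicator true prevalences in
the 0-1 % range for the whole-flock binary scheme and up to ~40 % for the
graded fixed-sample schemes.

Birds are placed across transects proportionally to transect width (the
homogeneity null); an optional wall-placement bias makes affected birds
relatively more likely to sit in wall transects, mirroring the wall-vs-central
gradient reported for breast feather loss and dirtiness.  Indicator
assignment is independent Bernoulli per bird and indicator (multi-label: a
hen may carry several conditions).  Observers detect each affected bird with
a stated sensitivity and miscount unaffected birds at a stated false-positive
rate.

Randomness: one global seed drives an independent named stream per operation,
so adding operations never perturbs existing draws, and identical
configurations reproduce byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import WALL, HouseGeometry, TransectLayout, estimate_birds_per_transect
from .indicators import (
    AVIARY_TRANSECT,
    SCHEMES,
    BirdScoreRecord,
    IndicatorScheme,
    TransectCountRecord,
)
from .stats import ModelSpec, factor_test, fit_binomial_glm

__all__ = [
    "SimConfig",
    "SimulatedFlock",
    "PowerEstimate",
    "SimulationError",
    "simulate_flock",
    "observe_transects",
    "sample_birds",
    "power_experiment",
]


class SimulationError(ValueError):
    """Raised on inconsistent simulation configurations."""


def _stream(seed: int, op_name: str, *extra: int) -> np.random.Generator:
    """Independent generator for (seed, operation name [, indices])."""
    key = zlib.crc32(op_name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, key, *extra)))


@dataclass(frozen=True)
class SimConfig:
    """Ground truth and observation model for one synthetic flock.

    Parameters
    ----------
    geometry:
        House layout; the flock size and transect widths come from here.
    prevalence:
        True per-indicator prevalence as a fraction in [0, 1], keyed by
        indicator code.
    wall_bias:
        Relative risk that an *affected* bird resides in a wall transect
        (1 = homogeneous placement, > 1 = affected birds drift to the walls).
    vertical_weights:
        Probability that a bird occupies each of the 4 vertical levels
        (litter, tiers 1-3); must sum to 1.
    sensitivity:
        Probability that a transect observer counts an affected bird.
    fp_rate:
        Probability that an unaffected bird is wrongly counted.
    sample_n:
        Birds drawn per graded-scheme sample (default 50).
    severity_pi2:
        For graded-scheme emulation: probability that an affected sampled
        bird is scored 2 rather than 1.  Never touches transect counts.
    seed:
        Global seed for all operation streams.
    """

    geometry: HouseGeometry
    prevalence: Mapping[str, float]
    wall_bias: float = 1.0
    vertical_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sensitivity: float = 1.0
    fp_rate: float = 0.0
    sample_n: int = 50
    severity_pi2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for code, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"prevalence for {code!r} must be in [0, 1], got {p}")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise SimulationError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if not 0.0 <= self.fp_rate <= 1.0:
            raise SimulationError(f"fp_rate must be in [0, 1], got {self.fp_rate}")
        if not 0.0 <= self.severity_pi2 <= 1.0:
            raise SimulationError(f"severity_pi2 must be in [0, 1], got {self.severity_pi2}")
        if self.wall_bias <= 0:
            raise SimulationError(f"wall_bias must be > 0, got {self.wall_bias}")
        if abs(sum(self.vertical_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.vertical_weights
        ):
            raise SimulationError(
                f"vertical_weights must be a probability vector, got {self.vertical_weights}"
            )
        if self.sample_n < 1:
            raise SimulationError(f"sample_n must be >= 1, got {self.sample_n}")


@dataclass(frozen=True)
class SimulatedFlock:
    """Ground truth for one simulated flock.

    ``affected`` is a (flock_size, n_indicators) boolean matrix over
    ``indicator_codes``; ``transect_index`` (1-based) and ``vertical_level``
    (1 = litter .. 4 = top tier) give each bird's location.
    """

    config: SimConfig
    layout: TransectLayout
    indicator_codes: tuple[str, ...]
    transect_index: np.ndarray
    vertical_level: np.ndarray
    affected: np.ndarray

    @property
    def flock_size(self) -> int:
        return len(self.transect_index)

    def true_prevalence(self, indicator: str) -> float:
        """Realized fraction of the flock affected by ``indicator``."""
        j = self.indicator_codes.index(indicator)
        return float(self.affected[:, j].mean())


def simulate_flock(config: SimConfig) -> SimulatedFlock:
    """Draw one flock: indicator ground truth and bird placement.

    Indicators are independent Bernoulli per bird (multi-label).  Placement
    over transects is multinomial on transect widths; birds affected by at
    least one indicator have their wall-transect weights multiplied by
    ``wall_bias`` before normalisation.  Vertical level is independent of
    everything else.  Identical configs (including seed) reproduce exactly.
    """
    layout = estimate_birds_per_transect(config.geometry)
    n = config.geometry.flock_size
    codes = tuple(sorted(config.prevalence))
    rng = _stream(config.seed, "simulate_flock")

    prev = np.array([config.prevalence[c] for c in codes], dtype=float)
    affected = rng.random((n, len(codes))) < prev if codes else np.zeros((n, 0), bool)
    any_affected = affected.any(axis=1)

    widths = np.asarray(layout.widths)
    plain = widths / widths.sum()
    biased = widths * np.where(np.asarray(layout.kinds) == WALL, config.wall_bias, 1.0)
    biased = biased / biased.sum()

    # one uniform per bird through the placement CDF appropriate to its status
    u = rng.random(n)
    cum_plain = np.cumsum(plain)
    cum_biased = np.cumsum(biased)
    t_plain = np.searchsorted(cum_plain, u, side="right")
    t_biased = np.searchsorted(cum_biased, u, side="right")
    transect = np.where(any_affected, t_biased, t_plain).clip(0, len(widths) - 1) + 1

    v = rng.random(n)
    cum_v = np.cumsum(np.asarray(config.vertical_weights))
    level = np.searchsorted(cum_v, v, side="right").clip(0, 3) + 1

    return SimulatedFlock(
        config=config,
        layout=layout,
        indicator_codes=codes,
        transect_index=transect.astype(np.int64),
        vertical_level=level.astype(np.int64),
        affected=affected,
    )


def observe_transects(
    flock: SimulatedFlock,
    config: SimConfig | None = None,
    n_observers: int = 2,
) -> list[TransectCountRecord]:
    """Simulate transect walks: per observer, per transect, per indicator.

    The count is Binomial(affected birds present, sensitivity) plus
    Binomial(unaffected birds present, false-positive rate); observers draw
    independently.
    """
    config = config or flock.config
    rng = _stream(config.seed, "observe_transects")
    records = []
    for obs in range(1, n_observers + 1):
        for t in flock.layout:
            in_t = flock.transect_index == t.index
            n_here = int(in_t.sum())
            counts = {}
            for j, code in enumerate(flock.indicator_codes):
                n_aff = int((in_t & flock.affected[:, j]).sum())
                counted = rng.binomial(n_aff, config.sensitivity)
                counted += rng.binomial(n_here - n_aff, config.fp_rate)
                counts[code] = int(counted)
            records.append(
                TransectCountRecord(
                    house_id=flock.layout.house_id,
                    observer_id=f"obs{obs}",
                    transect_index=t.index,
                    transect_kind=t.kind,
                    counts=counts,
                )
            )
    return records


def sample_birds(
    flock: SimulatedFlock,
    config: SimConfig | None = None,
    scheme: IndicatorScheme | str = "norwel",
) -> list[BirdScoreRecord]:
    """Simple random sample of birds, scored under a graded scheme.

    For scheme indicators that exist in the simulated ground truth, an
    affected bird scores 2 with probability ``severity_pi2`` and 1 otherwise
    (binary indicators score 1); an unaffected bird scores 0.  Indicators the
    simulation does not model score 0.  Sampling the whole flock reproduces
    the population prevalence exactly at score >= 1.
    """
    config = config or flock.config
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    n = flock.flock_size
    if config.sample_n > n:
        raise SimulationError(
            f"sample_n {config.sample_n} exceeds flock size {n}"
        )
    rng = _stream(config.seed, "sample_birds")
    if config.sample_n == n:
        chosen = np.arange(n)
    else:
        chosen = np.sort(rng.choice(n, size=config.sample_n, replace=False))

    records = []
    for ordinal, b in enumerate(chosen, start=1):
        scores = {}
        for ind in scheme.indicators:
            if ind.code in flock.indicator_codes:
                j = flock.indicator_codes.index(ind.code)
                if flock.affected[b, j]:
                    if len(ind.levels) > 2:
                        scores[ind.code] = 2 if rng.random() < config.severity_pi2 else 1
                    else:
                        scores[ind.code] = 1
                else:
                    scores[ind.code] = 0
            else:
                scores[ind.code] = 0
        t = flock.layout.by_index(int(flock.transect_index[b]))
        records.append(
            BirdScoreRecord(
                house_id=flock.layout.house_id,
                scheme_name=scheme.name,
                bird_ordinal=ordinal,
                scores=scores,
                transect_index=t.index,
                transect_kind=t.kind,
                vertical_level=int(flock.vertical_level[b]),
            )
        )
    return records


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo power of a design to detect a between-flock difference."""

    method: str
    indicator: str
    power: float
    mc_se: float
    replicates: int
    alpha: float
    n_rejected: int
    seed: int


def _derived_seed(seed: int, label: str, rep: int, which: int) -> int:
    key = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    state = np.random.SeedSequence((seed & 0x7FFFFFFF, key, rep, which)).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


def power_experiment(
    config_a: SimConfig,
    config_b: SimConfig,
    method: str,
    replicates: int = 400,
    alpha: float = 0.05,
    indicator: str | None = None,
    seed: int | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of a sampling design to separate two flocks.

    Per replicate, one flock is drawn from each config, assessed with the
    chosen design, and the flock factor is tested with the likelihood-ratio
    chi-square of the binomial GLM; power is the rejection fraction at
    ``alpha``.

    ``method="transect"`` uses whole-flock transect counts (one observer,
    one cell per transect, trials = the width-proportional apportionment).
    ``method="sample_n"`` scores ``sample_n`` randomly sampled birds per
    flock (score >= 1 counts as affected).

    The two configs must differ only in their stated prevalences, so the
    comparison isolates the sampling design.  Replicate flocks are drawn
    from streams keyed by (seed, replicate) only — not by method — so calling
    this twice with the two methods and the same seed is a paired experiment
    on identical flocks.
    """
    if method not in ("transect", "sample_n"):
        raise ValueError(f"method must be 'transect' or 'sample_n', got {method!r}")
    if replicates < 100:
        raise ValueError(f"need >= 100 replicates for a stable estimate, got {replicates}")
    if sorted(config_a.prevalence) != sorted(config_b.prevalence):
        raise SimulationError("configs must state prevalences for the same indicators")
    for f in ("geometry", "wall_bias", "vertical_weights", "sensitivity",
              "fp_rate", "sample_n", "severity_pi2"):
        if getattr(config_a, f) != getattr(config_b, f):
            raise SimulationError(f"configs must differ only in prevalence; {f} differs")
    if indicator is None:
        differing = [c for c in config_a.prevalence
                     if config_a.prevalence[c] != config_b.prevalence[c]]
        indicator = differing[0] if differing else sorted(config_a.prevalence)[0]
    if config_a.prevalence[indicator] == 0 and config_b.prevalence[indicator] == 0:
        raise SimulationError(
            f"both configs have zero prevalence for {indicator!r}; power undefined"
        )
    seed = config_a.seed if seed is None else seed

    n_rejected = 0
    for rep in range(replicates):
        rows, successes, trials = [], [], []
        for which, cfg in enumerate((config_a, config_b)):
            rep_cfg = replace(
                cfg,
                geometry=replace(cfg.geometry, house_id=f"sim{'AB'[which]}"),
                seed=_derived_seed(seed, "power.flock", rep, which),
            )
            flock = simulate_flock(rep_cfg)
            if method == "transect":
                for rec in observe_transects(flock, rep_cfg, n_observers=1):
                    t = flock.layout.by_index(rec.transect_index)
                    rows.append({"flock": rep_cfg.geometry.house_id})
                    successes.append(min(rec.counts[indicator], t.estimated_birds))
                    trials.append(t.estimated_birds)
            else:
                birds = sample_birds(flock, rep_cfg, scheme="norwel")
                k = sum(1 for b in birds if b.scores.get(indicator, 0) >= 1)
                rows.append({"flock": rep_cfg.geometry.house_id})
                successes.append(k)
                trials.append(len(birds))
        fit = fit_binomial_glm(
            successes, trials, pd.DataFrame(rows), ModelSpec(indicator, ("flock",))
        )
        if fit.no_variation:
            continue  # nothing observed anywhere: cannot reject
        test = factor_test(fit, "flock")
        if test.pvalue is not None and test.pvalue < alpha:
            n_rejected += 1

    power = n_rejected / replicates
    mc_se = float(np.sqrt(power * (1.0 - power) / replicates))
    return PowerEstimate(
        method=method, indicator=indicator, power=power, mc_se=mc_se,
        replicates=replicates, alpha=alpha, n_rejected=n_rejected, seed=seed,
    )
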