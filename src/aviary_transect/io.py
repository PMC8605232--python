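"""CSV/YAML readers and writers for the assessment pipeline.

All tabular files are UTF-8 comma-separated CSV with a mandatory header row
and "." as decimal mark.  Lines starting with ``#`` are comments (output
files carry a provenance comment with tool version, config hash and seed).
Aisle widths are semicolon-joined inside a single field so a house stays one
row.

Schemas
-------
``houses.csv``
    house_id, house_width_m, n_structures, flock_size, usable_area_m2,
    floor_area_m2, aisle_widths
``transect_counts.csv``
    house_id, observer_id, transect_index, transect_kind, then one column per
    binary transect-scheme indicator.
``bird_scores.csv``
    house_id, scheme, bird_ordinal, transect_index, transect_kind,
    vertical_level, then one column per graded-scheme indicator (location
    fields may be blank for schemes that do not record it).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .geometry import HouseGeometry
from .indicators import (
    AVIARY_TRANSECT,
    SCHEMES,
    BirdScoreRecord,
    TransectCountRecord,
)
from .simulator import SimConfig

__all__ = [
    "RunConfig",
    "read_houses",
    "write_houses",
    "read_transect_counts",
    "write_transect_counts",
    "read_bird_scores",
    "write_bird_scores",
    "read_run_config",
    "parse_sim_config",
    "write_table",
    "config_hash",
]

HOUSE_COLUMNS = [
    "house_id", "house_width_m", "n_structures", "flock_size",
    "usable_area_m2", "floor_area_m2", "aisle_widths",
]
COUNT_META_COLUMNS = ["house_id", "observer_id", "transect_index", "transect_kind"]
SCORE_META_COLUMNS = [
    "house_id", "scheme", "bird_ordinal", "transect_index", "transect_kind",
    "vertical_level",
]


def config_hash(config: Mapping[str, object]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(seed: int | None = None, chash: str | None = None) -> list[str]:
    line = f"# aviary-transect v{__version__}"
    if chash is not None:
        line += f" config={chash}"
    if seed is not None:
        line += f" seed={seed}"
    return [line]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    chash: str | None = None,
) -> None:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for line in _provenance(seed, chash):
        buf.write(line + "\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_houses(houses: Sequence[HouseGeometry], path: str | Path, **kw) -> None:
    rows = [
        {
            "house_id": h.house_id,
            "house_width_m": h.house_width,
            "n_structures": h.n_structures,
            "flock_size": h.flock_size,
            "usable_area_m2": h.usable_area,
            "floor_area_m2": "" if h.floor_area is None else h.floor_area,
            "aisle_widths": ";".join(f"{a:g}" for a in h.aisle_widths),
        }
        for h in houses
    ]
    write_table(pd.DataFrame(rows, columns=HOUSE_COLUMNS), path, **kw)


def read_houses(path: str | Path) -> list[HouseGeometry]:
    df = pd.read_csv(path, comment="#", dtype={"house_id": str, "aisle_widths": str})
    missing = [c for c in HOUSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing house columns {missing}")
    houses = []
    for _, row in df.iterrows():
        floor = row["floor_area_m2"]
        houses.append(
            HouseGeometry(
                house_id=str(row["house_id"]),
                house_width=float(row["house_width_m"]),
                aisle_widths=tuple(
                    float(a) for a in str(row["aisle_widths"]).split(";") if a != ""
                ),
                n_structures=int(row["n_structures"]),
                flock_size=int(row["flock_size"]),
                usable_area=float(row["usable_area_m2"]),
                floor_area=None if pd.isna(floor) or floor == "" else float(floor),
            )
        )
    return houses


def write_transect_counts(
    records: Sequence[TransectCountRecord], path: str | Path, **kw
) -> None:
    codes = list(AVIARY_TRANSECT.codes)
    rows = []
    for r in records:
        row = {
            "house_id": r.house_id,
            "observer_id": r.observer_id,
            "transect_index": r.transect_index,
            "transect_kind": r.transect_kind,
        }
        row.update({c: int(r.counts.get(c, 0)) for c in codes})
        rows.append(row)
    write_table(pd.DataFrame(rows, columns=COUNT_META_COLUMNS + codes), path, **kw)


def read_transect_counts(path: str | Path) -> list[TransectCountRecord]:
    df = pd.read_csv(path, comment="#", dtype={"house_id": str, "observer_id": str})
    missing = [c for c in COUNT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing count columns {missing}")
    codes = [c for c in df.columns if c not in COUNT_META_COLUMNS]
    return [
        TransectCountRecord(
            house_id=str(row["house_id"]),
            observer_id=str(row["observer_id"]),
            transect_index=int(row["transect_index"]),
            transect_kind=str(row["transect_kind"]),
            counts={c: int(row[c]) for c in codes},
        )
        for _, row in df.iterrows()
    ]


def write_bird_scores(
    records: Sequence[BirdScoreRecord], path: str | Path, **kw
) -> None:
    codes: list[str] = []
    for r in records:
        for c in SCHEMES[r.scheme_name].codes:
            if c not in codes:
                codes.append(c)
    rows = []
    for r in records:
        row = {
            "house_id": r.house_id,
            "scheme": r.scheme_name,
            "bird_ordinal": r.bird_ordinal,
            "transect_index": "" if r.transect_index is None else r.transect_index,
            "transect_kind": "" if r.transect_kind is None else r.transect_kind,
            "vertical_level": "" if r.vertical_level is None else r.vertical_level,
        }
        row.update({c: r.scores.get(c, "") for c in codes})
        rows.append(row)
    write_table(pd.DataFrame(rows, columns=SCORE_META_COLUMNS + codes), path, **kw)


def read_bird_scores(path: str | Path) -> list[BirdScoreRecord]:
    df = pd.read_csv(path, comment="#", dtype={"house_id": str, "scheme": str})
    missing = [c for c in SCORE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing score columns {missing}")
    codes = [c for c in df.columns if c not in SCORE_META_COLUMNS]

    def opt_int(v):
        return None if pd.isna(v) or v == "" else int(v)

    def opt_str(v):
        return None if pd.isna(v) or v == "" else str(v)

    records = []
    for _, row in df.iterrows():
        scheme = SCHEMES[str(row["scheme"])]
        scores = {c: int(row[c]) for c in codes if c in scheme and not pd.isna(row[c])}
        records.append(
            BirdScoreRecord(
                house_id=str(row["house_id"]),
                scheme_name=scheme.name,
                bird_ordinal=int(row["bird_ordinal"]),
                scores=scores,
                transect_index=opt_int(row["transect_index"]),
                transect_kind=opt_str(row["transect_kind"]),
                vertical_level=opt_int(row["vertical_level"]),
            )
        )
    return records


@dataclass
class RunConfig:
    """One assessment run: input paths, scheme selection, and run options."""

    houses: Path | None = None
    transect_counts: Path | None = None
    bird_scores: Path | None = None
    scheme: str = "aviary_transect"
    alpha: float = 0.05
    out_dir: Path = Path("out")
    seed: int = 0
    verbosity: str = "INFO"
    sim: dict | None = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {sorted(SCHEMES)}")

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def read_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Recognised keys: ``houses``, ``transect_counts``, ``bird_scores``
    (paths, resolved relative to the config file), ``scheme``, ``alpha``,
    ``out_dir``, ``seed``, ``verbosity`` and an optional ``sim`` mapping
    (see :func:`parse_sim_config`).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    base = path.parent

    def respath(key):
        return None if raw.get(key) is None else (base / str(raw[key])).resolve()

    return RunConfig(
        houses=respath("houses"),
        transect_counts=respath("transect_counts"),
        bird_scores=respath("bird_scores"),
        scheme=raw.get("scheme", "aviary_transect"),
        alpha=float(raw.get("alpha", 0.05)),
        out_dir=(base / str(raw.get("out_dir", "out"))).resolve(),
        seed=int(raw.get("seed", 0)),
        verbosity=str(raw.get("verbosity", "INFO")),
        sim=raw.get("sim"),
        raw=raw,
    )


def parse_sim_config(sim: Mapping[str, object], seed: int | None = None) -> SimConfig:
    """Build a :class:`SimConfig` from the ``sim`` mapping of a run config.

    The mapping mirrors the SimConfig fields; ``geometry`` is a nested
    mapping with the house fields.  An explicit ``seed`` argument overrides
    the file value.
    """
    g = dict(sim["geometry"])  # type: ignore[arg-type]
    geometry = HouseGeometry(
        house_id=str(g.get("house_id", "sim")),
        house_width=float(g["house_width"]),
        aisle_widths=tuple(float(a) for a in g["aisle_widths"]),
        n_structures=int(g["n_structures"]),
        flock_size=int(g["flock_size"]),
        usable_area=float(g.get("usable_area", g["flock_size"] / 8.0)),
        floor_area=None if g.get("floor_area") is None else float(g["floor_area"]),
    )
    return SimConfig(
        geometry=geometry,
        prevalence={str(k): float(v) for k, v in dict(sim["prevalence"]).items()},  # type: ignore[arg-type]
        wall_bias=float(sim.get("wall_bias", 1.0)),
        vertical_weights=tuple(float(w) for w in sim.get("vertical_weights", (0.25,) * 4)),  # type: ignore[arg-type]
        sensitivity=float(sim.get("sensitivity", 1.0)),
        fp_rate=float(sim.get("fp_rate", 0.0)),
        sample_n=int(sim.get("sample_n", 50)),
        severity_pi2=float(sim.get("severity_pi2", 0.5)),
        seed=int(sim.get("seed", 0) if seed is None else seed),
    )
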