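"""Published field-study reference values for six commercial aviary flocks.

These constants transcribe the published layout, stocking-density and
graded-sample tables of the six-flock Norwegian field study that the transect
scheme was developed on.  They serve as golden inputs for regression tests and
for the reproduction script: the package must re-derive the printed transect
bird apportionments, stocking densities and graded-sample standard errors from
the raw quantities alone.

Flock 2's aisle widths are typographically garbled in the published layout
table; the values below are a reconstruction (they reproduce the printed
per-transect bird counts exactly) but flock 2 is excluded from golden layout
comparisons, see :data:`GOLDEN_LAYOUT_FLOCKS`.
"""

from __future__ import annotations

from .geometry import HouseGeometry

__all__ = [
    "PUBLISHED_HOUSES",
    "PUBLISHED_STRUCTURE_WIDTHS",
    "PUBLISHED_BIRDS_PER_TRANSECT",
    "PUBLISHED_DENSITIES",
    "GOLDEN_LAYOUT_FLOCKS",
    "PUBLISHED_GRADED_CELLS",
    "PUBLISHED_FLOCK_NOTES",
]

#: House layouts: aisle widths left wall -> right wall (m), house width (m),
#: structure-row count, flock size, usable and floor areas (m^2).
PUBLISHED_HOUSES: tuple[HouseGeometry, ...] = (
    HouseGeometry("flock1", 14.0, (1.75, 1.75, 1.75, 1.75), 3, 7500, 1850.0, 1000.0),
    # flock2 aisles reconstructed from the printed bird counts (see module docstring)
    HouseGeometry("flock2", 12.0, (1.54, 1.51, 1.51, 1.54), 3, 7700, 990.0, 506.0),
    HouseGeometry("flock3", 11.0, (1.11, 1.11, 1.11), 2, 7840, 915.0, 432.0),
    HouseGeometry("flock4", 10.0, (2.11, 2.11), 1, 7200, 815.0, 385.0),
    HouseGeometry("flock5", 12.0, (1.03, 1.10, 1.04), 2, 7500, 1005.0, 648.0),
    HouseGeometry("flock6", 11.0, (1.40, 1.49, 1.49, 1.40), 3, 7500, 910.0, 450.0),
)

#: Printed structure widths (m), rounded/truncated to 2 decimals in the report.
PUBLISHED_STRUCTURE_WIDTHS: dict[str, float] = {
    "flock1": 2.33,
    "flock2": 1.96,
    "flock3": 3.83,
    "flock4": 5.78,
    "flock5": 4.41,
    "flock6": 1.74,
}

#: Printed estimated birds per transect, left wall -> right wall.
PUBLISHED_BIRDS_PER_TRANSECT: dict[str, tuple[int, ...]] = {
    "flock1": (1563, 2188, 2188, 1563),
    "flock2": (1619, 2231, 2231, 1619),
    "flock3": (2158, 3524, 2158),
    "flock4": (3600, 3600),
    "flock5": (2023, 3447, 2030),
    "flock6": (1548, 2202, 2202, 1548),
}

#: Printed stocking densities (birds per m^2 usable area, truncated to 2 dp).
PUBLISHED_DENSITIES: dict[str, float] = {
    "flock1": 4.05,
    "flock2": 7.77,
    "flock3": 8.56,
    "flock4": 8.83,
    "flock5": 7.46,
    "flock6": 8.24,
}

#: Flocks whose printed aisle widths are unambiguous; golden layout tests use
#: these only (flock 2 reconstruction is checked nowhere).
GOLDEN_LAYOUT_FLOCKS: tuple[str, ...] = ("flock1", "flock3", "flock4", "flock5", "flock6")

#: Published graded-sample prevalence cells (50 birds per flock): each entry is
#: (flock, indicator, score_level, printed prevalence %, printed SE %).
PUBLISHED_GRADED_CELLS: tuple[tuple[str, str, int, float, float], ...] = (
    ("flock1", "fl_head", 1, 24.0, 6.1),
    ("flock1", "fl_head", 2, 28.0, 6.4),
    ("flock1", "fl_back", 1, 26.0, 6.3),
    ("flock1", "fl_back", 2, 28.0, 6.4),
    ("flock1", "dirty", 1, 6.0, 3.4),
    ("flock2", "fl_head", 1, 6.0, 3.4),
    ("flock2", "fl_head", 2, 0.0, 0.0),
    ("flock2", "fl_back", 1, 12.0, 4.6),
    ("flock2", "fl_back", 2, 2.0, 2.0),
    ("flock2", "dirty", 1, 30.0, 6.5),
    ("flock3", "fl_head", 1, 16.0, 5.2),
    ("flock3", "fl_head", 2, 0.0, 0.0),
    ("flock3", "fl_back", 1, 26.0, 6.3),
    ("flock3", "fl_back", 2, 32.0, 6.6),
    ("flock3", "dirty", 1, 0.0, 0.0),
    ("flock4", "fl_head", 1, 0.0, 0.0),
    ("flock4", "fl_head", 2, 0.0, 0.0),
    ("flock4", "fl_back", 1, 2.0, 2.0),
    ("flock4", "fl_back", 2, 0.0, 0.0),
    ("flock4", "dirty", 1, 4.0, 2.8),
    ("flock5", "fl_head", 1, 18.0, 5.5),
    ("flock5", "fl_head", 2, 0.0, 0.0),
    ("flock5", "fl_back", 1, 10.0, 4.3),
    ("flock5", "fl_back", 2, 6.0, 3.4),
    ("flock5", "dirty", 1, 30.0, 6.5),
    ("flock6", "fl_head", 1, 8.0, 3.9),
    ("flock6", "fl_head", 2, 0.0, 0.0),
    ("flock6", "fl_back", 1, 6.0, 3.4),
    ("flock6", "fl_back", 2, 0.0, 0.0),
    ("flock6", "dirty", 1, 16.0, 5.2),
)

#: Whole-flock descriptive records (beak trimming, antagonistic incidents,
#: flightiness, birds needing care, mortality of previous/current flock).
#: "unknown" is a legal value for producer-reported mortality.
PUBLISHED_FLOCK_NOTES: dict[str, dict[str, object]] = {
    "flock1": {
        "beak_trimmed": "no",
        "antagonistic_incidents": 1,
        "flightiness": "calm",
        "birds_needing_care": 1,
        "mortality_previous_flock_pct": 2.1,
        "mortality_to_date_pct": "unknown",
    },
    "flock2": {
        "beak_trimmed": "no",
        "antagonistic_incidents": 0,
        "flightiness": "cautious",
        "birds_needing_care": 3,
        "mortality_previous_flock_pct": 3.1,
        "mortality_to_date_pct": 2.0,
    },
    "flock3": {
        "beak_trimmed": "no",
        "antagonistic_incidents": 2,
        "flightiness": "calm",
        "birds_needing_care": 3,
        "mortality_previous_flock_pct": 2.1,
        "mortality_to_date_pct": 0.9,
    },
    "flock4": {
        "beak_trimmed": "no",
        "antagonistic_incidents": 4,
        "flightiness": "calm",
        "birds_needing_care": 8,
        "mortality_previous_flock_pct": "unknown",
        "mortality_to_date_pct": "unknown",
    },
    "flock5": {
        "beak_trimmed": "no",
        "antagonistic_incidents": 0,
        "flightiness": "calm",
        "birds_needing_care": 2,
        "mortality_previous_flock_pct": 4.4,
        "mortality_to_date_pct": 2.0,
    },
    "flock6": {
        "beak_trimmed": "no",
        "antagonistic_incidents": 2,
        "flightiness": "calm",
        "birds_needing_care": 3,
        "mortality_previous_flock_pct": 3.1,
        "mortality_to_date_pct": 1.6,
    },
}
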