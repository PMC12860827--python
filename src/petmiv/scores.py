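"""Lobar structural scoring of chest HRCT and lung MR readings.

Each of six scoring regions (five lobes plus the lingula) is rated per
radiological feature on a three-level extent scale: 0 = feature absent,
1 = present and affecting at most half of the lobe, 2 = present and
affecting more than half of the lobe.  Feature, region and total scores
are plain sums of these grades.  No side-specific analysis is performed
(patients with situs inversus would otherwise produce spurious
left/right mismatches), so all score arithmetic is invariant under
relabeling of regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "REGIONS",
    "DEFAULT_FEATURES",
    "MODALITIES",
    "LOBE_GROUPS",
    "ScoreError",
    "EichingerSheet",
    "score_column",
]

#: The six scoring regions: five lobes plus the lingula.
REGIONS: tuple[str, ...] = (
    "right_upper",
    "middle",
    "right_lower",
    "left_upper",
    "lingula",
    "left_lower",
)

#: Default radiological features rated per region.
DEFAULT_FEATURES: tuple[str, ...] = (
    "bronchiectasis",
    "consolidation",
    "mucus_plugging",
    "tree_in_bud",
)

MODALITIES: tuple[str, ...] = ("HRCT", "MR")

#: Anatomical grouping used for the per-lobe summary and its
#: Kruskal-Wallis comparison: upper lobes vs lower lobes vs middle/lingula.
LOBE_GROUPS: dict[str, tuple[str, ...]] = {
    "upper": ("right_upper", "left_upper"),
    "lower": ("right_lower", "left_lower"),
    "middle_lingula": ("middle", "lingula"),
}

VALID_GRADES = (0, 1, 2)


class ScoreError(ValueError):
    """Invalid score sheet content or lookup."""


def score_column(modality: str, region: str, feature: str) -> str:
    """Column name used for one (modality, region, feature) cell in wide CSVs."""
    return f"{modality.lower()}_{region}_{feature}"


@dataclass(frozen=True)
class EichingerSheet:
    """Per-lobe, per-feature extent grades for one patient and one modality.

    ``ratings`` maps ``(region, feature)`` to a grade in {0, 1, 2} and must
    be complete over ``regions`` × ``features``.
    """

    patient_id: str
    modality: str
    ratings: Mapping[tuple[str, str], int]
    regions: tuple[str, ...] = REGIONS
    features: tuple[str, ...] = DEFAULT_FEATURES

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ScoreError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if len(set(self.regions)) != len(self.regions):
            raise ScoreError(f"duplicate regions in {self.regions}")
        if len(set(self.features)) != len(self.features):
            raise ScoreError(f"duplicate features in {self.features}")
        ratings = dict(self.ratings)
        for region in self.regions:
            for feature in self.features:
                key = (region, feature)
                if key not in ratings:
                    raise ScoreError(
                        f"patient {self.patient_id} ({self.modality}): "
                        f"missing rating for region={region}, feature={feature}"
                    )
                grade = ratings[key]
                if grade not in VALID_GRADES:
                    raise ScoreError(
                        f"patient {self.patient_id} ({self.modality}): grade {grade!r} "
                        f"for region={region}, feature={feature} not in {VALID_GRADES}"
                    )
        extra = set(ratings) - {(r, f) for r in self.regions for f in self.features}
        if extra:
            raise ScoreError(f"unknown rating cells: {sorted(extra)[:5]}")
        object.__setattr__(self, "ratings", {k: int(v) for k, v in ratings.items()})

    def feature_score(self, feature: str) -> int:
        """Sum of one feature's grades over all regions (0 .. 2·n_regions)."""
        if feature not in self.features:
            raise ScoreError(f"unknown feature {feature!r}; sheet has {self.features}")
        return sum(self.ratings[(r, feature)] for r in self.regions)

    def region_score(self, region: str) -> int:
        """Sum of all features' grades in one region (0 .. 2·n_features)."""
        if region not in self.regions:
            raise ScoreError(f"unknown region {region!r}; sheet has {self.regions}")
        return sum(self.ratings[(region, f)] for f in self.features)

    def total_score(self) -> int:
        """Sum of all cells; equals both the feature-score and region-score sums."""
        return sum(self.ratings.values())

    @property
    def max_score(self) -> int:
        return 2 * len(self.regions) * len(self.features)

    def to_columns(self) -> dict[str, int]:
        """Flatten to the wide-CSV column layout."""
        return {
            score_column(self.modality, r, f): self.ratings[(r, f)]
            for r in self.regions
            for f in self.features
        }

    @classmethod
    def from_columns(
        cls,
        patient_id: str,
        modality: str,
        row: Mapping[str, int],
        features: tuple[str, ...] = DEFAULT_FEATURES,
        regions: tuple[str, ...] = REGIONS,
    ) -> "EichingerSheet":
        """Build a sheet from a wide-format row of ``modality_region_feature`` cells."""
        ratings = {}
        for r in regions:
            for f in features:
                col = score_column(modality, r, f)
                if col not in row:
                    raise ScoreError(f"patient {patient_id}: missing column {col!r}")
                ratings[(r, f)] = row[col]
        return cls(patient_id, modality, ratings, regions, features)
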