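"""Three-domain MRI injury representation and the weighted injury score.

Very preterm infants (born at or before 30 weeks gestation) are scanned at
term-equivalent age and injury is read in three domains: intraventricular
hemorrhage (IVH, Papile grade I-IV), white matter injury (WMI, punctate or
cystic lesions), and cerebellar hemorrhage (CH, sized relative to a
cerebellar hemisphere, possibly bilateral). Each domain contributes integer
points; the total score feeds threshold classification and the composite
logistic risk model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterator

IVH_GRADES = ("none", "I", "II", "III", "IV")
IVH_CATEGORIES = ("none", "low", "high")
CH_SIZES = ("none", "punctate_or_small", "large")
WMI_CATEGORIES = ("none", "isolated_punctate", "multiple_or_cystic")

# "punctate" and "small" CH are separate radiological descriptions but carry
# the same point value (<50% of a hemisphere); they map to one scored level.
CH_SIZE_SYNONYMS = {
    "none": "none",
    "punctate": "punctate_or_small",
    "small": "punctate_or_small",
    "punctate_or_small": "punctate_or_small",
    "large": "large",
}

#: The seven weighted levels, in descending clinical severity. This is also
#: the default feature order for the greedy weight search.
WEIGHT_FEATURES = (
    "ivh_high",
    "wmi_multiple_or_cystic",
    "ch_large",
    "ivh_low",
    "wmi_isolated",
    "ch_small",
    "ch_bilateral_bonus",
)

#: Milder level -> more severe level within the same domain. The milder
#: level may never carry more points than the severe one.
DOMAIN_SEVERE_SIBLING = {
    "ivh_low": "ivh_high",
    "wmi_isolated": "wmi_multiple_or_cystic",
    "ch_small": "ch_large",
}


def classify_ivh(grade: str) -> str:
    """Collapse a Papile grade into none / low (I-II) / high (III-IV)."""
    if grade not in IVH_GRADES:
        raise ValueError(f"unknown IVH grade {grade!r}; expected one of {IVH_GRADES}")
    if grade == "none":
        return "none"
    return "low" if grade in ("I", "II") else "high"


def classify_wmi(lesion_count: int, cystic: bool) -> str:
    """Categorize white matter injury.

    No lesions and no cysts -> none; one or two punctate lesions ->
    isolated_punctate; more than two lesions, or any cystic lesion ->
    multiple_or_cystic (cystic change dominates regardless of count).
    """
    if lesion_count < 0:
        raise ValueError("lesion count must be non-negative")
    if cystic or lesion_count > 2:
        return "multiple_or_cystic"
    if lesion_count >= 1:
        return "isolated_punctate"
    return "none"


@dataclass(frozen=True)
class InjuryProfile:
    """One infant's MRI findings across the three injury domains."""

    ivh_grade: str = "none"
    ch_size: str = "none"
    ch_bilateral: bool = False
    wmi_lesion_count: int = 0
    wmi_cystic: bool = False

    def __post_init__(self) -> None:
        if self.ivh_grade not in IVH_GRADES:
            raise ValueError(f"unknown IVH grade {self.ivh_grade!r}")
        size = CH_SIZE_SYNONYMS.get(self.ch_size)
        if size is None:
            raise ValueError(f"unknown CH size {self.ch_size!r}")
        object.__setattr__(self, "ch_size", size)
        if self.ch_bilateral and size == "none":
            raise ValueError("bilateral CH requires a non-absent CH size")
        if not isinstance(self.wmi_lesion_count, int) or self.wmi_lesion_count < 0:
            raise ValueError("wmi_lesion_count must be a non-negative integer")
        if self.wmi_cystic and self.wmi_lesion_count < 1:
            raise ValueError("cystic WMI requires at least one lesion")

    @property
    def ivh_category(self) -> str:
        return classify_ivh(self.ivh_grade)

    @property
    def wmi_category(self) -> str:
        return classify_wmi(self.wmi_lesion_count, self.wmi_cystic)

    def feature_indicators(self) -> dict[str, int]:
        """0/1 indicator for each weighted level (at most one per domain)."""
        ivh = self.ivh_category
        wmi = self.wmi_category
        return {
            "ivh_high": int(ivh == "high"),
            "ivh_low": int(ivh == "low"),
            "wmi_multiple_or_cystic": int(wmi == "multiple_or_cystic"),
            "wmi_isolated": int(wmi == "isolated_punctate"),
            "ch_large": int(self.ch_size == "large"),
            "ch_small": int(self.ch_size == "punctate_or_small"),
            "ch_bilateral_bonus": int(self.ch_bilateral),
        }


@dataclass(frozen=True)
class WeightTable:
    """Integer points per scored injury level; absent levels score 0.

    Within a domain the more severe level must carry at least as many
    points as the milder one, and all points are non-negative integers.
    """

    ivh_low: int
    ivh_high: int
    wmi_isolated: int
    wmi_multiple_or_cystic: int
    ch_small: int
    ch_large: int
    ch_bilateral_bonus: int

    def __post_init__(self) -> None:
        for name in WEIGHT_FEATURES:
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        for mild, severe in DOMAIN_SEVERE_SIBLING.items():
            if getattr(self, mild) > getattr(self, severe):
                raise ValueError(
                    f"{mild} ({getattr(self, mild)}) may not exceed {severe} "
                    f"({getattr(self, severe)})"
                )

    def replace(self, **changes: int) -> "WeightTable":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in WEIGHT_FEATURES}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WeightTable":
        return cls(**json.loads(text))

    @property
    def max_score(self) -> int:
        """Largest attainable score: the sum of per-domain maxima."""
        return (
            max(self.ivh_low, self.ivh_high)
            + max(self.wmi_isolated, self.wmi_multiple_or_cystic)
            + max(self.ch_small, self.ch_large)
            + self.ch_bilateral_bonus
        )


def final_weights() -> WeightTable:
    """The published weighted scoring system.

    High-grade IVH and multiple-punctate/cystic WMI carry 5 points each,
    low-grade IVH and isolated punctate WMI 2 points, large CH 3 points,
    punctate/small CH 1 point, and bilateral CH adds 1 bonus point
    (maximum attainable score 14).
    """
    return WeightTable(
        ivh_low=2,
        ivh_high=5,
        wmi_isolated=2,
        wmi_multiple_or_cystic=5,
        ch_small=1,
        ch_large=3,
        ch_bilateral_bonus=1,
    )


def baseline_weights() -> WeightTable:
    """Equal weighting: 0 points for an absent feature, 1 point for present.

    Because at most one level per domain applies to any one infant, the
    per-domain and per-level readings of "equal weight" produce the same
    table; the maximum attainable baseline score is 4 (CH size + CH
    bilaterality + IVH + WMI).
    """
    return WeightTable(
        ivh_low=1,
        ivh_high=1,
        wmi_isolated=1,
        wmi_multiple_or_cystic=1,
        ch_small=1,
        ch_large=1,
        ch_bilateral_bonus=1,
    )


def score_injury(profile: InjuryProfile, weights: WeightTable) -> int:
    """Total injury score: CH size + CH bilateral bonus + IVH + WMI points."""
    indicators = profile.feature_indicators()
    return sum(getattr(weights, name) * flag for name, flag in indicators.items())


@dataclass(frozen=True)
class ScoreThreshold:
    """Predicted-severe iff score is strictly greater than the threshold."""

    threshold: int

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


def classify_by_threshold(score: int, threshold: "ScoreThreshold | int") -> bool:
    """Strict-inequality rule: a score of exactly the threshold is negative."""
    cut = threshold.threshold if isinstance(threshold, ScoreThreshold) else threshold
    return score > cut


def iter_profiles(max_lesions: int = 4) -> Iterator[InjuryProfile]:
    """Enumerate valid injury profiles (WMI lesion counts 0..max_lesions)."""
    for grade in IVH_GRADES:
        for size in CH_SIZES:
            bilaterals = (False, True) if size != "none" else (False,)
            for bilateral in bilaterals:
                for count in range(max_lesions + 1):
                    cystics = (False, True) if count >= 1 else (False,)
                    for cystic in cystics:
                        yield InjuryProfile(
                            ivh_grade=grade,
                            ch_size=size,
                            ch_bilateral=bilateral,
                            wmi_lesion_count=count,
                            wmi_cystic=cystic,
                        )
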