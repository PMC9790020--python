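"""Macro-level network-design recommendations from complexity and resolution.

The rule engine encodes a simple decision framework: dataset complexity
(median frequency by default, the best predictor of downsampling loss)
drives the depth choice — high-complexity data favour *shallow* networks,
low-complexity data *deep* ones — while image resolution drives the
capacity choice — high-resolution data favour *lightweight* networks,
low-resolution data *large-size* ones.  The numeric cutoffs are indicative
and task dependent, so every recommendation records the thresholds used.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .complexity_measures import ComplexityProfile
from .errors import ValidationError

__all__ = [
    "AdvisorThresholds",
    "DesignRecommendation",
    "recommend_design",
    "max_acceptable_downsampling",
]


@dataclass(frozen=True)
class AdvisorThresholds:
    """Cutoffs for the design rules.

    complexity_cutoff : value of the deciding measure at or above which a
        dataset counts as high complexity (default 0.05 cycles/sample MDF).
    megapixel_cutoff : resolution in megapixels at or above which a dataset
        counts as high resolution.
    error_tolerance : acceptable mean overlap error E when choosing a
        downsampling factor.
    measure : which profile field decides complexity ('mdf', 'mnf', 'de', 'pc').
    """

    complexity_cutoff: float = 0.05
    megapixel_cutoff: float = 1.0
    error_tolerance: float = 0.05
    measure: str = "mdf"


@dataclass(frozen=True)
class DesignRecommendation:
    depth_class: str  # 'deep' | 'shallow'
    size_class: str  # 'large-size' | 'lightweight'
    max_downsampling: int
    rationale: str
    thresholds_used: AdvisorThresholds

    @property
    def category(self) -> str:
        return f"{self.depth_class} {self.size_class}"

    def as_dict(self) -> dict:
        d = {
            "depth_class": self.depth_class,
            "size_class": self.size_class,
            "category": self.category,
            "max_downsampling": self.max_downsampling,
            "rationale": self.rationale,
            "thresholds_used": asdict(self.thresholds_used),
        }
        return d


def recommend_design(
    profile: ComplexityProfile,
    resolution: tuple[int, int],
    thresholds: AdvisorThresholds | None = None,
    audit: pd.DataFrame | None = None,
) -> DesignRecommendation:
    """Map a complexity profile and image resolution to one of four
    macro-level categories (deep/shallow x large-size/lightweight).

    If a degradation *audit* table is supplied, the maximum acceptable
    downsampling factor at the configured error tolerance is included;
    otherwise it defaults to 1 (no downsampling advice without evidence).
    """
    th = thresholds or AdvisorThresholds()
    w, h = resolution
    if w <= 0 or h <= 0:
        raise ValidationError(f"resolution must be positive, got {resolution}")
    if th.measure not in ("de", "mnf", "mdf", "pc"):
        raise ValidationError(f"unknown deciding measure {th.measure!r}")
    value = getattr(profile, th.measure)
    megapixels = w * h / 1e6

    high_complexity = value >= th.complexity_cutoff
    high_resolution = megapixels >= th.megapixel_cutoff
    depth = "shallow" if high_complexity else "deep"
    size = "lightweight" if high_resolution else "large-size"

    reasons = [
        f"{th.measure.upper()} = {value:.4g} is "
        f"{'>=' if high_complexity else '<'} {th.complexity_cutoff:.4g} "
        f"({'high' if high_complexity else 'low'} complexity) -> {depth} network",
        f"resolution {w}x{h} = {megapixels:.2f} MP is "
        f"{'>=' if high_resolution else '<'} {th.megapixel_cutoff:.4g} MP "
        f"({'high' if high_resolution else 'low'} resolution) -> {size} network",
    ]
    max_down = 1
    if audit is not None:
        max_down = max_acceptable_downsampling(audit, th.error_tolerance)
        reasons.append(
            f"mean overlap error stays <= {th.error_tolerance:.4g} "
            f"up to downsampling factor {max_down}"
        )
    return DesignRecommendation(
        depth_class=depth,
        size_class=size,
        max_downsampling=max_down,
        rationale="; ".join(reasons),
        thresholds_used=th,
    )


def max_acceptable_downsampling(audit: pd.DataFrame, tolerance: float = 0.05) -> int:
    """Largest audited factor whose mean overlap error stays within *tolerance*.

    *audit* is a degradation table indexed by factor with an ``error``
    column (as produced by ``degradation_audit``).  Returns 1 when even the
    smallest audited factor exceeds the tolerance.  Non-decreasing in
    tolerance by construction.
    """
    if audit is None or len(audit) == 0:
        raise ValidationError("degradation audit table is empty")
    if "error" not in audit.columns:
        raise ValidationError("audit table lacks an 'error' column")
    if not 0 <= tolerance <= 1:
        raise ValidationError(f"tolerance must be in [0, 1], got {tolerance}")
    acceptable = 1
    for factor in sorted(int(f) for f in audit.index):
        if float(audit.loc[factor, "error"]) <= tolerance:
            acceptable = max(acceptable, factor)
        else:
            break
    return acceptable
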