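"""Directionality of CSS effects and parental-boundary analysis.

The directionality ratio for one CSS and trait is

    r = (T_host - T_CSS) / (T_host - T_donor)

``r > 0``: the substitution shifted the phenotype *towards* the donor
strain; ``r < 0``: *away* from it; ``r > 1``: towards and beyond —
*more extreme* than the donor itself.  ``r`` equals NormUnit/100
identically.

The boundary (ceiling/floor) analysis asks whether the two parental
means bound the range of CSS means for a trait — evidence that parental
genetics set physiological limits on phenotypic variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import PreconditionError, UndefinedNormalizerError
from .panel_io import TraitSummary
from .rounding import percent

logger = logging.getLogger(__name__)

Category = Literal["towards", "away", "at_host"]


@dataclass(frozen=True)
class DirectionalityCall:
    strain_id: str
    trait_id: str
    sex: str
    r: float
    category: Category
    more_extreme: bool
    significant: bool


@dataclass(frozen=True)
class BoundaryResult:
    trait_id: str
    sex: str
    upper_parental: bool
    lower_parental: bool

    @property
    def n_boundaries(self) -> int:
        return int(self.upper_parental) + int(self.lower_parental)


def direction_ratio(
    css: TraitSummary, host: TraitSummary, donor: TraitSummary
) -> float:
    """(T_host - T_CSS) / (T_host - T_donor); unit-free and affine-invariant."""
    d = host.mean - donor.mean
    if d == 0.0:
        raise UndefinedNormalizerError("host and donor means equal; r undefined")
    return (host.mean - css.mean) / d


def classify_direction(r: float) -> tuple[Category, bool]:
    """Map r to (category, more_extreme).  r = 0 exactly (CSS at the host
    mean) gets its own category rather than a forced sign."""
    if r > 0:
        return "towards", r > 1
    if r < 0:
        return "away", False
    return "at_host", False


def make_call(
    css: TraitSummary,
    host: TraitSummary,
    donor: TraitSummary,
    significant: bool,
) -> DirectionalityCall:
    r = direction_ratio(css, host, donor)
    category, more_extreme = classify_direction(r)
    return DirectionalityCall(
        css.strain_id, css.trait_id, css.sex, r, category, more_extreme, significant
    )


@dataclass(frozen=True)
class DirectionalitySummary:
    n: int
    n_towards: int
    n_away: int
    n_at_host: int
    n_more_extreme: int
    pct_towards: float
    pct_away: float
    pct_at_host: float
    pct_more_extreme: float
    empty: bool = False


def directionality_summary(
    calls: Iterable[DirectionalityCall],
    subset: Literal["significant", "nonsignificant", "all"] = "significant",
    decimals: int = 1,
) -> DirectionalitySummary:
    """Counts and percentages of towards/away/more-extreme shifts.

    Percentages are 100*count/total rounded half-away-from-zero at
    ``decimals`` places (one decimal matches the panel tables; pass 0
    for the integer percentages quoted in running text).
    """
    if subset == "significant":
        sel = [c for c in calls if c.significant]
    elif subset == "nonsignificant":
        sel = [c for c in calls if not c.significant]
    else:
        sel = list(calls)
    n = len(sel)
    if n == 0:
        logger.warning("directionality_summary: empty %s subset", subset)
        return DirectionalitySummary(0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    n_t = sum(c.category == "towards" for c in sel)
    n_a = sum(c.category == "away" for c in sel)
    n_h = sum(c.category == "at_host" for c in sel)
    n_me = sum(c.more_extreme for c in sel)
    pct = lambda k: percent(k, n, decimals)
    return DirectionalitySummary(
        n, n_t, n_a, n_h, n_me, pct(n_t), pct(n_a), pct(n_h), pct(n_me)
    )


def boundary_analysis(
    css_means: Sequence[float],
    host_mean: float,
    donor_mean: float,
    trait_id: str = "",
    sex: str = "",
) -> BoundaryResult:
    """Do the parental means bound the CSS means above / below?

    Comparison is on strain means (not individual animals); a CSS mean
    exactly equal to a parental mean counts as bounded.
    """
    if not css_means:
        raise PreconditionError("boundary_analysis requires at least one CSS mean")
    hi = max(host_mean, donor_mean)
    lo = min(host_mean, donor_mean)
    return BoundaryResult(
        trait_id,
        sex,
        upper_parental=max(css_means) <= hi,
        lower_parental=min(css_means) >= lo,
    )
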