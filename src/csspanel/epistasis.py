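"""Genome-wide cumulative-effect test for non-additivity (epistasis).

If chromosome effects combined additively, the signed NormUnit effects
summed across a panel of CSSs should approach 100% of the host-donor
difference — each substituted chromosome contributes its share of the
parental gap.  Sums far above 100% mean the same phenotypic shift is
produced many times over by different chromosomes, which is only
possible with strong epistasis in the intact parental genomes.

The decision rule: a trait is *epistatic* when ``|cumulative effect| -
SEM > 100%``, with the SEM propagated across strains.  Three subsets are
tested per trait: CSSs with significant effects, CSSs without, and all
combined (the two sums add exactly to the combined one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .effects import EffectSize
from .errors import PreconditionError
from .panel_io import TraitSummary

logger = logging.getLogger(__name__)

Subset = Literal["significant", "nonsignificant", "combined"]
SUBSETS: tuple[Subset, ...] = ("significant", "nonsignificant", "combined")


@dataclass(frozen=True)
class CumulativeEffect:
    trait_id: str
    sex: str
    subset: Subset
    sum_percent: float
    sem_percent: float
    epistatic: bool
    empty: bool = False


def _select(effects: Sequence[EffectSize], subset: Subset) -> list[EffectSize]:
    if subset == "significant":
        return [e for e in effects if e.significant]
    if subset == "nonsignificant":
        return [e for e in effects if not e.significant]
    return list(effects)


def cumulative_effect(
    effects: Sequence[EffectSize],
    subset: Subset = "combined",
    host: TraitSummary | None = None,
    donor: TraitSummary | None = None,
    covariance_aware: bool = False,
) -> CumulativeEffect:
    """Sum signed NormUnit effects over one subset and propagate the SEM.

    Default propagation is simple quadrature, ``sem = sqrt(sum sem_i^2)``,
    treating strains as independent.  In truth every effect shares the
    same host and donor means; ``covariance_aware=True`` adds the induced
    covariance terms (requires ``host`` and ``donor`` summaries), for
    sensitivity analysis.

    An empty subset yields a zero, non-epistatic row flagged ``empty``
    so panel aggregates stay defined.
    """
    effects = list(effects)
    if not effects:
        raise PreconditionError("cumulative_effect requires at least one effect")
    keys = {(e.trait_id, e.sex) for e in effects}
    if len(keys) > 1:
        raise PreconditionError(f"effects mix traits: {sorted(keys)}")
    (trait_id, sex), = keys
    if subset == "combined" and not covariance_aware:
        # built from the subset aggregates so the linearity identities
        # (combined sum = sig + nonsig, combined var = sig var + nonsig var)
        # hold exactly in floating point
        sig = cumulative_effect(effects, "significant")
        non = cumulative_effect(effects, "nonsignificant")
        total = sig.sum_percent + non.sum_percent
        sem = math.sqrt(sig.sem_percent**2 + non.sem_percent**2)
        return CumulativeEffect(
            trait_id, sex, "combined", total, sem, abs(total) - sem > 100.0
        )
    sel = _select(effects, subset)
    if not sel:
        return CumulativeEffect(trait_id, sex, subset, 0.0, 0.0, False, empty=True)
    total = sum(e.norm_unit for e in sel)
    if covariance_aware:
        if host is None or donor is None:
            raise PreconditionError(
                "covariance-aware propagation needs host and donor summaries"
            )
        d = donor.mean - host.mean
        # dC/d(css_i) = 100/D each; shared-parent partials accumulate over i
        ratios = [e.norm_unit / 100.0 for e in sel]
        var_css = sum(
            e.sem_norm_unit**2
            - (100.0 / d) ** 2
            * (host.sem**2 * (1 - r) ** 2 + donor.sem**2 * r**2)
            for e, r in zip(sel, ratios)
        )
        dh = -(100.0 / d) * sum(1 - r for r in ratios)
        dd = -(100.0 / d) * sum(ratios)
        var = var_css + host.sem**2 * dh**2 + donor.sem**2 * dd**2
        sem = math.sqrt(max(var, 0.0))
    else:
        sem = math.sqrt(sum(e.sem_norm_unit**2 for e in sel))
    epistatic = abs(total) - sem > 100.0
    return CumulativeEffect(trait_id, sex, subset, total, sem, epistatic)


@dataclass
class EpistasisSummary:
    """Per-trait cumulative rows plus panel-level aggregates."""

    rows: list[CumulativeEffect]
    percent_epistatic: dict[Subset, float]
    median_abs_sum: dict[Subset, float]
    n_traits: int


def epistasis_summary(
    effects_by_trait: Mapping[tuple[str, str], Sequence[EffectSize]],
) -> EpistasisSummary:
    """Run the cumulative test for every qualifying trait and aggregate.

    ``effects_by_trait`` must already be restricted to the qualifying
    traits (multigenic with a significant parental difference) — the
    report module applies that filter.  Aggregates per subset: percent
    of traits epistatic, and median |cumulative effect|; empty subsets
    are excluded from both.
    """
    if not effects_by_trait:
        logger.warning("epistasis_summary: no qualifying traits")
        return EpistasisSummary([], {}, {}, 0)
    rows: list[CumulativeEffect] = []
    for (trait_id, sex), effects in sorted(effects_by_trait.items()):
        for subset in SUBSETS:
            rows.append(cumulative_effect(effects, subset))
    pct: dict[Subset, float] = {}
    med: dict[Subset, float] = {}
    for subset in SUBSETS:
        sub = [r for r in rows if r.subset == subset and not r.empty]
        if not sub:
            continue
        pct[subset] = 100.0 * sum(r.epistatic for r in sub) / len(sub)
        med[subset] = float(np.median([abs(r.sum_percent) for r in sub]))
    return EpistasisSummary(rows, pct, med, len(effects_by_trait))
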