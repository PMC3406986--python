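"""Effect-size normalization for CSS phenotypic shifts.

Two normalizations are supported:

* **NormUnit** — the CSS shift as a signed percent of the host-donor
  difference: ``100 * (T_CSS - T_host) / (T_donor - T_host)``.  0% means
  the CSS sits at the host, 100% at the donor; positive values are
  shifts toward the donor.
* **Hi_Low** — the same shift as a signed percent of the full range of
  strain means (parents and all CSSs) for the trait.

The inbred-panel design precludes conventional variance-component
effect sizes, hence these range-based measures.  The SEM of NormUnit is
propagated by the delta method treating the three strain means as
independent (different animals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import PreconditionError, UndefinedNormalizerError
from .panel_io import PanelDataset, TraitSummary
from .qtl import QTLCall


@dataclass(frozen=True)
class EffectSize:
    """Normalized effect of one CSS on one (trait, sex)."""

    strain_id: str
    trait_id: str
    sex: str
    norm_unit: float        # signed percent of host-donor difference
    hi_low: float           # signed percent of panel range
    sem_norm_unit: float    # delta-method SEM of norm_unit, percent
    significant: bool


def norm_unit(css: TraitSummary, host: TraitSummary, donor: TraitSummary) -> float:
    """Signed percent of the host-donor difference: 100*(T_CSS-T_host)/(T_donor-T_host)."""
    d = donor.mean - host.mean
    if d == 0.0:
        raise UndefinedNormalizerError(
            f"host and donor means equal ({host.mean}) for "
            f"({css.trait_id}, {css.sex}); NormUnit undefined"
        )
    # grouped so the identity norm_unit == 100 * direction ratio is exact
    return 100.0 * ((css.mean - host.mean) / d)


def hi_low(
    css: TraitSummary, host: TraitSummary, all_means: Iterable[float]
) -> float:
    """Signed percent of the full panel range of strain means.

    ``all_means`` must include the host, the donor, and every CSS mean
    for the trait.
    """
    means = list(all_means)
    if len(means) < 2:
        raise PreconditionError("hi_low needs at least 2 strain means")
    rng = max(means) - min(means)
    if rng == 0.0:
        raise UndefinedNormalizerError(
            f"zero range of strain means for ({css.trait_id}, {css.sex})"
        )
    return 100.0 * (css.mean - host.mean) / rng


def effect_sem(
    css: TraitSummary, host: TraitSummary, donor: TraitSummary
) -> float:
    """First-order (delta-method) SEM of NormUnit, in percent.

    With D = T_donor - T_host and N = T_CSS - T_host,

        SEM^2 = (100/D)^2 * [ sem_css^2
                              + sem_host^2 * (1 - N/D)^2
                              + sem_donor^2 * (N/D)^2 ]

    assuming the three strain means are independent, which holds by
    design (different animals per strain).
    """
    d = donor.mean - host.mean
    if d == 0.0:
        raise UndefinedNormalizerError("host and donor means equal; SEM undefined")
    for s in (css, host, donor):
        if math.isnan(s.sem):
            raise PreconditionError(f"SEM undefined for strain {s.strain_id} (n={s.n})")
    ratio = (css.mean - host.mean) / d
    var = (100.0 / d) ** 2 * (
        css.sem**2
        + host.sem**2 * (1.0 - ratio) ** 2
        + donor.sem**2 * ratio**2
    )
    return math.sqrt(var)


def compute_effects(
    panel: PanelDataset,
    trait_id: str,
    sex: str,
    calls: Sequence[QTLCall],
) -> list[EffectSize]:
    """NormUnit, Hi_Low and propagated SEM for every tested CSS of one trait.

    ``calls`` supplies the significance flags (from :func:`detect_qtls`)
    and defines which CSS lines enter; the panel supplies the means.
    """
    host = panel.summary(panel.host_id, trait_id, sex)
    donor = panel.summary(panel.donor_id, trait_id, sex)
    if host is None or donor is None:
        raise PreconditionError(f"host/donor summary missing for ({trait_id}, {sex})")
    all_means = list(panel.strain_means(trait_id, sex).values())
    out = []
    for call in calls:
        css = panel.summary(call.strain_id, trait_id, sex)
        if css is None:
            raise PreconditionError(
                f"no summary for called strain {call.strain_id} ({trait_id}, {sex})"
            )
        out.append(
            EffectSize(
                call.strain_id,
                trait_id,
                sex,
                norm_unit(css, host, donor),
                hi_low(css, host, all_means),
                effect_sem(css, host, donor),
                call.significant,
            )
        )
    return out


def average_effect(
    effects: Iterable[EffectSize], significant_only: bool = True
) -> float:
    """Arithmetic mean of |NormUnit| over the selected CSS-trait pairs.

    The absolute value keeps opposite-signed shifts from cancelling:
    the panel-level "average phenotypic effect" is a magnitude.
    """
    sel = [e for e in effects if e.significant or not significant_only]
    if not sel:
        raise PreconditionError("average_effect over an empty selection")
    return sum(abs(e.norm_unit) for e in sel) / len(sel)
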