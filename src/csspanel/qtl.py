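"""QTL detection: per-strain t-tests against the host, strain-wise
Bonferroni correction, and trait classification.

In a CSS panel each substituted chromosome is tested independently: a
CSS whose trait mean differs significantly from the host strain carries
at least one QTL on its donor chromosome.  Correction is applied across
strains, never across traits, and a trait is called *multigenic* when at
least three CSSs differ significantly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

from scipy import stats

from .errors import DegenerateInputError, PreconditionError
from .panel_io import PanelDataset, TraitSummary

logger = logging.getLogger(__name__)

TestMethod = Literal["welch", "pooled"]
BonferroniScope = Literal["per_trait", "per_panel"]

TRAIT_CLASSES = ("nonsignificant", "monogenic", "digenic", "multigenic")


@dataclass(frozen=True)
class QTLCall:
    """One CSS-versus-host comparison for one (trait, sex)."""

    strain_id: str
    trait_id: str
    sex: str
    t_stat: float
    df: float
    p_raw: float
    alpha_adjusted: float
    significant: bool


@dataclass(frozen=True)
class TraitClassification:
    trait_id: str
    sex: str
    n_significant: int
    trait_class: str
    parental_diff_significant: bool


def welch_t(
    a: TraitSummary, b: TraitSummary, method: TestMethod = "welch"
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test from summary statistics.

    Returns ``(t, df, p)`` with ``t = (mean_a - mean_b) / sqrt(sem_a^2 +
    sem_b^2)`` and Welch-Satterthwaite degrees of freedom; ``method=
    "pooled"`` gives the classical equal-variance Student test instead.

    Zero-variance groups are a real possibility with count-like traits:
    identical means give the null result (t=0, p=1); different means
    with no variance anywhere are a degenerate input and raise.
    """
    for s in (a, b):
        if s.n < 2 or not s.sd_defined:
            raise PreconditionError(
                f"strain {s.strain_id} has n={s.n} / undefined sd; need n >= 2"
            )
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise DegenerateInputError(
            f"zero variance in both groups with unequal means "
            f"({a.strain_id} vs {b.strain_id})"
        )
    if method == "pooled":
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        df = float(a.n + b.n - 2)
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def detect_qtls(
    panel: PanelDataset,
    trait_id: str,
    sex: str,
    alpha: float = 0.05,
    method: TestMethod = "welch",
    bonferroni: BonferroniScope = "per_trait",
) -> list[QTLCall]:
    """Test every CSS line against the host for one (trait, sex).

    The Bonferroni divisor ``m`` is the number of CSS lines actually
    tested for the trait (``per_trait``, the default, since data
    availability varies by trait) or the full panel size (``per_panel``).
    Lines with n < 2 or undefined SD are skipped with a warning.
    """
    host = panel.summary(panel.host_id, trait_id, sex)
    if host is None or not host.sd_defined:
        raise PreconditionError(f"no usable host summary for ({trait_id}, {sex})")
    testable: list[TraitSummary] = []
    for sid in panel.css_ids:
        s = panel.summary(sid, trait_id, sex)
        if s is None:
            continue
        if not s.sd_defined:
            logger.warning("skipping %s for (%s, %s): n=%d", sid, trait_id, sex, s.n)
            continue
        testable.append(s)
    if not testable:
        logger.warning("no testable CSS lines for (%s, %s)", trait_id, sex)
        return []
    m = len(testable) if bonferroni == "per_trait" else len(panel.css_ids)
    alpha_adj = alpha / m
    calls = []
    for s in testable:
        t, df, p = welch_t(s, host, method=method)
        calls.append(
            QTLCall(s.strain_id, trait_id, sex, t, df, p, alpha_adj, p < alpha_adj)
        )
    return calls


def classify_trait(
    calls: Iterable[QTLCall], parental_diff_significant: bool = False
) -> TraitClassification:
    """Count significant CSSs and classify the trait.

    0 significant -> nonsignificant, 1 -> monogenic, 2 -> digenic,
    >= 3 -> multigenic.  Order-invariant.
    """
    calls = list(calls)
    if not calls:
        raise PreconditionError("classify_trait requires at least one QTL call")
    keys = {(c.trait_id, c.sex) for c in calls}
    if len(keys) > 1:
        raise PreconditionError(f"calls mix traits: {sorted(keys)}")
    (trait_id, sex), = keys
    k = sum(c.significant for c in calls)
    cls = TRAIT_CLASSES[min(k, 3)]
    return TraitClassification(trait_id, sex, k, cls, parental_diff_significant)


def parental_difference(
    panel: PanelDataset,
    trait_id: str,
    sex: str,
    alpha: float = 0.05,
    method: TestMethod = "welch",
) -> bool:
    """Does the host differ significantly from the donor for this trait?

    A single comparison, so ``alpha`` is uncorrected.  Traits failing
    this gate are excluded from effect-size normalization because the
    host-donor difference is their denominator.
    """
    host = panel.summary(panel.host_id, trait_id, sex)
    donor = panel.summary(panel.donor_id, trait_id, sex)
    if host is None or donor is None:
        raise PreconditionError(
            f"host/donor summary missing for ({trait_id}, {sex})"
        )
    _, _, p = welch_t(host, donor, method=method)
    return p < alpha
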