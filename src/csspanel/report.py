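"""Panel-level pipeline driver and summary tables.

``run_pipeline`` executes detection -> effects -> epistasis ->
directionality for every (trait, sex) in a panel; ``build_summary``
condenses the results into the shapes a panel survey reports: trait
classes, QTL counts and average effects for multigenic traits,
epistasis aggregates per subset, directionality percentages, and
parental-boundary counts.

The survey convention throughout: each CSS with a significant effect
counts as *at least one* QTL on its chromosome — a deliberate minimum
estimate of genetic complexity, since one substitution may carry many
linked loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .directionality import (
    BoundaryResult,
    DirectionalityCall,
    DirectionalitySummary,
    boundary_analysis,
    directionality_summary,
    make_call,
)
from .effects import EffectSize, compute_effects
from .epistasis import EpistasisSummary, epistasis_summary
from .errors import ParameterError, PreconditionError
from .panel_io import PanelDataset
from .qtl import (
    QTLCall,
    TraitClassification,
    classify_trait,
    detect_qtls,
    parental_difference,
)
from .rounding import percent, round_half_away

logger = logging.getLogger(__name__)

TraitKey = tuple[str, str]  # (trait_id, sex)


@dataclass
class PanelResults:
    """Raw per-stage outputs for one panel."""

    panel: PanelDataset
    calls: dict[TraitKey, list[QTLCall]]
    classifications: dict[TraitKey, TraitClassification]
    effects: dict[TraitKey, list[EffectSize]]
    qualifying: list[TraitKey]          # multigenic AND parental diff significant
    epistasis: EpistasisSummary
    direction_calls: list[DirectionalityCall]
    boundaries: dict[TraitKey, BoundaryResult]


def run_pipeline(
    panel: PanelDataset,
    alpha: float = 0.05,
    method: str = "welch",
    bonferroni: str = "per_trait",
) -> PanelResults:
    """Run every analysis stage on every (trait, sex) of the panel.

    Effect sizes, epistasis, directionality and boundaries are computed
    only for traits with a significant parental difference (the
    normalizing denominator); epistasis and directionality aggregates
    are further restricted to the multigenic subset among those.
    """
    calls: dict[TraitKey, list[QTLCall]] = {}
    classes: dict[TraitKey, TraitClassification] = {}
    effects: dict[TraitKey, list[EffectSize]] = {}
    dir_calls: list[DirectionalityCall] = []
    boundaries: dict[TraitKey, BoundaryResult] = {}

    for trait_id, sex in panel.traits:
        try:
            trait_calls = detect_qtls(
                panel, trait_id, sex, alpha=alpha, method=method, bonferroni=bonferroni
            )
        except PreconditionError as exc:
            logger.warning("skipping (%s, %s): %s", trait_id, sex, exc)
            continue
        if not trait_calls:
            continue
        key = (trait_id, sex)
        calls[key] = trait_calls
        donor = panel.summary(panel.donor_id, trait_id, sex)
        par_sig = (
            parental_difference(panel, trait_id, sex, alpha=alpha, method=method)
            if donor is not None and donor.sd_defined
            else False
        )
        classes[key] = classify_trait(trait_calls, parental_diff_significant=par_sig)
        if not par_sig:
            continue
        trait_effects = compute_effects(panel, trait_id, sex, trait_calls)
        effects[key] = trait_effects
        host = panel.summary(panel.host_id, trait_id, sex)
        sig_by_strain = {c.strain_id: c.significant for c in trait_calls}
        css_means = []
        for c in trait_calls:
            s = panel.summary(c.strain_id, trait_id, sex)
            css_means.append(s.mean)
            dir_calls.append(make_call(s, host, donor, sig_by_strain[c.strain_id]))
        boundaries[key] = boundary_analysis(
            css_means, host.mean, donor.mean, trait_id, sex
        )

    qualifying = [
        k
        for k, cls in classes.items()
        if cls.trait_class == "multigenic" and cls.parental_diff_significant
    ]
    epi = epistasis_summary({k: effects[k] for k in qualifying})
    qual_set = set(qualifying)
    dir_calls = [c for c in dir_calls if (c.trait_id, c.sex) in qual_set]
    return PanelResults(
        panel, calls, classes, effects, sorted(qualifying), epi, dir_calls,
        {k: b for k, b in boundaries.items() if k in qual_set},
    )


@dataclass
class PanelSummary:
    """Headline numbers for one panel, at table precision."""

    panel_id: str
    n_traits: int
    class_counts: dict[str, int]
    class_pct: dict[str, float]                 # integer precision
    n_qtls: int                                 # significant CSS-trait pairs, all traits
    n_multigenic_qtls: int                      # ... restricted to multigenic traits
    n_qualifying_traits: int                    # multigenic & parental-diff significant
    n_qualifying_qtls: int
    avg_qtls_per_trait: float | None            # over qualifying traits
    qtls_min_max: tuple[int, int] | None
    avg_effect_pct: float | None                # mean |NormUnit| of significant effects
    effect_min_max: tuple[float, float] | None
    epistasis: EpistasisSummary = None
    directionality: dict[str, DirectionalitySummary] = field(default_factory=dict)
    boundary_counts: dict[int, int] = field(default_factory=dict)


def build_summary(results: PanelResults) -> PanelSummary:
    """Aggregate pipeline outputs into the survey's headline statistics.

    Deterministic: identical results give identical summaries.
    """
    if not results.calls:
        raise PreconditionError("no QTL calls available: detection stage missing")
    classes = results.classifications
    n_traits = len(classes)
    counts = {c: 0 for c in ("multigenic", "digenic", "monogenic", "nonsignificant")}
    for cls in classes.values():
        counts[cls.trait_class] += 1
    pct = {c: percent(k, n_traits, 0) for c, k in counts.items()}

    n_qtls = sum(
        sum(c.significant for c in calls) for calls in results.calls.values()
    )
    n_multi = sum(
        classes[k].n_significant
        for k in results.calls
        if classes[k].trait_class == "multigenic"
    )

    qual = results.qualifying
    if qual:
        per_trait = [classes[k].n_significant for k in qual]
        n_qual_qtls = sum(per_trait)
        avg = n_qual_qtls / len(qual)
        qmin, qmax = min(per_trait), max(per_trait)
        sig_effects = [
            abs(e.norm_unit)
            for k in qual
            for e in results.effects[k]
            if e.significant
        ]
        avg_eff = sum(sig_effects) / len(sig_effects) if sig_effects else None
        eff_mm = (min(sig_effects), max(sig_effects)) if sig_effects else None
    else:
        n_qual_qtls, avg, qmin, qmax = 0, None, None, None
        avg_eff, eff_mm = None, None

    directionality = {
        subset: directionality_summary(results.direction_calls, subset=subset)
        for subset in ("significant", "nonsignificant", "all")
    }
    bcounts = {0: 0, 1: 0, 2: 0}
    for b in results.boundaries.values():
        bcounts[b.n_boundaries] += 1

    return PanelSummary(
        panel_id=results.panel.panel_id,
        n_traits=n_traits,
        class_counts=counts,
        class_pct=pct,
        n_qtls=n_qtls,
        n_multigenic_qtls=n_multi,
        n_qualifying_traits=len(qual),
        n_qualifying_qtls=n_qual_qtls,
        avg_qtls_per_trait=avg,
        qtls_min_max=(qmin, qmax) if qual else None,
        avg_effect_pct=avg_eff,
        effect_min_max=eff_mm,
        epistasis=results.epistasis,
        directionality=directionality,
        boundary_counts=bcounts,
    )


def extrapolate_qtl_count(
    avg_per_trait: float,
    chromosomes_represented: int,
    total_chromosomes: int = 22,
) -> float:
    """Project the average QTLs per trait to a complete panel.

    Incomplete panels (missing strains) undercount QTLs; assuming
    missing chromosomes behave like those surveyed, scale by
    total/represented.  The mouse genome has 19 autosomes + X + Y +
    mitochondria, hence the default 22 substitutable chromosomes.
    """
    if chromosomes_represented <= 0 or chromosomes_represented > total_chromosomes:
        raise ParameterError(
            f"chromosomes_represented must be in 1..{total_chromosomes}, "
            f"got {chromosomes_represented}"
        )
    return avg_per_trait * total_chromosomes / chromosomes_represented


def directionality_row(
    n_away: int, n_towards: int, n_more_extreme: int, decimals: int = 1
) -> str:
    """Render one directionality table row, percent (count) per cell."""
    total = n_away + n_towards
    if total == 0:
        raise ParameterError("directionality_row requires a positive total")
    cells = [
        (percent(n, total, decimals), n)
        for n in (n_away, n_towards, n_more_extreme)
    ]
    return "\t".join(f"{p:.{decimals}f}% ({n})" for p, n in cells)


def _fmt(x, nd=1):
    return "NA" if x is None else f"{x:.{nd}f}"


def render(summary: PanelSummary, fmt: str, out_dir) -> list[Path]:
    """Write summary tables as CSV files or a human-readable text report."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "text"):
        raise ParameterError(f"unknown format {fmt!r}; expected 'csv' or 'text'")
    paths: list[Path] = []
    if fmt == "csv":
        cls = pd.DataFrame(
            {
                "trait_class": list(summary.class_counts),
                "count": list(summary.class_counts.values()),
                "percent": [summary.class_pct[c] for c in summary.class_counts],
            }
        )
        p = out_dir / "trait_classes.csv"
        cls.to_csv(p, index=False)
        paths.append(p)

        epi = summary.epistasis
        epi_df = pd.DataFrame(
            {
                "subset": list(epi.percent_epistatic),
                "pct_epistatic": [
                    round_half_away(v, 1) for v in epi.percent_epistatic.values()
                ],
                "median_abs_sum": [
                    round_half_away(epi.median_abs_sum[s], 1)
                    for s in epi.percent_epistatic
                ],
            }
        )
        p = out_dir / "epistasis.csv"
        epi_df.to_csv(p, index=False)
        paths.append(p)

        d = summary.directionality
        dir_df = pd.DataFrame(
            {
                "subset": list(d),
                "n": [d[s].n for s in d],
                "pct_towards": [d[s].pct_towards for s in d],
                "pct_away": [d[s].pct_away for s in d],
                "pct_more_extreme": [d[s].pct_more_extreme for s in d],
            }
        )
        p = out_dir / "directionality.csv"
        dir_df.to_csv(p, index=False)
        paths.append(p)
        return paths

    lines = [
        f"Panel {summary.panel_id}: {summary.n_traits} traits analyzed",
        "",
        "Trait classes:",
    ]
    for c, k in summary.class_counts.items():
        lines.append(f"  {c:>15}: {summary.class_pct[c]:.0f}% ({k})")
    lines += [
        "",
        f"QTLs (significant CSS-trait pairs): {summary.n_qtls}",
        f"  in multigenic traits: {summary.n_multigenic_qtls}",
        f"Qualifying traits (multigenic, parents differ): "
        f"{summary.n_qualifying_traits}",
        f"  QTLs among qualifying traits: {summary.n_qualifying_qtls}",
        f"  average QTLs per trait: {_fmt(summary.avg_qtls_per_trait)}",
        f"  average |effect| (% of parental difference): "
        f"{_fmt(summary.avg_effect_pct)}",
        "",
        "Epistasis (cumulative-effect test):",
    ]
    for subset, v in summary.epistasis.percent_epistatic.items():
        lines.append(
            f"  {subset:>15}: {round_half_away(v, 0):.0f}% of traits epistatic, "
            f"median |sum| {round_half_away(summary.epistasis.median_abs_sum[subset], 1):.1f}%"
        )
    lines += ["", "Directionality (significant effects):"]
    ds = summary.directionality.get("significant")
    if ds is not None and not ds.empty:
        lines.append(
            f"  towards donor {ds.pct_towards:.1f}% ({ds.n_towards}), "
            f"away {ds.pct_away:.1f}% ({ds.n_away}), "
            f"more extreme than donor {ds.pct_more_extreme:.1f}% ({ds.n_more_extreme})"
        )
    lines += [
        "",
        f"Parental boundaries: both {summary.boundary_counts.get(2, 0)}, "
        f"one {summary.boundary_counts.get(1, 0)}, "
        f"none {summary.boundary_counts.get(0, 0)}",
    ]
    p = out_dir / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    return [p]
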