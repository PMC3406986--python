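"""Reading, validating and summarizing consomic-panel phenotype tables.

A chromosome substitution strain (CSS) panel consists of a *host* inbred
strain, a *donor* inbred strain, and a set of CSS/congenic lines each
carrying one donor chromosome (or chromosome segment) on the host
background.  Phenotypes arrive as a tidy CSV with one row per animal per
trait (``strain,trait,sex,animal,value``); the panel layout arrives as a
JSON config naming the host, the donor and the CSS lines.

Every downstream statistic consumes per-strain :class:`TraitSummary`
objects (mean, SD, n, SEM), never raw animal records, so this module is
the only place measurements are touched.  Sexes are never pooled: each
(trait, sex) pair is an independent analysis unit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("strain", "trait", "sex", "animal", "value")

Role = Literal["host", "donor", "css"]
Segment = Literal["whole", "centromeric", "telomeric", "congenic"]


@dataclass(frozen=True)
class StrainRecord:
    """One strain in the panel layout.

    ``chromosome`` is a label like ``"11"`` or ``"X"`` (empty for the
    parental strains); ``segment`` distinguishes whole-chromosome
    consomics from congenic lines carrying only the centromeric or
    telomeric part of a chromosome.  Congenic lines are distinct test
    units — no chromosome-level aggregation happens anywhere.
    """

    strain_id: str
    role: Role
    chromosome: str = ""
    segment: Segment = "whole"


@dataclass(frozen=True)
class Measurement:
    """One animal's value for one trait."""

    strain_id: str
    trait_id: str
    sex: str
    animal_id: str
    value: float


@dataclass(frozen=True)
class TraitSummary:
    """Per-strain, per-trait summary statistics.

    ``mean`` is the quantity the effect-size formulas call T_host, T_CSS
    or T_donor depending on the strain's role.  ``sd`` uses the sample
    (n-1) denominator and is NaN for n = 1 groups, which downstream
    tests refuse.
    """

    strain_id: str
    trait_id: str
    sex: str
    mean: float
    sd: float
    n: int
    sem: float

    @property
    def sd_defined(self) -> bool:
        return self.n >= 2 and not math.isnan(self.sd)


class CSSLineConfig(BaseModel):
    strain: str
    chromosome: str
    segment: Segment = "whole"

    @field_validator("chromosome")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("css lines must name a chromosome")
        return v


class PanelConfig(BaseModel):
    """Schema for the panel-layout JSON."""

    panel_id: str
    host: str
    donor: str
    css: list[CSSLineConfig] = Field(min_length=1)

    def strain_records(self) -> list[StrainRecord]:
        recs = [
            StrainRecord(self.host, "host"),
            StrainRecord(self.donor, "donor"),
        ]
        recs += [
            StrainRecord(c.strain, "css", c.chromosome, c.segment)
            for c in self.css
        ]
        ids = [r.strain_id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate strain ids in config: {ids}")
        return recs


@dataclass
class PanelDataset:
    """A validated panel: strain layout plus per-(strain, trait, sex)
    summaries ready for QTL testing."""

    panel_id: str
    strains: list[StrainRecord]
    summaries: dict[tuple[str, str, str], TraitSummary]
    traits: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traits:
            self.traits = sorted({(s.trait_id, s.sex) for s in self.summaries.values()})
        known = {s.strain_id for s in self.strains}
        stray = {k[0] for k in self.summaries} - known
        if stray:
            raise ValidationError(f"summaries reference unknown strains: {sorted(stray)}")

    @property
    def host_id(self) -> str:
        return next(s.strain_id for s in self.strains if s.role == "host")

    @property
    def donor_id(self) -> str:
        return next(s.strain_id for s in self.strains if s.role == "donor")

    @property
    def css_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains if s.role == "css"]

    def summary(self, strain_id: str, trait_id: str, sex: str) -> TraitSummary | None:
        return self.summaries.get((strain_id, trait_id, sex))

    def strain_means(self, trait_id: str, sex: str) -> dict[str, float]:
        """Means of every strain with data for (trait, sex), keyed by strain."""
        return {
            k[0]: s.mean
            for k, s in self.summaries.items()
            if k[1] == trait_id and k[2] == sex
        }


def summarize(measurements: Iterable[Measurement]) -> list[TraitSummary]:
    """Mean, sample SD, n and SEM per (strain, trait, sex) group.

    Deterministic and permutation-invariant.  Singleton groups are kept
    with ``sd = sem = NaN`` so the refusal happens, loudly, at test time
    rather than silently here.
    """
    groups: dict[tuple[str, str, str], list[float]] = {}
    for m in measurements:
        groups.setdefault((m.strain_id, m.trait_id, m.sex), []).append(m.value)
    out = []
    for (strain, trait, sex), values in sorted(groups.items()):
        arr = np.sort(np.asarray(values, dtype=float))  # permutation-invariant
        n = arr.size
        if n == 0:
            logger.warning("empty group (%s, %s, %s) skipped", strain, trait, sex)
            continue
        mean = float(arr.mean())
        if n >= 2:
            sd = float(arr.std(ddof=1))
            sem = sd / math.sqrt(n)
        else:
            sd = sem = float("nan")
        out.append(TraitSummary(strain, trait, sex, mean, sd, n, sem))
    return out


def iqr_filter(
    measurements: Sequence[Measurement],
    k: float = 3.0,
    enabled: bool = True,
) -> list[Measurement]:
    """Remove values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` within each
    (strain, trait, sex) group.

    Disabled by default in the pipeline (small per-strain samples of
    4-12 animals make outlier trimming risky); quartiles use linear
    interpolation between order statistics when enabled.
    """
    if not enabled:
        return list(measurements)
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    groups: dict[tuple[str, str, str], list[Measurement]] = {}
    for m in measurements:
        groups.setdefault((m.strain_id, m.trait_id, m.sex), []).append(m)
    kept: list[Measurement] = []
    for key, ms in groups.items():
        if len(ms) < 4:
            raise ParameterError(
                f"group {key} has {len(ms)} values; >= 4 required for IQR filtering"
            )
        values = np.array([m.value for m in ms])
        q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quartiles
        iqr = q3 - q1
        if iqr == 0.0:
            # degenerate spread (a majority of identical values): any finite k
            # would delete every non-modal value, so leave the group alone
            kept.extend(ms)
            continue
        lo, hi = q1 - k * iqr, q3 + k * iqr
        removed = [m for m in ms if not (lo <= m.value <= hi)]
        if removed:
            logger.info("iqr_filter removed %d value(s) from %s", len(removed), key)
        kept.extend(m for m in ms if lo <= m.value <= hi)
    return kept


def read_measurements(phenotype_path) -> list[Measurement]:
    """Parse the tidy phenotype CSV into Measurement records."""
    df = pd.read_csv(phenotype_path, dtype={"strain": str, "trait": str,
                                            "sex": str, "animal": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"phenotype file missing required column(s): {', '.join(missing)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[~np.isfinite(values)]
    if len(bad):
        raise ValidationError(
            f"non-finite or non-numeric values at rows {list(bad[:5])}"
        )
    dup = df.duplicated(subset=["strain", "trait", "sex", "animal"])
    if dup.any():
        rows = df.loc[dup, ["strain", "trait", "sex", "animal"]].head()
        raise ValidationError(f"duplicate animal records:\n{rows}")
    return [
        Measurement(r.strain, r.trait, r.sex, r.animal, float(v))
        for r, v in zip(df.itertuples(index=False), values)
    ]


def read_panel(phenotype_path, config_path, iqr_k: float | None = None) -> PanelDataset:
    """Read and validate a panel: phenotype CSV + layout JSON -> PanelDataset.

    ``iqr_k`` enables the optional IQR outlier filter (default: off).
    Traits with no host-strain data are rejected because every statistic
    is anchored on the host mean.
    """
    with open(config_path) as fh:
        config = PanelConfig.model_validate(json.load(fh))
    strains = config.strain_records()
    known = {s.strain_id for s in strains}

    measurements = read_measurements(phenotype_path)
    unknown = sorted({m.strain_id for m in measurements} - known)
    if unknown:
        raise ValidationError(
            f"phenotype file contains strain(s) absent from config: {unknown}"
        )
    if iqr_k is not None:
        measurements = iqr_filter(measurements, k=iqr_k)

    summaries = {(s.strain_id, s.trait_id, s.sex): s for s in summarize(measurements)}
    host = config.host
    traits = sorted({(s.trait_id, s.sex) for s in summaries.values()})
    hostless = [t for t in traits if (host, *t) not in summaries]
    if hostless:
        raise ValidationError(
            f"trait(s) lack host-strain data and cannot be analyzed: {hostless}"
        )
    return PanelDataset(config.panel_id, strains, summaries, traits)


def write_measurements(measurements: Iterable[Measurement], path) -> None:
    """Write records back to the declared CSV dialect (round-trip safe)."""
    df = pd.DataFrame(
        [(m.strain_id, m.trait_id, m.sex, m.animal_id, m.value) for m in measurements],
        columns=list(PHENOTYPE_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")
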