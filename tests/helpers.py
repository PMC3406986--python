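"""Shared construction helpers for the test suite."""

from __future__ import annotations

import math

from csspanel import PanelDataset, StrainRecord, TraitSummary


def ts(
    strain: str = "S",
    mean: float = 0.0,
    sd: float = 1.0,
    n: int = 10,
    trait: str = "t1",
    sex: str = "M",
) -> TraitSummary:
    return TraitSummary(strain, trait, sex, mean, sd, n, sd / math.sqrt(n))


def panel_from_means(
    css_means: dict[str, float],
    host_mean: float = 0.0,
    donor_mean: float = 1.0,
    sd: float = 1.0,
    n: int = 10,
    trait: str = "t1",
    sex: str = "M",
) -> PanelDataset:
    """A one-trait panel built directly from strain means (shared sd, n)."""
    strains = [StrainRecord("HOST", "host"), StrainRecord("DONOR", "donor")]
    strains += [
        StrainRecord(s, "css", chromosome=str(i + 1))
        for i, s in enumerate(css_means)
    ]
    summaries = {}
    for s, m in {"HOST": host_mean, "DONOR": donor_mean, **css_means}.items():
        summaries[(s, trait, sex)] = ts(s, m, sd, n, trait, sex)
    return PanelDataset("test", strains, summaries)
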