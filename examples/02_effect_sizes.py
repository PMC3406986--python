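"""Normalized effect sizes for detected QTLs.

NormUnit expresses each CSS shift as a percent of the host-donor
difference (0% = at the host, 100% = at the donor); Hi_Low uses the
full range of strain means instead.  The SEM of NormUnit is propagated
from the three strain means by the delta method.
"""

from csspanel import (SynthConfig, average_effect, compute_effects,
                      detect_qtls, generate_panel)

cfg = SynthConfig(n_css=20, n_per_strain=10, sigma=0.2, n_nonzero=5,
                  cumulative_target=250.0, seed=11)
panel, truth = generate_panel(cfg)
calls = detect_qtls(panel, "trait001", "pooled")
effects = compute_effects(panel, "trait001", "pooled", calls)

print(f"{'strain':8} {'NormUnit':>9} {'+/-SEM':>7} {'Hi_Low':>8}  significant")
for e in sorted(effects, key=lambda e: -abs(e.norm_unit))[:8]:
    print(f"{e.strain_id:8} {e.norm_unit:8.1f}% {e.sem_norm_unit:6.1f} "
          f"{e.hi_low:7.1f}%  {e.significant}")

avg = average_effect(effects, significant_only=True)
print(f"\naverage |effect| among significant CSSs: {avg:.1f}% "
      f"of the parental difference")
# Values above 100% mean a single chromosome shifts the trait further
# than the entire gap between the parental strains.
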