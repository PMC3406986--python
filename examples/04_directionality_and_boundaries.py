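"""Directionality of QTL effects and parental boundaries.

For each CSS the ratio r = (T_host - T_CSS)/(T_host - T_donor) says
whether the substitution moved the trait towards the donor (r > 0),
away from it (r < 0), or beyond the donor itself (r > 1).  The panel is
generated with a 90% bias toward the donor, which the summary recovers.
"""

from csspanel import (SynthConfig, boundary_analysis, detect_qtls,
                      directionality_summary, extrapolate_qtl_count,
                      generate_panel, make_call, round_half_away)

cfg = SynthConfig(n_css=20, n_nonzero=8, towards_bias=0.9,
                  cumulative_target=300.0, sigma=0.1, n_per_strain=20, seed=2)
panel, truth = generate_panel(cfg)
calls = detect_qtls(panel, "trait001", "pooled")
host = panel.summary("HOST", "trait001", "pooled")
donor = panel.summary("DONOR", "trait001", "pooled")

dcalls = [
    make_call(panel.summary(c.strain_id, "trait001", "pooled"), host, donor,
              c.significant)
    for c in calls
]
s = directionality_summary(dcalls, "significant")
print(f"significant CSSs: {s.n}  towards donor {s.pct_towards}%  "
      f"away {s.pct_away}%  more extreme than donor {s.pct_more_extreme}%")

css_means = [panel.summary(c.strain_id, "trait001", "pooled").mean for c in calls]
b = boundary_analysis(css_means, host.mean, donor.mean)
print(f"parental means bound the CSS range: upper={b.upper_parental} "
      f"lower={b.lower_parental} ({b.n_boundaries} boundaries)")

# projecting QTL counts from an incomplete panel to a complete one:
proj = extrapolate_qtl_count(5.5, chromosomes_represented=18, total_chromosomes=22)
print(f"5.5 QTLs/trait over 18 of 22 chromosomes -> "
      f"{round_half_away(proj, 1)} for a complete panel")
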