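"""Recompute group summaries from the packaged per-participant tables.

The package ships the published per-participant session metrics of both
study groups (18 adaptive-arm and 18 static-arm participants, five metrics
per state).  Summaries use the population (divisor-n) SD convention, which
is what reproduces the published summary rows.
"""

from vretsim import fixture_frames, load_fixture_tables, one_way_anova, summarize

tables = fixture_frames()
for group, df in tables.items():
    for prefix, label in (("state1", "LOW"), ("state2", "HIGH")):
        s = summarize(df[f"{prefix}_maintenance"])
        print(
            f"{group:>12} {label:>4}: maintenance mean {s.mean:5.2f} s "
            f"({s.occupancy_percent:5.2f}%), SD {s.sd:5.2f} s"
        )

r = one_way_anova(
    tables["experimental"]["state1_maintenance"],
    tables["control"]["state1_maintenance"],
)
print(
    f"\nLOW-state maintenance, experimental vs control: "
    f"F({r.df_between},{r.df_within}) = {r.F:.2f}, p = {r.p:.2g}"
)
print(f"long-form records: {len(load_fixture_tables())} (18 x 2 groups x 2 states)")
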