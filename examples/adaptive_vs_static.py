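"""Paired adaptive-vs-static comparison on a small synthetic cohort.

Every participant is run once under biofeedback control and once under the
fixed pre-recorded schedule with identical seeds; occupancy is the mean
fraction of each active-state minute spent inside the desired band.
A full-size run uses n = 18 (one study group); n = 8 here keeps the
example quick.
"""

from vretsim import SessionConfig, StateLabel, make_cohort, run_cohort

result = run_cohort(make_cohort(8, seed=1), SessionConfig(seed=1))

for state in (StateLabel.LOW, StateLabel.HIGH):
    occ_a = result.occupancy("adaptive", state)
    occ_s = result.occupancy("static", state)
    a = result.anova[state]
    print(
        f"{state:>4}: adaptive {occ_a:5.2f}%  static {occ_s:5.2f}%  "
        f"F({a.df_between},{a.df_within}) = {a.F:.2f}, p = {a.p:.3g}"
    )

print(
    "\nHigher adaptive occupancy means the feedback loop held participants\n"
    "inside the clinician-chosen anxiety band longer than the one-size-fits-\n"
    "all schedule, which over- or under-stimulates non-median participants.\n"
    "At this reduced size a single seed is noisy; the full comparison\n"
    "averages five seeds at n = 18."
)
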