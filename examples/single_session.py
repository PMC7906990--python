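"""Run one adaptive closed-loop session against a synthetic participant.

The session acquires the Relaxed EDA baseline during a one-minute
stimulus-free rest, then runs LOW / REST / HIGH / REST minutes with the
controller recomputing the correction at every 100 Hz EDA sample.
"""

from vretsim import ParticipantProfile, SessionConfig, run_session

profile = ParticipantProfile(sensitivity=0.8, latency=3.2, seed=11)
log = run_session(profile, SessionConfig(mode="adaptive", seed=4))

print(f"relaxed EDA value : {log.baseline.relaxed_value:.4f} (arbitrary units)")
print(f"baseline converged: {log.baseline.converged_at:.2f} s")
print(f"spiders spawned   : {log.spiders_spawned}, exited: {log.spiders_exited}")
for state, m in log.metrics.items():
    print(
        f"{state:>4}: maintenance {m.maintenance:5.2f} s "
        f"({100 * m.maintenance / 60:5.1f}% of the minute), "
        f"less-anxious {m.less_anxious:5.2f} s, more-anxious {m.more_anxious:5.2f} s, "
        f"entrance {m.entrance_time:.2f} s, recovery {m.recovery_duration} s"
    )
print(
    "\nMaintenance is the time normalized EDA stayed inside the desired band\n"
    "(0.7-0.8 for LOW, 0.4-0.5 for HIGH); entrance is the time to first\n"
    "reach it, recovery the time to re-enter the rest band (>= 0.92) in the\n"
    "following rest minute."
)
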