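"""Generate a synthetic 4-choice odd-ball session and inspect it.

Each selection flashes the four direction stimuli twice in random order;
the attended one carries an ERP-like deflection (P300 surrogate) over
the posterior channels.
"""
from p300kit import SessionSpec, event_counts, generate_session

spec = SessionSpec(paradigm="four_choice", n_repetitions=2, n_selections=10,
                   snr=2.0, seed=42)
recording, schedule, truth = generate_session(spec)

n_target, n_nontarget = event_counts(schedule, truth)
print(f"recording: {recording.n_channels} channels x {recording.n_samples} samples "
      f"@ {recording.fs:.0f} Sa/s")
print(f"events: {len(schedule)} flashes, {n_target} targets, {n_nontarget} non-targets")
print(f"attended directions per selection: {truth.attended.tolist()}")
# exactly one flash in four is a target, so the ratio is always 1:3
assert n_nontarget == 3 * n_target
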