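"""The defensive cognitive contagion (DCC) adoption-probability matrix.

Each entry is the probability an agent holding the row belief adopts an
incoming message carrying the column belief: near-certain within one level,
a coin flip at distance two, and effectively zero beyond distance three —
dissonance protects entrenched beliefs while repeated near beliefs get in.
"""

from podsim import BeliefSpace, dcc_matrix_frame, preset

space = BeliefSpace()  # 7 levels: 0 strong disbelief ... 6 strong belief
frame = dcc_matrix_frame(space, preset("dcc"))

print("Adoption probability by (holder belief, message belief):")
print(frame.round(3).to_string())
print()
print(f"distance 1 -> {frame.iloc[6, 5]:.3f}: a 'strong believer' almost surely")
print("accepts a 'believe' message, while")
print(f"distance 6 -> {frame.iloc[6, 0]:.2e}: a polar-opposite message is rejected.")
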