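"""Classify consciousness from a brainwave trace with the 10% energy rule.

Generates a synthetic post-stun EEG whose post-stun energy is 5% of the
pre-stun level, computes the windowed energy report and prints the verdict.
"""

from stunwatch.eeg import analyze_trace, classify_brainwave, display_round
from stunwatch.synthetic import generate_eeg

# 40 s trace at 100 Hz: pre-stun RMS 5 mV, post-stun energy 5% of pre-stun
trace = generate_eeg(pre_level=5.0, post_ratio=0.05, seed=42)

report = analyze_trace(trace)  # pre window [0,10) s; P1/P2/P3 = 10-20/20-30/30-40 s
verdict = classify_brainwave(report)

print(f"pre-stun energy       : {report.e_pre:.2f} mV^2")
print(f"criterion (10% rule)  : {display_round(report.criterion):.2f} mV^2")
print(f"P1, P2, P3 energies   : {report.e_p1:.3f}, {report.e_p2:.3f}, {report.e_p3:.3f} mV^2")
print(f"classification        : {verdict}")
# The bird counts as unconscious only if all three post-stun windows sit at
# or below 10% of the pre-stun energy.
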