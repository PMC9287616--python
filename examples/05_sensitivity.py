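"""Global sensitivity: which parameters drive phagocytosis inhibition.

Latin-hypercube samples the phagocytosis-submodule parameters over a
3-fold range and reports partial rank correlation coefficients (PRCC)
of the combined checkpoint inhibition H_Mac_C.
"""

from tnbcqsp.sensitivity import sensitivity_phagocytosis

result = sensitivity_phagocytosis(n=300, seed=2)
frame = result.to_frame()
for row in frame.itertuples(index=False):
    bar = "#" * int(abs(row.prcc) * 40)
    print(f"{row.parameter:>18s} {row.prcc:+.2f} {bar}")
# positive PRCC: raising the parameter strengthens checkpoint inhibition
# (PD-1/SIRPa densities); negative: weakens it (half-max constants).
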