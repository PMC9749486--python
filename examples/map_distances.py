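"""Kosambi map arithmetic and the inbred-line recombination correction.

Converts a recombination fraction to centimorgans and back, and shows how
the recombinant fraction observed among fully selfed RILs overstates the
per-meiosis fraction (repeated selfing gives every interval extra chances
to recombine).
"""

from bsaqtl import kosambi_cm, kosambi_r, r_from_ril_R, ril_R_from_r

r = 0.10
d = kosambi_cm(r)
print(f"per-meiosis recombination fraction r = {r}")
print(f"Kosambi map distance               = {d:.3f} cM")
print(f"back-converted fraction            = {kosambi_r(d):.6f}")

R = ril_R_from_r(r)  # Haldane-Waddington: 2r / (1 + 2r)
print(f"\nrecombinant fraction among RILs    = {R:.4f}  (inflated from {r})")
print(f"recovered per-meiosis fraction     = {r_from_ril_R(R):.4f}")
print(f"after only five selfings (F6)      = {ril_R_from_r(r, generations=6):.4f}")

# A fraction of 1/6 among RILs therefore maps to ~10.1 cM, not ~18 cM:
print(f"\nnaive  : kosambi_cm(1/6)           = {kosambi_cm(1 / 6):.3f} cM")
print(f"correct: kosambi_cm(r_from_R(1/6)) = {kosambi_cm(r_from_ril_R(1 / 6)):.3f} cM")
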