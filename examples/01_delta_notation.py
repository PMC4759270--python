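"""Atom fraction <-> delta-notation conversions against AIR and VCDT.

A NanoSIMS measurement yields the minor-isotope atom fraction
f = minor/(minor+major); geochemists usually report the same composition
as a per-mil deviation from a standard.
"""

from nanosip import AIR_N, VCDT_S, atom_fraction, counting_se, delta_from_fraction, fraction_from_delta

# A pixel (or ROI) with 37 15N counts against 9963 14N counts:
f = atom_fraction(37, 9963)
se = counting_se(37, 9963)
print(f"atom fraction      : {f:.6f}  ({100 * f:.4f} atom%)")
print(f"counting SE        : {se:.2e}  (shot-noise floor of the ratio)")

# The natural-abundance cross-check: 0.3751 atom% 15N is +24.0 permil vs AIR
delta = delta_from_fraction(0.003751, AIR_N)
print(f"0.3751 atom% 15N   : {delta:+.1f} permil vs AIR (natural specimens)")

# The conversion is exactly invertible
back = fraction_from_delta(delta, AIR_N)
print(f"inverted           : {100 * back:.4f} atom% (round trip)")

# Sulfur uses VCDT under the two-isotope (32S/34S) model
d34 = delta_from_fraction(0.0442, VCDT_S)
print(f"4.42 atom% 34S     : {d34:+.1f} permil vs VCDT")
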