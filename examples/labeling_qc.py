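"""Dye-incorporation QC for labeled RNA probes.

Computes the dye density (pmol Cy5 per ug RNA) and the base:dye ratio
(nucleotides per attached dye) from spectrophotometer readings, and checks
the 700-1200 nt/dye acceptance window.
"""

from rbpscreen import LabelingMeasurement, base_dye_ratio, dye_density, labeling_pass

# A labeling reaction resuspended in 16 uL: A260 = 0.843, Cy5 A649 = 0.234
m = LabelingMeasurement(a260=0.9, a_dye=0.234, mass_ug=5.0, volume_uL=16.0)
print(f"dye density = {dye_density(m):.4f} pmol dye per ug RNA")
# ~3 pmol/ug is the protocol's optimization target

m2 = LabelingMeasurement(a260=0.843, a_dye=0.03, mass_ug=5.0, volume_uL=16.0)
ratio = base_dye_ratio(m2)
print(f"base:dye    = {ratio:.1f} nucleotides per dye")
print(f"QC pass     = {labeling_pass(ratio)}  (window 700-1200 nt/dye, inclusive)")
# One dye per ~850 nt: dense enough to detect binding, sparse enough not to
# perturb RNA structure.
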