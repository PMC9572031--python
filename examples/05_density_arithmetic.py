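"""Density arithmetic on the published median cell counts.

The whole-image analyzed area after border cropping is 33.66 mm²; dividing a
group's median cell count by it gives the group's density in cells/mm².
These are the headline numbers of the analysis.
"""

from mlcquant import DEFAULT_ANALYZED_AREA_MM2, mlc_density

counts = {
    "control eyes": 220.50,
    "acute RVO eyes": 388.00,
    "chronic RVO eyes": 422.00,
    "all RVO eyes": 391.00,
}
for name, count in counts.items():
    d = mlc_density(count, DEFAULT_ANALYZED_AREA_MM2)
    print(f"{name:>17}: median count {count:6.1f} / {DEFAULT_ANALYZED_AREA_MM2} mm² "
          f"= {d:5.2f} cells/mm²")
print(f"\nnon-edematous area = {DEFAULT_ANALYZED_AREA_MM2} − 9.14 "
      f"= {DEFAULT_ANALYZED_AREA_MM2 - 9.14:.2f} mm²")
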