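"""Aqueous phthalate speciation across the envelope pH range.

Phthalic acid is diprotic (pKa 2.95 and 4.9); below pH ~5 a large share of
dissolved phthalate is protonated (HL-, H2L), which matters because the
surface reaction consumes the free dianion L2- plus two protons.
"""

from ionex import speciate
from ionex.scenarios import PHTHALATE_AQUEOUS

print(f"{'pH':>4}  {'L2-':>6}  {'HL-':>6}  {'H2L':>6}  {'NaL-':>6}")
for ph in (2.5, 3.5, 4.9, 6.0, 8.0, 10.0):
    res = speciate({"L": 1e-3, "Na": 5e-4}, ph, PHTHALATE_AQUEOUS)
    f = res.fractions["L"]
    print(f"{ph:>4.1f}  {f['L']:>6.3f}  {f.get('HL', 0):>6.3f}"
          f"  {f.get('H2L', 0):>6.3f}  {f.get('NaL', 0):>6.4f}")

print("\nFractions of total phthalate; they sum to 1 at every pH. At pH 4.9")
print("(= pKa2) HL- and L2- are equal; the NaL- ion pair stays negligible.")
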