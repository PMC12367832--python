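"""Build the potency x severity matrix for the chloroaniline assay panel.

Each of the 19 active assays is banded by AC50 (High < 0.1 µM, Medium
0.1-10 µM, Low > 10 µM) and rated for severity from its ToxCast-style
descriptors; the matrix is then mapped to a bioactivity level of concern
under the three selectable rule sets.
"""

from namloc import Level, MAX_RED, MIN_RED, POT_ONLY, FrameworkConfig
from namloc.bioactivity import SeverityLexicon, build_matrix, matrix_to_loc
from namloc.fixtures import fixture_chloroaniline_assays

cfg = FrameworkConfig()
lexicon = SeverityLexicon.default()
matrix = build_matrix(fixture_chloroaniline_assays(), cfg.potency_cutoffs, lexicon)

print("cell counts (rows: potency, columns: severity):")
print("        sev H  sev M  sev L")
for pot in "HML":
    row = [matrix.counts[(Level(pot), Level(sev))] for sev in "HML"]
    print(f"  pot {pot}  {row[0]:4d}  {row[1]:5d}  {row[2]:5d}")
print(f"  inactive: {matrix.n_inactive} of {matrix.n_assays} assays")

for ruleset in (MIN_RED, MAX_RED, POT_ONLY):
    print(f"level of concern under {ruleset.name:8s}: "
          f"{matrix_to_loc(matrix, ruleset).level.value}")
print("min_red requires high potency AND high severity for a High call;")
print("max_red promotes more cells; pot_only ignores severity entirely.")
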