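"""Generate a seeded synthetic population and recover its ground truth.

Builds 30 chemicals with prescribed bioactivity (TD) and bioavailability
(TK) bands — AC50s and solved clearance parameters sit two-fold clear of
every cutoff — runs the full pipeline and checks the recovered overall
category against the intended one.
"""

from namloc import FrameworkConfig
from namloc.overall import combine
from namloc.pipeline import classify_chemical
from namloc.synthetic import SyntheticProfile, generate_assay_panel, generate_tk_inputs

cfg = FrameworkConfig()
profile = SyntheticProfile(n_chemicals=30, panel_size=8, seed=7)
assays, td_truth = generate_assay_panel(profile, cfg)
tks, tk_truth = generate_tk_inputs(profile, cfg)

by_chem = {}
for a in assays:
    by_chem.setdefault(a.chem_id, []).append(a)

recovered = 0
for i, chem in enumerate(profile.chem_ids()):
    res = classify_chemical(chem_id=chem, config=cfg, assays=by_chem[chem], pk=tks[i])
    want = combine(profile.td_of(i), profile.tk_of(i), cfg.epaa_matrix)
    ok = res.overall_result.overall.level is want
    recovered += ok
    if i < 5:
        print(f"{chem}: intended TD={profile.td_of(i).value} "
              f"TK={profile.tk_of(i).value} -> overall {want.value}; "
              f"pipeline gave {res.overall_result.overall.level.value} "
              f"({'ok' if ok else 'MISS'})")

print(f"...\nrecovered {recovered}/{profile.n_chemicals} intended categories")
print("Clear-cut profiles recover exactly by construction; real assay panels")
print("carry boundary-adjacent AC50s and coverage gaps that this does not test.")
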