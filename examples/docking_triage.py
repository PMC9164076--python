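"""Grid-box configuration and docking-score triage for the GRIN2B receptor."""

from netpharm import best_binder, classify_binders, make_grid_config
from netpharm.datasets import GRIN2B_GRID_BOX, docking_records

print(make_grid_config(GRIN2B_GRID_BOX, "grin2b_7eu8.pdbqt", "loratadine.pdbqt"))
# A Vina-style engine consumes this text directly: 40 Å cube centered on the
# GRIN2B active site, 8 exhaustiveness, 10 poses, 4 kcal/mol energy range.

records = docking_records()
report = classify_binders(records, threshold=-6.0)
print(f"{'ligand':15s} energy(kcal/mol)  active")
for record in report.ranking:
    active = record.binding_energy < report.threshold
    print(f"{record.ligand:15s} {record.binding_energy:8.1f}          {active}")
best = best_binder(records)
print(f"\n{len(report.actives)} of {len(records)} ligands bind stably (< -6.0 kcal/mol);")
print(f"best binder: {best.ligand} at {best.binding_energy} kcal/mol")
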