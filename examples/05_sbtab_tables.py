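"""Read and write annotated experimental-data tables (SBtab dialect).

Writes a small metabolite-concentration table with ChEBI annotations,
reads it back, and converts it into the ConcentrationSet the assembly
step consumes.
"""
import tempfile

import kindraft as kd

table = kd.DataTable(
    table_type="Quantity",
    columns=["Name", "Value", "Unit", "Identifiers:chebi"],
    rows=[
        {"Name": "glucose", "Value": 0.0556, "Unit": "mM",
         "Identifiers:chebi": "CHEBI:17234"},
        {"Name": "pyruvate", "Value": 0.9, "Unit": "mM",
         "Identifiers:chebi": "CHEBI:15361"},
    ],
)

with tempfile.NamedTemporaryFile("r", suffix=".tsv") as fh:
    kd.write_sbtab(table, fh.name)
    print("on disk:")
    print(open(fh.name).read())
    back = kd.read_sbtab(fh.name)

conc = kd.table_to_concentrations(back)
print("as concentrations (mM):", conc.values)
# The round trip is lossless, and the Quantity table maps directly onto
# the initial-concentration input of the draft-model assembly step.
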