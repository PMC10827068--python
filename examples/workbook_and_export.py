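"""Round-trip a model through the two-sheet workbook format and export it
for Cytoscape.

Models live in spreadsheets with a "species" sheet (ID, name, Yinit, Ymax,
tau) and a "reactions" sheet (ID, Rule, Weight, n, EC50); this script
writes one, reads it back, and emits a SIF edge list plus edge attributes.
"""

import tempfile
from pathlib import Path

from hillnet import (
    build_cardiacdevnet,
    export_cytoscape_edges,
    read_model_workbook,
    write_model_workbook,
)

model = build_cardiacdevnet()
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cardiacDevNet.xlsx"
    write_model_workbook(model, path)
    reread = read_model_workbook(path)
    print(f"round-trip lossless: {reread == model}")
    sif, tsv = export_cytoscape_edges(reread, Path(tmp) / "cardiacDevNet")
    print(f"\n{sif.name}:")
    print(sif.read_text())
print("Each SIF line is one signed regulatory edge; pseudo-nodes named"
      " INPUT_<species> stand for environmental stimuli so Cytoscape can"
      " draw input reactions too.")
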