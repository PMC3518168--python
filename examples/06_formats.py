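"""Matrix I/O: NEXUS, TNT xread and CSV round-trips.

Writes the packaged matrix in all three dialects into a temporary
directory and reads each back, confirming the cells (including the
distinction between missing '?' and inapplicable '-') survive.
"""

import tempfile
from pathlib import Path

import ommclad as oc
from ommclad import read_matrix, write_matrix

matrix = oc.ommatidae_matrix()
with tempfile.TemporaryDirectory() as tmp:
    for dialect, name in [("nexus", "m.nex"), ("tnt", "m.tnt"),
                          ("csv", "m.csv")]:
        path = Path(tmp) / name
        write_matrix(matrix, path, dialect)
        again = read_matrix(path, dialect)
        print(f"{dialect:<6} round-trip equal: {again == matrix} "
              f"({path.stat().st_size} bytes)")

missing = (matrix.cells == oc.MISSING).mean()
inap = (matrix.cells == oc.INAPPLICABLE).mean()
print(f"missing cells: {missing:.1%}, inapplicable cells: {inap:.1%}")
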