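"""Convert PRMTOP force-field parameters to the Gaussian-style MM block.

Writes a synthetic topology to disk, reads it back, inverts the diagonal
Lennard-Jones A/B coefficients to per-type (R, eps), and prints the five
record kinds (VDW, HrmStr1, HrmBnd1, AmbTrs, ImpTrs).
"""

import tempfile
from pathlib import Path

from energysplit import (
    FixtureSpec,
    make_fixture,
    params_from_prmtop,
    write_gaussian_mm_block,
)
from energysplit.fixtures import write_prmtop
from energysplit.prmtop import PrmtopFile

system = make_fixture(FixtureSpec("chain", 8))
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "chain8.prmtop"
    write_prmtop(system, path)
    params = params_from_prmtop(PrmtopFile.read(path))

print(write_gaussian_mm_block(params))
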