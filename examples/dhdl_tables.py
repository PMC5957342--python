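"""Ingesting externally produced dH/dlambda tables.

Free-energy derivatives are often exported by MD engines as two-column
(time, dH/dlambda) text with '#'/'@' comment headers.  This example
writes three such tables for a linear profile, reads them back, and
integrates them — the path one would use to apply the TI estimator to
derivative dumps produced elsewhere.
"""

import numpy as np
from pathlib import Path
import tempfile

from densassign import DerivativeSeries, integrate_ti
from densassign.fileio import read_dhdl_table, write_dhdl_table

workdir = Path(tempfile.mkdtemp(prefix="dhdl_"))
rng = np.random.default_rng(0)

# emulate an engine dump: <dH/dl> = 2 + 6*lambda plus noise, 100 ps each
for lam in (0.0, 0.5, 1.0):
    series = DerivativeSeries(
        lam=lam, dt=0.1,
        values=2.0 + 6.0 * lam + rng.normal(0.0, 0.5, 1000),
        burn_in=0.0,
    )
    write_dhdl_table(workdir / f"dhdl_{lam:.1f}.xvg", series)

windows = [
    read_dhdl_table(workdir / f"dhdl_{lam:.1f}.xvg", burn_in=10.0)
    for lam in (0.0, 0.5, 1.0)
]
result = integrate_ti(windows)
print(f"read {len(windows)} windows from {workdir}")
print(f"dG = {result.delta_g:.3f} +- {result.stderr:.3f} kJ/mol "
      f"(exact for this linear profile: 5.000)")
# Burn-in removal (first 10 ps) and block-averaged window errors are
# applied exactly as for internally generated series.
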