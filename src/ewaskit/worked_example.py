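"""Worked-example summary statistics for two-stage inverse-variance combination.

Discovery and replication (effect, p) pairs for 13 replicated eGFR-associated
DMPs from a published multi-ethnic whole-blood EWAS of kidney function
(effects in mL/min/1.73 m^2 per unit beta).  The printed pairs are inputs:
converting each to a standard error via the normal quantile and combining the
two stages by fixed-effect inverse-variance weighting reproduces the published
combined-stage estimates, which makes this table a compact end-to-end check of
the meta-analysis arithmetic.

78 trans-ethnic discovery DMPs were tested for replication, giving the
Bonferroni cutoff 0.05/78 = 6.4E-04.
"""

from __future__ import annotations

import pandas as pd

N_REPLICATION_TESTS = 78

_ROWS = [
    # probe_id, chrom, pos, gene, disc_effect, disc_p, repl_effect, repl_p
    ("cg13235761", "chr1", 203_592_452, "", -37.61, 4.33e-06, -25.28, 5.08e-05),
    ("cg26099045", "chr2", 64_064_666, "", 14.82, 5.74e-06, 11.24, 1.01e-04),
    ("cg04428662", "chr4", 2_932_461, "MFSD10", -30.84, 3.21e-06, -34.94, 3.43e-07),
    ("cg23174201", "chr5", 151_674_695, "SPARC", -35.83, 5.10e-06, -34.87, 1.72e-07),
    ("cg17170437", "chr6", 44_229_461, "SLC29A1", -47.62, 1.96e-06, -18.62, 1.49e-04),
    ("cg14871770", "chr10", 96_658_622, "CYP2C9/CYP2C19", -53.12, 1.98e-06, -25.87, 1.70e-04),
    ("cg02157636", "chr11", 68_709_367, "TESMIN", -53.21, 2.15e-06, -27.25, 1.14e-05),
    ("cg26039141", "chr11", 75_402_116, "RPS3", -39.14, 3.40e-06, -33.42, 1.78e-05),
    ("cg22593432", "chr13", 32_001_768, "", -29.91, 1.54e-07, -17.66, 1.79e-04),
    ("cg11789371", "chr14", 102_085_048, "HSP90AA1", -35.40, 4.44e-06, -22.66, 3.58e-04),
    ("cg05796561", "chr18", 57_128_273, "", -45.24, 2.96e-06, -22.91, 1.69e-04),
    ("cg17944885", "chr19", 12_114_920, "ZNF20/ZNF788P", -32.71, 1.41e-09, -16.34, 5.67e-07),
    ("cg15787712", "chr19", 13_837_429, "LOC284454/MIR23", -37.60, 6.00e-09, -28.65, 2.06e-05),
]


def replicated_dmps() -> pd.DataFrame:
    """The 13 replicated DMPs with discovery and replication effect/p pairs."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "probe_id",
            "chrom",
            "pos",
            "gene",
            "discovery_effect",
            "discovery_p",
            "replication_effect",
            "replication_p",
        ],
    )
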