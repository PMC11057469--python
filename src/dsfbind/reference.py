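"""Published reference data shipped with the package.

``load_reference_kd_table`` returns the cross-species serum-albumin/PFAS
affinity table (DSF-derived Kd ± SEM in mM, maximal ΔTm ± SEM in °C, pooled
r², and — where reported — the number n of replicate Kd estimates) for
human (HSA), bovine (BSA), porcine (PSA), and rat (RSA) serum albumin
against eight PFAS congeners.  The fluorotelomer alcohol 6:2 FTOH is
nonbinding for every species and carried as N/A rows.

Note: for the HSA–PFOS pair two Kd values circulate in the source summaries
(0.69 and 0.62 mM, from differently pooled replicate sets); this table uses
0.69, the value consistent with the published chain-length contrast
percentages.
"""

from __future__ import annotations

from importlib import resources

from .compare import KdTable, read_kd_table

__all__ = ["load_reference_kd_table", "REFERENCE_BASELINE_TM_C"]

#: Ligand-free melting temperatures (°C) of the four study albumins.
REFERENCE_BASELINE_TM_C = {"HSA": 71.3, "BSA": 62.6, "PSA": 71.3, "RSA": 66.8}


def load_reference_kd_table() -> KdTable:
    """The shipped cross-species albumin–PFAS affinity table."""
    with resources.as_file(
        resources.files("dsfbind.data").joinpath("albumin_pfas_kd.csv")
    ) as path:
        return read_kd_table(path)
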