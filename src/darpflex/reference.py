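"""Reference equilibrium and kinetic constants for the tubulin-DARPin system.

Published constants for the parent binder D1 and its affinity-matured
variants, as measured by fluorescence (titration + stopped-flow) and by
SPR.  These serve two roles: as true parameters for the synthetic-data
generators (so recovery tests run under realistic conditions), and as
inputs to the kinetic-ratio arithmetic when reproducing the summary table.

All values are SI (mol/L, 1/s, 1/(M s)); ``*_se`` are the reported
uncertainties where available (0 where none was printed).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VariantConstants", "FLUORESCENCE", "SPR", "PROBE_CONC"]


@dataclass(frozen=True)
class VariantConstants:
    """One variant's constants from a single method (fluorescence or SPR)."""

    k_off: float            # 1/s
    k_off_se: float
    k_on: float             # 1/(M s)
    k_on_se: float
    k_d_titration: float | None = None     # mol/L (None where not determined)
    k_d_titration_se: float | None = None
    printed_ratio_nm: float | None = None  # the published k_off/k_on in nM
    printed_ratio_se_nm: float | None = None


# Fluorescence block: equilibrium titration K_D plus stopped-flow rates.
FLUORESCENCE: dict[str, VariantConstants] = {
    "D1": VariantConstants(
        k_off=1.49, k_off_se=0.07, k_on=1.30e7, k_on_se=0.0,
        k_d_titration=127e-9, k_d_titration_se=12e-9,
        printed_ratio_nm=115.0, printed_ratio_se_nm=6.0,
    ),
    "A-C2": VariantConstants(
        k_off=0.0071, k_off_se=0.0002, k_on=1.60e7, k_on_se=0.0,
        k_d_titration=0.82e-9, k_d_titration_se=0.18e-9,
        printed_ratio_nm=0.444, printed_ratio_se_nm=0.013,
    ),
    "TM-3": VariantConstants(
        k_off=0.0049, k_off_se=0.0002, k_on=1.82e7, k_on_se=0.0,
        k_d_titration=0.90e-9, k_d_titration_se=0.19e-9,
        printed_ratio_nm=0.269, printed_ratio_se_nm=0.013,
    ),
    "digested TM-3": VariantConstants(
        k_off=0.0046, k_off_se=0.0001, k_on=2.67e7, k_on_se=0.0,
        k_d_titration=1.03e-9, k_d_titration_se=0.28e-9,
        printed_ratio_nm=0.172, printed_ratio_se_nm=0.004,
    ),
}

# SPR block: Langmuir kinetics; D1 additionally has a plateau-titration K_D.
SPR: dict[str, VariantConstants] = {
    "D1": VariantConstants(
        k_off=0.22, k_off_se=0.01, k_on=8e5, k_on_se=1.5e5,
        k_d_titration=300e-9, k_d_titration_se=30e-9,
        printed_ratio_nm=275.0, printed_ratio_se_nm=75.0,
    ),
    "A-C2": VariantConstants(
        k_off=0.0041, k_off_se=0.0001, k_on=1.2e6, k_on_se=0.2e6,
        printed_ratio_nm=3.4, printed_ratio_se_nm=0.6,
    ),
    "TM-3": VariantConstants(
        k_off=0.0025, k_off_se=0.0002, k_on=1.9e6, k_on_se=0.2e6,
        printed_ratio_nm=1.3, printed_ratio_se_nm=0.2,
    ),
    "TM-3 1-149": VariantConstants(
        k_off=0.0027, k_off_se=0.0001, k_on=1.7e6, k_on_se=0.1e6,
        printed_ratio_nm=1.6, printed_ratio_se_nm=0.2,
    ),
}

# Labeled-probe concentrations used in the titration experiments (mol/L):
# 100 nM for the parent binder, 15 nM for the high-affinity variants.
PROBE_CONC: dict[str, float] = {
    "D1": 100e-9,
    "A-C2": 15e-9,
    "TM-3": 15e-9,
    "digested TM-3": 15e-9,
}
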