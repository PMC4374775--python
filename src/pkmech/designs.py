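"""Reference concentration designs and kinetic constants for TpPK.

These are the published experimental conditions for the Thermofilum pendens
pyruvate kinase: the initial-velocity grid (PEP3- x ADP-Mg at 30 mM free
Mg2+) and the four dead-end inhibition designs (oxalate as the PEP analog,
AMP as the ADP analog), together with the fitted constants they produced.
The synthetic-data generators use them as defaults so simulated studies
match the real ones point for point.

All concentrations in mM.
"""

from __future__ import annotations

from .rate_laws import HillParams, InhibitionParams, RandomREParams

__all__ = [
    "PEP_LEVELS_MM",
    "ADPMG_LEVELS_MM",
    "FREE_MG_MM",
    "INHIBITION_DESIGNS",
    "TPPK_MG_PARAMS",
    "TPPK_MN_HILL_PEP",
    "TPPK_MN_HILL_CATION",
    "OXALATE_VS_PEP",
    "AMP_VS_ADPMG",
    "TABLE1_K05_MG_MM",
    "TABLE1_K05_MN_MM",
]

#: Varied PEP3- levels of the initial-velocity study (the fixed-PEP list of
#: the complementary panel).
PEP_LEVELS_MM = (0.031, 0.14, 0.34, 0.69, 1.30)

#: Fixed/varied ADP-Mg levels of the initial-velocity study.
ADPMG_LEVELS_MM = (0.084, 0.12, 0.16, 0.37, 0.67)

#: Free Mg2+ held constant throughout the kinetic work.
FREE_MG_MM = 30.0

#: Dead-end inhibition designs: varied-substrate levels, inhibitor levels,
#: and the fixed co-substrate concentration.
INHIBITION_DESIGNS = {
    # oxalate vs PEP3- (ADP held at 2 mM); oxalate in mM (10-40 uM)
    "oxalate_vs_pep": {
        "substrate_mM": (0.054, 0.077, 0.10, 0.22, 1.1),
        "inhibitor_mM": (0.0, 0.010, 0.020, 0.030, 0.040),
        "fixed_cosubstrate_mM": 2.0,
        "varied": "PEP3-",
        "inhibitor": "oxalate",
    },
    # oxalate vs ADP-Mg (PEP3- held at 30 mM)
    "oxalate_vs_adpmg": {
        "substrate_mM": (0.045, 0.063, 0.090, 0.18, 0.90),
        "inhibitor_mM": (0.0, 0.010, 0.020, 0.030, 0.040),
        "fixed_cosubstrate_mM": 30.0,
        "varied": "ADP-Mg",
        "inhibitor": "oxalate",
    },
    # AMP vs PEP3- (ADP held at 2 mM)
    "amp_vs_pep": {
        "substrate_mM": (0.15, 0.30, 0.55, 0.77, 1.5),
        "inhibitor_mM": (0.0, 4.0, 8.0, 12.0, 16.0),
        "fixed_cosubstrate_mM": 2.0,
        "varied": "PEP3-",
        "inhibitor": "AMP",
    },
    # AMP vs ADP-Mg (PEP3- held at 30 mM)
    "amp_vs_adpmg": {
        "substrate_mM": (0.045, 0.063, 0.090, 0.18, 0.90),
        "inhibitor_mM": (0.0, 8.0, 12.0, 16.0, 20.0),
        "fixed_cosubstrate_mM": 30.0,
        "varied": "ADP-Mg",
        "inhibitor": "AMP",
    },
}

#: Globally fitted random rapid-equilibrium constants with Mg2+:
#: Vmax 183 umol.min-1.mg-1, Km(PEP3-) 0.38 mM, Km(ADP-Mg) 0.16 mM.
TPPK_MG_PARAMS = RandomREParams(vmax=183.0, ka=0.38, kb=0.16)

#: Hill fits with Mn2+: PEP3- saturation (K0.5 1.0 mM, n 1.2) and free-Mn2+
#: saturation (K0.5 0.02 mM, n 1.6); Vmax 41 umol.min-1.mg-1.
TPPK_MN_HILL_PEP = HillParams(vmax=41.0, k05=1.0, n=1.2)
TPPK_MN_HILL_CATION = HillParams(vmax=41.0, k05=0.02, n=1.6)

#: Half-saturation constants for the free divalent cation (mM): Mg2+ is
#: 250-fold weaker than Mn2+.
TABLE1_K05_MG_MM = 5.0
TABLE1_K05_MN_MM = 0.02

#: Published inhibition constants: oxalate competitive vs PEP3-
#: (Ki 0.05 mM) and AMP competitive vs ADP-Mg (Ki 35 mM).  The apparent
#: (V, Km) are the global-fit constants of the matching varied substrate.
OXALATE_VS_PEP = InhibitionParams(v=183.0, km=0.38, ki=0.05, kind="competitive")
AMP_VS_ADPMG = InhibitionParams(v=183.0, km=0.16, ki=35.0, kind="competitive")
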