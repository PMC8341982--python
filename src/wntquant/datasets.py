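"""Reference measurements and literature constants for the model chain.

The bundled numbers are the live-cell FCS medians for the CTNNB1 pools
(nM, HAP1 cells, with and without WNT3A stimulation) plus the two
literature-derived kinetic quantities the equilibrium analysis cannot
supply: the CTNNB1 synthesis rate b and the CB-DC dissociation constant K1.
They are the default inputs of the parameter-derivation pipeline; every
downstream number (rate ratios, steady states, time courses, scans) is
recomputed from them.
"""

from __future__ import annotations

from .derive import EquilibriumMeasurement, estimate_tcf_total

__all__ = [
    "LIT_SYNTHESIS_RATE",
    "LIT_K1_DISSOCIATION",
    "TCF_TOTAL",
    "RESIDUAL_FREE_TCF_FRACTION",
    "RATE_SCALE",
    "STEEP_MIN",
    "SGFP2_D",
    "SGFP2_MASS_KDA",
    "FUSION_MASS_KDA",
    "S45F_CYTOPLASM_NM",
    "S45F_NUCLEUS_NM",
    "reference_measurements",
]

#: CTNNB1 synthesis rate b (nM/min), from the kinetic literature.
LIT_SYNTHESIS_RATE = 0.423
#: Dissociation constant K1 = k2/k1 of CTNNB1 binding to the destruction
#: complex (nM), from the kinetic literature.
LIT_K1_DISSOCIATION = 120.0

#: Fraction of the committed TCF pool that remains free after stimulation.
RESIDUAL_FREE_TCF_FRACTION = 0.2
#: Total nuclear TCF (nM): 86 nM bound after stimulation plus a fifth of
#: that remaining free, committed at reporting precision.
TCF_TOTAL = round(estimate_tcf_total(86.0, RESIDUAL_FREE_TCF_FRACTION))

#: Global time-scale factor bringing the model to equilibrium in ~4.5 h.
RATE_SCALE = 20.0
#: Minutes after WNT onset at which the OFF->ON parameter transition completes.
STEEP_MIN = 150.0

#: Measured diffusion coefficient of free SGFP2 in cells (um^2/s) and the
#: molecular masses (kDa) entering the Einstein-Stokes scaling for the
#: monomeric fusion protein.
SGFP2_D = 24.1
SGFP2_MASS_KDA = 27.0
FUSION_MASS_KDA = 115.0

#: Measured total cytoplasmic / nuclear concentration of the
#: degradation-resistant S45F mutant (nM), the target of the k3 scans.
S45F_CYTOPLASM_NM = 351.0
S45F_NUCLEUS_NM = 429.0


def reference_measurements() -> dict[str, EquilibriumMeasurement]:
    """The measured equilibrium pools (nM) keyed by WNT condition.

    The DC-bound pool uses the average of the two condition medians (57 and
    68 nM, statistically indistinguishable) under the assumption that k3 is
    unchanged by stimulation; the TCF-bound nuclear pool without WNT is the
    FCS median 22 nM.
    """
    common = dict(tcf_total=float(TCF_TOTAL), k1_ratio=LIT_K1_DISSOCIATION,
                  b=LIT_SYNTHESIS_RATE)
    return {
        "WNT_OFF": EquilibriumMeasurement(
            condition="WNT_OFF", cb_free=91.0, nb_free=87.0, nb_tcf=22.0,
            cb_dc=62.5, **common),
        "WNT_ON": EquilibriumMeasurement(
            condition="WNT_ON", cb_free=145.0, nb_free=170.0, nb_tcf=86.0,
            cb_dc=62.5, **common),
    }
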