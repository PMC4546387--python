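"""Unit conventions used throughout the package.

All quantities are carried in a single consistent unit system:

====================  ======
voltage               mV
time                  ms
current               pA
capacitance           pF
conductance           nS
resistance            MOhm
====================  ======

These units are mutually consistent without conversion factors in the
dynamical equations: ``I [pA] / C [pF]`` is directly mV/ms, and
``g [nS] = C [pF] / tau [ms]``.  The only non-unit factor is between
resistance and conductance (1 nS = 1000 / MOhm) and between a pA*MOhm
product and voltage (1 pA * 1 MOhm = 1e-3 mV); both are centralised here.
"""

#: multiply a resistance in MOhm by this to get its reciprocal in nS,
#: i.e. ``G_nS = NS_PER_INV_MOHM / R_MOhm``.
NS_PER_INV_MOHM = 1000.0

#: 1 pA * 1 MOhm in mV.
MV_PER_PA_MOHM = 1e-3


def resistance_to_conductance(r_mohm: float) -> float:
    """Input resistance (MOhm) -> input conductance (nS)."""
    return NS_PER_INV_MOHM / r_mohm


def conductance_to_resistance(g_ns: float) -> float:
    """Input conductance (nS) -> input resistance (MOhm)."""
    return NS_PER_INV_MOHM / g_ns
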