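"""Physical constants and unit conversions.

Units are fixed repo-wide: lengths in µm, times in s, amounts as molecule
counts.  Bimolecular rate constants for volume-phase (luminal/cytosolic)
reactions are entered in 1/(M*s) and converted to per-molecule-pair reaction
volumes in µm³; membrane-phase (2D) rate constants are entered directly in
µm²/s per molecule pair.
"""

N_AVOGADRO = 6.02214076e23

#: number of µm³ in one litre
LITRE_UM3 = 1e15


def molar_rate_to_um3(k_molar: float) -> float:
    """Convert a bimolecular rate constant from 1/(M*s) to µm³/s per pair.

    k/(N_A * V[L]) [1/s]  ==  (k * 1e15 / N_A) / V[µm³] [1/s]
    """
    return k_molar * LITRE_UM3 / N_AVOGADRO


def um3_rate_to_molar(k_um3: float) -> float:
    """Inverse of :func:`molar_rate_to_um3`."""
    return k_um3 * N_AVOGADRO / LITRE_UM3
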