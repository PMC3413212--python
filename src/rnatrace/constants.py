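"""Ideal RNA covalent geometry and related constants.

Bond lengths (Å) and angles (deg) follow standard small-molecule values for
ribonucleotides; they parameterize both the synthetic-model forward builder
and the restraint targets used during coordinate calculation.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# backbone / sugar covalent geometry
# ---------------------------------------------------------------------------

BOND_LENGTHS: dict[tuple[str, str], float] = {
    ("O3'", "P"): 1.607,   # inter-nucleotide phosphodiester
    ("P", "O5'"): 1.593,
    ("O5'", "C5'"): 1.440,
    ("C5'", "C4'"): 1.510,
    ("C4'", "C3'"): 1.524,
    ("C3'", "O3'"): 1.423,
    ("C3'", "C2'"): 1.525,
    ("C2'", "C1'"): 1.528,
    ("C1'", "O4'"): 1.414,
    ("O4'", "C4'"): 1.453,
    ("C2'", "O2'"): 1.413,
    ("C1'", "N"): 1.470,   # glycosidic bond (N9 purine / N1 pyrimidine)
}

BOND_ANGLES: dict[tuple[str, str, str], float] = {
    ("C3'", "O3'", "P"): 119.7,
    ("O3'", "P", "O5'"): 104.0,
    ("P", "O5'", "C5'"): 120.9,
    ("O5'", "C5'", "C4'"): 111.5,
    ("C5'", "C4'", "C3'"): 115.5,
    ("C4'", "C3'", "O3'"): 110.6,
    ("C2'", "C3'", "O3'"): 111.8,
    ("C5'", "C4'", "O4'"): 109.8,
    # ribose ring
    ("C1'", "C2'", "C3'"): 101.5,
    ("C2'", "C3'", "C4'"): 102.7,
    ("C3'", "C4'", "O4'"): 105.5,
    ("C4'", "O4'", "C1'"): 109.7,
    ("O4'", "C1'", "C2'"): 106.4,
    # substituents
    ("C1'", "C2'", "O2'"): 110.6,
    ("C3'", "C2'", "O2'"): 113.3,
    ("O4'", "C1'", "N"): 108.5,
    ("C2'", "C1'", "N"): 112.0,
}

#: Sugar atoms whose centroid defines the "sugar center" anchor.
RIBOSE_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

#: Backbone + sugar atom names in 5'->3' construction order.
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
SUGAR_COMPLETION_ATOMS = ("C2'", "C1'", "O4'", "O2'")

# ---------------------------------------------------------------------------
# sugar pucker / pseudorotation
# ---------------------------------------------------------------------------

#: Pseudorotation amplitude (deg) used for ideal ring targets.
PSEUDOROTATION_AMPLITUDE = 38.0

#: Phase (deg) of the two canonical puckers.
PUCKER_PHASE = {"C3'-endo": 15.0, "C2'-endo": 160.0}

#: Pseudorotation windows used to classify a phase into a pucker label.
PUCKER_WINDOWS = {"C3'-endo": (-18.0, 54.0), "C2'-endo": 126.0, }

#: delta torsion bands (deg) used to map conformer means onto puckers.
DELTA_C3_ENDO = 84.0
DELTA_C2_ENDO = 145.0
DELTA_PUCKER_SPLIT = 115.0  # below -> C3'-endo, above -> C2'-endo

#: Default glycosidic torsion (chi, O4'-C1'-N-C) per leading pucker: anti.
DEFAULT_CHI = {"C3'-endo": -158.0, "C2'-endo": -120.0}


def nu_targets(pucker: str, amplitude: float = PSEUDOROTATION_AMPLITUDE) -> np.ndarray:
    """Ideal ring torsions nu0..nu4 (deg) for a pucker from the
    pseudorotation formula nu_j = tau_m * cos(P + 144*(j-2))."""
    try:
        phase = PUCKER_PHASE[pucker]
    except KeyError:
        raise ValueError(f"unknown pucker {pucker!r}") from None
    j = np.arange(5)
    return amplitude * np.cos(np.deg2rad(phase + 144.0 * (j - 2)))


def pseudorotation_phase(nus: np.ndarray) -> float:
    """Pseudorotation phase (deg, in [-90, 270)) from ring torsions nu0..nu4."""
    nus = np.asarray(nus, dtype=float)
    denom = 2.0 * nus[2] * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0)))
    phase = np.rad2deg(np.arctan2(nus[4] + nus[1] - nus[3] - nus[0], denom))
    if nus[2] < 0:
        # arctan2 already handles the sign through the denominator
        pass
    return float(phase % 360.0 if phase % 360.0 < 270.0 else phase % 360.0 - 360.0)


def pucker_from_phase(phase: float) -> str:
    """Classify a pseudorotation phase into the nearer canonical pucker."""
    d3 = abs((phase - PUCKER_PHASE["C3'-endo"] + 180.0) % 360.0 - 180.0)
    d2 = abs((phase - PUCKER_PHASE["C2'-endo"] + 180.0) % 360.0 - 180.0)
    return "C3'-endo" if d3 <= d2 else "C2'-endo"


def pucker_from_delta(delta: float) -> str:
    return "C3'-endo" if delta < DELTA_PUCKER_SPLIT else "C2'-endo"


# ---------------------------------------------------------------------------
# scattering weights for synthetic maps (approximate atomic numbers)
# ---------------------------------------------------------------------------

ELEMENT_WEIGHTS = {"C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0}


def element_of(atom_name: str) -> str:
    return atom_name.strip()[0]


#: Suite torsion names in order: (delta-1, epsilon-1, zeta-1, alpha, beta, gamma, delta)
SUITE_TORSION_NAMES = ("delta-1", "epsilon-1", "zeta-1", "alpha", "beta", "gamma", "delta")

PURINES = ("A", "G")
PYRIMIDINES = ("C", "U")
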