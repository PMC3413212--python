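"""All-atom nucleotide models: torsion read-back, anchors, PDB/mmCIF I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .geometry import torsion

__all__ = ["NucleotideModel", "read_model", "SUITE_TORSION_ATOMS"]

#: atom paths for the 7 suite torsions; offsets are relative to the suite's
#: 5' nucleotide (index j-1 for suite j).
SUITE_TORSION_ATOMS = (
    (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),   # delta-1
    (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)),     # epsilon-1
    (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)),     # zeta-1
    (("O3'", 0), ("P", 1), ("O5'", 1), ("C5'", 1)),     # alpha
    (("P", 1), ("O5'", 1), ("C5'", 1), ("C4'", 1)),     # beta
    (("O5'", 1), ("C5'", 1), ("C4'", 1), ("C3'", 1)),   # gamma
    (("C5'", 1), ("C4'", 1), ("C3'", 1), ("O3'", 1)),   # delta
)

_NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


@dataclass
class NucleotideModel:
    """An ordered RNA chain: per-nucleotide atom coordinate dicts (5'->3'),
    the sequence, and optional per-suite conformer assignments/residuals."""

    residues: list[dict[str, np.ndarray]]
    sequence: str
    conformers: list[str] | None = None
    suite_residuals: list[float] | None = None
    suite_predictions: list | None = None  # SuitePrediction per suite (flagged)
    chain_id: str = "A"

    def __post_init__(self):
        if len(self.residues) != len(self.sequence):
            raise ValueError("sequence length must match residue count")

    # -- access -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_suites(self) -> int:
        return max(len(self.residues) - 1, 0)

    def atom(self, i: int, name: str) -> np.ndarray:
        return self.residues[i][name]

    def has_atom(self, i: int, name: str) -> bool:
        return name in self.residues[i]

    def sugar_center(self, i: int) -> np.ndarray:
        return np.mean([self.residues[i][a] for a in constants.RIBOSE_RING_ATOMS], axis=0)

    def copy(self) -> "NucleotideModel":
        return NucleotideModel(
            residues=[{k: v.copy() for k, v in r.items()} for r in self.residues],
            sequence=self.sequence,
            conformers=list(self.conformers) if self.conformers else None,
            suite_residuals=list(self.suite_residuals) if self.suite_residuals else None,
            chain_id=self.chain_id,
        )

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "NucleotideModel":
        out = self.copy()
        for r in out.residues:
            for k in r:
                r[k] = rot @ r[k] + trans
        return out

    # -- torsion read-back ---------------------------------------------------

    def suite_torsions(self, suite: int) -> np.ndarray:
        """Torsions (delta-1, epsilon-1, zeta-1, alpha, beta, gamma, delta)
        of suite ``suite`` (1-based over the chain: suite j joins
        nucleotides j-1 and j; accepted range 1..n-1)."""
        if not 1 <= suite <= self.n_suites:
            raise IndexError(f"suite {suite} out of range")
        base = suite - 1
        vals = []
        for path in SUITE_TORSION_ATOMS:
            pts = [self.residues[base + off][name] for name, off in path]
            vals.append(torsion(*pts))
        return np.array(vals)

    def nu_torsions(self, i: int) -> np.ndarray:
        r = self.residues[i]
        return np.array([torsion(*(r[a] for a in quad)) for quad in _NU_ATOMS])

    def pucker(self, i: int) -> str:
        phase = constants.pseudorotation_phase(self.nu_torsions(i))
        return constants.pucker_from_phase(phase)

    def chi(self, i: int) -> float:
        r = self.residues[i]
        if "N9" in r:
            return torsion(r["O4'"], r["C1'"], r["N9"], r["C4"])
        return torsion(r["O4'"], r["C1'"], r["N1"], r["C2"])

    def pseudo_chi(self, i: int) -> float:
        """Torsion P-C1'-N9-N1 (purine) or P-C1'-N1-N3 (pyrimidine)."""
        r = self.residues[i]
        if "N9" in r:
            return torsion(r["P"], r["C1'"], r["N9"], r["N1"])
        return torsion(r["P"], r["C1'"], r["N1"], r["N3"])

    def suite_anchors(self, suite: int):
        """Anchor atoms (C1'[j-1], P[j], C1'[j], P[j+1], C1'[j+1]) for the
        conformer predictor; raises for terminal suites lacking them."""
        from .conformers import SuiteAnchors

        j = suite
        if not (1 <= j <= self.n_suites) or j + 1 >= len(self.residues):
            raise IndexError(f"suite {suite} lacks flanking anchors")
        return SuiteAnchors(
            c1p_prev=self.atom(j - 1, "C1'"),
            p=self.atom(j, "P"),
            c1p=self.atom(j, "C1'"),
            p_next=self.atom(j + 1, "P"),
            c1p_next=self.atom(j + 1, "C1'"),
        )

    def base_atom_names(self, i: int) -> list[str]:
        backbone = set(constants.BACKBONE_ATOMS) | set(constants.SUGAR_COMPLETION_ATOMS)
        return [n for n in self.residues[i] if n not in backbone]

    # -- I/O ----------------------------------------------------------------

    def to_gemmi(self):
        import gemmi

        st = gemmi.Structure()
        st.name = "rnatrace model"
        mdl = gemmi.Model("1")
        chain = gemmi.Chain(self.chain_id)
        for i, (res_atoms, code) in enumerate(zip(self.residues, self.sequence), start=1):
            res = gemmi.Residue()
            res.name = code
            res.seqid = gemmi.SeqId(i, " ")
            for name, pos in res_atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(constants.element_of(name))
                at.pos = gemmi.Position(*pos)
                at.occ = 1.0
                at.b_iso = 20.0
                res.add_atom(at)
            chain.add_residue(res)
        mdl.add_chain(chain)
        st.add_model(mdl)
        st.setup_entities()
        return st

    def write_pdb(self, path: str) -> None:
        self.to_gemmi().write_pdb(str(path))

    def write_cif(self, path: str) -> None:
        self.to_gemmi().make_mmcif_document().write_file(str(path))


def read_model(path: str) -> NucleotideModel:
    """Read an RNA chain from PDB or mmCIF (first model, first chain)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chain = st[0][0]
    residues = []
    seq = []
    for res in chain:
        name = res.name.strip()
        code = name[-1] if name else "N"
        if code not in "ACGU":
            continue
        atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
        residues.append(atoms)
        seq.append(code)
    if not residues:
        raise ValueError(f"no RNA residues found in {path}")
    return NucleotideModel(residues=residues, sequence="".join(seq), chain_id=chain.name)
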