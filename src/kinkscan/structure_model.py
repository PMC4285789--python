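"""Structure parsing and per-residue secondary-structure assignment.

Reads PDB/mmCIF files into light-weight chain models carrying backbone
coordinates, computes backbone dihedrals, and labels helical residues
either with an internal Kabsch–Sander hydrogen-bond-energy implementation
of the DSSP 4-helix rule or from a pre-computed DSSP output file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from . import constants as C
from ._geom import dihedral
from .errors import DsspAlignmentError, StructureParseError

__all__ = [
    "ResidueRecord",
    "ChainModel",
    "read_structure",
    "compute_dihedrals",
    "assign_helix_states",
    "kabsch_sander_energy",
    "backbone_amide_h",
    "parse_dssp_states",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ResidueRecord:
    """One amino acid with backbone coordinates and annotations.

    Coordinates are in Å; any of the four backbone atoms may be absent
    (``None``).  ``extra_atoms`` holds all remaining heavy atoms (sidechain
    plus OXT) keyed by atom name, for surface-area and sidechain
    hydrogen-bond calculations.
    """

    chain_id: str
    seq_num: int
    insertion_code: str = ""
    aa: str = "X"
    name: str = "UNK"
    coords_N: Optional[np.ndarray] = None
    coords_CA: Optional[np.ndarray] = None
    coords_C: Optional[np.ndarray] = None
    coords_O: Optional[np.ndarray] = None
    extra_atoms: dict = field(default_factory=dict)
    phi: Optional[float] = None
    psi: Optional[float] = None
    ss_state: str = "-"
    malformed: bool = False

    def backbone_complete(self) -> bool:
        return all(
            getattr(self, f"coords_{a}") is not None for a in BACKBONE_ATOMS
        )

    def atom(self, name: str) -> Optional[np.ndarray]:
        if name in BACKBONE_ATOMS:
            return getattr(self, f"coords_{name}")
        return self.extra_atoms.get(name)

    def heavy_atoms(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for a in BACKBONE_ATOMS:
            xyz = getattr(self, f"coords_{a}")
            if xyz is not None:
                out.append((a, xyz))
        for a, xyz in self.extra_atoms.items():
            if not a.startswith("H"):
                out.append((a, xyz))
        return out

    def check_backbone_plausibility(self) -> None:
        """Flag the residue malformed if bonded backbone distances are absurd."""
        if not self.backbone_complete():
            return
        n_ca = float(np.linalg.norm(self.coords_CA - self.coords_N))
        ca_c = float(np.linalg.norm(self.coords_C - self.coords_CA))
        if not (1.2 <= n_ca <= 1.8 and 1.2 <= ca_c <= 1.8):
            self.malformed = True


@dataclass
class ChainModel:
    """An ordered polypeptide chain from one structure model."""

    pdb_id: str
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    source: str = "other"  # xray | nmr | other

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ss_string(self) -> str:
        return "".join(r.ss_state if r.ss_state == "H" else "-" for r in self.residues)


def _one_letter(resname: str) -> Optional[str]:
    """Map a residue name to a one-letter code, 'X' for unmappable amino
    acids, None for non-amino-acids (skipped)."""
    resname = resname.upper()
    if resname in C.THREE_TO_ONE:
        return C.THREE_TO_ONE[resname]
    if resname in C.NONSTANDARD_PARENT:
        return C.NONSTANDARD_PARENT[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        one = info.one_letter_code.upper()
        return one if one in C.AMINO_ACIDS else "X"
    return None


def _resolve_altlocs(res: gemmi.Residue) -> dict[str, np.ndarray]:
    """One coordinate per atom name: highest occupancy wins, ties broken by
    altloc identifier order."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in res:
        xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        key = atom.name
        cand = (-float(atom.occ), atom.altloc or "", xyz)
        if key not in best or cand[:2] < best[key][:2]:
            best[key] = cand
    return {k: v[2] for k, v in best.items()}


def _detect_source(st: gemmi.Structure) -> str:
    info = dict(st.info)
    method = (info.get("_exptl.method") or "").upper()
    if "NMR" in method:
        return "nmr"
    if "X-RAY" in method or "DIFFRACTION" in method:
        return "xray"
    return "other"


def read_structure(path, format: str = "auto") -> list[ChainModel]:
    """Parse a PDB or mmCIF file into one ChainModel per polypeptide chain.

    Alternate locations are resolved to a single coordinate per atom,
    hetero compounds and waters are excluded, nonstandard residues are
    mapped to a parent amino acid where known and to ``'X'`` otherwise.
    Only the first model is used (the first conformer of NMR entries).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with record context
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    source = _detect_source(st)
    pdb_id = (st.name or path.stem).lower()
    model = st[0]

    chains: list[ChainModel] = []
    for ch in model:
        chain = ChainModel(pdb_id=pdb_id, chain_id=ch.name, source=source)
        for res in ch:
            if res.is_water():
                continue
            aa = _one_letter(res.name)
            if aa is None:
                continue
            coords = _resolve_altlocs(res)
            rec = ResidueRecord(
                chain_id=ch.name,
                seq_num=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                aa=aa,
                name=res.name.upper(),
            )
            for a in BACKBONE_ATOMS:
                if a in coords:
                    setattr(rec, f"coords_{a}", coords[a])
            rec.extra_atoms = {
                k: v for k, v in coords.items() if k not in BACKBONE_ATOMS
            }
            rec.check_backbone_plausibility()
            chain.residues.append(rec)
        # order and de-duplicate by (seq_num, insertion_code)
        chain.residues.sort(key=lambda r: (r.seq_num, r.insertion_code))
        seen: dict[tuple, ResidueRecord] = {}
        for r in chain.residues:
            seen.setdefault((r.seq_num, r.insertion_code), r)
        chain.residues = list(seen.values())
        if not chain.residues:
            warnings.warn(
                f"{pdb_id} chain {ch.name}: no standard residues, skipped"
            )
            continue
        chains.append(chain)
    return chains


def compute_dihedrals(chain: ChainModel) -> ChainModel:
    """Populate phi/psi (degrees, (-180, 180]) where the flanking atoms exist.

    phi(i) needs C(i-1), N(i), CA(i), C(i); psi(i) needs N(i), CA(i), C(i),
    N(i+1).  A missing atom leaves the dihedral undefined.
    """
    res = chain.residues
    for i, r in enumerate(res):
        prev_c = res[i - 1].coords_C if i > 0 else None
        next_n = res[i + 1].coords_N if i + 1 < len(res) else None
        if (
            prev_c is not None
            and r.coords_N is not None
            and r.coords_CA is not None
            and r.coords_C is not None
        ):
            r.phi = dihedral(prev_c, r.coords_N, r.coords_CA, r.coords_C)
        else:
            r.phi = None
        if (
            next_n is not None
            and r.coords_N is not None
            and r.coords_CA is not None
            and r.coords_C is not None
        ):
            r.psi = dihedral(r.coords_N, r.coords_CA, r.coords_C, next_n)
        else:
            r.psi = None
    return chain


def backbone_amide_h(donor: ResidueRecord, prev: ResidueRecord) -> Optional[np.ndarray]:
    """Idealized amide-H position: 1 Å from N, opposite the preceding C=O."""
    if (
        donor.coords_N is None
        or prev.coords_C is None
        or prev.coords_O is None
    ):
        return None
    co = prev.coords_C - prev.coords_O
    norm = np.linalg.norm(co)
    if norm == 0:
        return None
    return donor.coords_N + co / norm


def kabsch_sander_energy(
    acceptor: ResidueRecord, donor: ResidueRecord, donor_prev: ResidueRecord
) -> Optional[float]:
    """Electrostatic hydrogen-bond energy (kcal/mol) between the amide of
    ``donor`` and the carbonyl of ``acceptor``; ``None`` if atoms missing or
    the donor is Proline (no amide proton)."""
    if donor.aa == "P":
        return None
    if acceptor.coords_C is None or acceptor.coords_O is None:
        return None
    h = backbone_amide_h(donor, donor_prev)
    if h is None:
        return None
    n = donor.coords_N
    c, o = acceptor.coords_C, acceptor.coords_O
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return C.KS_MIN_ENERGY
    e = C.KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(max(e, C.KS_MIN_ENERGY))


def _internal_hbond_set(chain: ChainModel) -> set[tuple[int, int]]:
    """(donor_idx, acceptor_idx) pairs with Kabsch-Sander energy below the
    bond threshold, for sequence offsets donor - acceptor in {3, 4, 5}."""
    res = chain.residues
    bonds = set()
    for j in range(1, len(res)):
        donor, prev = res[j], res[j - 1]
        for k in (3, 4, 5):
            i = j - k
            if i < 0:
                continue
            e = kabsch_sander_energy(res[i], donor, prev)
            if e is not None and e < C.KS_HBOND_CUTOFF:
                bonds.add((j, i))
    return bonds


def parse_dssp_states(path) -> dict[tuple[str, int, str], str]:
    """Read per-residue summary states from a standard DSSP output file."""
    states: dict[tuple[str, int, str], str] = {}
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        if line[13] == "!":
            continue
        try:
            seq_num = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        chain_id = line[11].strip()
        ss = line[16]
        states[(chain_id, seq_num, icode)] = ss
    return states


def assign_helix_states(
    chain: ChainModel, mode: str = "internal", dssp_path=None
) -> ChainModel:
    """Label residues 'H' (alpha-helical) either internally or from DSSP output.

    Internal mode evaluates the Kabsch–Sander electrostatic hydrogen-bond
    energy and applies the DSSP 4-helix rule: residues i+1 … i+4 are
    helical when both (i, i+4) and (i+1, i+5) amide→carbonyl bonds exist.
    ``dssp_file`` mode reads the summary states of a standard DSSP output
    and maps its 'H' records onto the chain.
    """
    res = chain.residues
    for r in res:
        r.ss_state = "-"
    if mode == "dssp_file":
        if dssp_path is None:
            raise ValueError("dssp_file mode requires dssp_path")
        states = parse_dssp_states(dssp_path)
        unmatched = [
            (r.chain_id, r.seq_num, r.insertion_code)
            for r in res
            if (r.chain_id, r.seq_num, r.insertion_code) not in states
        ]
        if unmatched:
            raise DsspAlignmentError(
                f"{len(unmatched)} chain residues missing from DSSP file: "
                f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}"
            )
        for r in res:
            if states[(r.chain_id, r.seq_num, r.insertion_code)] == "H":
                r.ss_state = "H"
        return chain
    if mode != "internal":
        raise ValueError(f"unknown mode: {mode!r}")

    bonds = _internal_hbond_set(chain)

    def turn4(i: int) -> bool:
        return (i + 4, i) in bonds

    for i in range(len(res)):
        if turn4(i) and turn4(i + 1):
            for j in range(i + 1, min(i + 5, len(res))):
                res[j].ss_state = "H"
    return chain
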