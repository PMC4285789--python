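"""Per-residue annotations: hydrogen bonds, solvent accessibility,
hydrophobicity, and profile-based amino-acid frequencies from an ingested
multiple sequence alignment.

Backbone hydrogen bonds use the Kabsch–Sander electrostatic energy;
sidechain-to-backbone bonds use a distance–angle rule.  Solvent accessible
surface area is Shrake–Rupley with a deterministic golden-spiral point set,
expressed relative to extended Gly-X-Gly maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import constants as C
from ._geom import angle_between
from .errors import ProfileMappingError
from .structure_model import ChainModel, kabsch_sander_energy

__all__ = [
    "HBondRecord",
    "SequenceProfile",
    "HydrophobicityScale",
    "backbone_hbonds",
    "sidechain_backbone_hbonds",
    "relative_sasa",
    "shrake_rupley_sasa",
    "sequence_weights",
    "build_profile",
    "position_hydrophobicity",
    "read_fasta_alignment",
]


@dataclass
class HBondRecord:
    """A detected hydrogen bond between chain residues (0-based indices)."""

    donor_idx: int
    acceptor_idx: int
    kind: str  # bb_i3 | bb_i4 | bb_i5 | sidechain_backbone
    energy_or_geometry: object  # kcal/mol for backbone; (distance Å, angle °) else

    def __post_init__(self):
        offsets = {"bb_i3": 3, "bb_i4": 4, "bb_i5": 5}
        if self.kind in offsets and self.donor_idx - self.acceptor_idx != offsets[self.kind]:
            raise ValueError(
                f"{self.kind} requires donor - acceptor = {offsets[self.kind]}"
            )


def backbone_hbonds(chain: ChainModel) -> list[HBondRecord]:
    """Backbone amide→carbonyl bonds at sequence offsets 3, 4 and 5.

    A record is emitted when the Kabsch–Sander energy is below the bond
    threshold.  Proline never appears as a donor (no amide proton); pairs
    with missing atoms are skipped (unassessable).
    """
    res = chain.residues
    out = []
    for j in range(1, len(res)):
        donor, prev = res[j], res[j - 1]
        for k in (3, 4, 5):
            i = j - k
            if i < 0:
                continue
            e = kabsch_sander_energy(res[i], donor, prev)
            if e is not None and e < C.KS_HBOND_CUTOFF:
                out.append(
                    HBondRecord(
                        donor_idx=j,
                        acceptor_idx=i,
                        kind=f"bb_i{k}",
                        energy_or_geometry=e,
                    )
                )
    return out


def assessable_i4_pairs(chain: ChainModel) -> list[int]:
    """Acceptor indices i whose (i+4 → i) bond can be evaluated: both the
    acceptor carbonyl and the donor amide construction atoms exist and the
    donor is not Proline."""
    res = chain.residues
    out = []
    for i in range(len(res) - 4):
        j = i + 4
        donor, prev = res[j], res[j - 1]
        if donor.aa == "P":
            continue
        if (
            res[i].coords_C is not None
            and res[i].coords_O is not None
            and donor.coords_N is not None
            and prev.coords_C is not None
            and prev.coords_O is not None
        ):
            out.append(i)
    return out


def sidechain_backbone_hbonds(chain: ChainModel) -> list[HBondRecord]:
    """Sidechain polar donor → backbone O/N bonds by geometry.

    Criterion: donor heavy atom within 3.5 Å of the acceptor and the
    antecedent–donor–acceptor angle ≥ 90° (skipped if the antecedent atom
    is absent).
    """
    res = chain.residues
    out = []
    for di, dres in enumerate(res):
        for donor_name, antecedent in C.SIDECHAIN_DONORS.get(dres.aa, []):
            dpos = dres.extra_atoms.get(donor_name)
            if dpos is None:
                continue
            ante = dres.atom(antecedent)
            for ai, ares in enumerate(res):
                if ai == di:
                    continue
                for acc_name in ("O", "N"):
                    apos = ares.atom(acc_name)
                    if apos is None:
                        continue
                    dist = float(np.linalg.norm(apos - dpos))
                    if dist > C.SC_HBOND_MAX_DIST:
                        continue
                    if ante is not None:
                        ang = angle_between(ante - dpos, apos - dpos)
                        if ang < C.SC_HBOND_MIN_ANGLE:
                            continue
                    else:
                        ang = float("nan")
                    out.append(
                        HBondRecord(
                            donor_idx=di,
                            acceptor_idx=ai,
                            kind="sidechain_backbone",
                            energy_or_geometry=(dist, ang),
                        )
                    )
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


def shrake_rupley_sasa(
    chain: ChainModel,
    probe: float = C.SASA_PROBE_RADIUS,
    n_points: int = C.SASA_N_SPHERE_POINTS,
) -> np.ndarray:
    """Absolute accessible surface area (Å²) per residue, all heavy atoms."""
    atoms = []
    owners = []
    radii = []
    for ri, r in enumerate(chain.residues):
        for name, xyz in r.heavy_atoms():
            atoms.append(xyz)
            owners.append(ri)
            radii.append(C.VDW_RADII.get(_element_of(name), C.VDW_DEFAULT) + probe)
    if not atoms:
        return np.zeros(len(chain.residues))
    coords = np.asarray(atoms)
    radii = np.asarray(radii)
    owners = np.asarray(owners)
    sphere = _sphere_points(n_points)
    areas = np.zeros(len(chain.residues))
    for k in range(len(coords)):
        pts = coords[k] + radii[k] * sphere
        # neighbors that could occlude
        d = np.linalg.norm(coords - coords[k], axis=1)
        nb = np.flatnonzero((d < radii + radii[k]) & (d > 0))
        if len(nb):
            dist2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (dist2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[owners[k]] += frac * 4.0 * np.pi * radii[k] ** 2
    return areas


def relative_sasa(
    chain: ChainModel,
    probe: float = C.SASA_PROBE_RADIUS,
    n_points: int = C.SASA_N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-residue accessible area as a fraction of the residue type's
    extended Gly-X-Gly maximum, clipped to [0, 1]; NaN for residues with
    no atoms."""
    abs_area = shrake_rupley_sasa(chain, probe=probe, n_points=n_points)
    out = np.full(len(chain.residues), np.nan)
    for i, r in enumerate(chain.residues):
        if not r.heavy_atoms():
            continue
        ref = C.MAX_SASA_GLY_X_GLY.get(r.aa)
        if ref is None:
            ref = float(np.mean(list(C.MAX_SASA_GLY_X_GLY.values())))
        out[i] = min(1.0, abs_area[i] / ref)
    return out


@dataclass
class HydrophobicityScale:
    """Amino acid → transfer free energy (kcal/mol)."""

    values: dict = field(default_factory=lambda: dict(C.INTERFACE_OCTANOL_DG))

    def __post_init__(self):
        missing = set(C.AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale missing amino acids: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path) -> "HydrophobicityScale":
        values = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, dg = line.split("\t")[:2]
            values[aa.strip()] = float(dg)
        return cls(values=values)


def read_fasta_alignment(path) -> list[tuple[str, str]]:
    """(id, aligned sequence) pairs from an aligned FASTA file."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def sequence_weights(msa: list) -> np.ndarray:
    """Per-sequence weights: dissimilar sequences weigh more.

    Weight ∝ 1 − (mean fractional identity to all other sequences),
    floored at a small positive constant and normalized to sum 1.
    """
    seqs = [s if isinstance(s, str) else s[1] for s in msa]
    n = len(seqs)
    if n == 0:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    if n == 1:
        return np.array([1.0])
    arr = np.array([list(s) for s in seqs])
    ident = np.zeros(n)
    for i in range(n):
        others = np.arange(n) != i
        # fractional identity over columns where at least one is non-gap
        eq = (arr[others] == arr[i][None, :]).mean(axis=1)
        ident[i] = eq.mean()
    w = np.maximum(1.0 - ident, 1e-3)
    return w / w.sum()


@dataclass
class SequenceProfile:
    """Per-position amino-acid frequency vectors for one helix.

    ``freqs`` has shape (n_positions, 20) in the order of the standard
    one-letter alphabet; each covered position sums to 1.  ``coverage``
    flags positions with at least one non-gap observation.
    """

    freqs: np.ndarray
    n_sequences: int
    weights: np.ndarray
    coverage: np.ndarray

    def frequency(self, position: int, aa: str) -> float:
        return float(self.freqs[position, C.AMINO_ACIDS.index(aa)])


def build_profile(
    msa: list,
    weights: Optional[np.ndarray],
    structure_seq: str,
) -> SequenceProfile:
    """Weighted per-position frequencies for ``structure_seq``'s positions.

    The first MSA row whose ungapped sequence contains ``structure_seq``
    maps structure positions to alignment columns; gap characters are
    excluded with frequencies renormalized over observed residues.
    """
    pairs = [(s if isinstance(s, str) else s[1]) for s in msa]
    if not pairs:
        raise ProfileMappingError("empty alignment")
    if weights is None:
        weights = sequence_weights(msa)
    weights = np.asarray(weights, dtype=float)

    # locate the structure row and the helix within it
    row_idx = col_map = None
    for ri, aligned in enumerate(pairs):
        ungapped = aligned.replace("-", "").replace(".", "")
        pos = ungapped.find(structure_seq)
        if pos < 0:
            continue
        cols = [ci for ci, ch in enumerate(aligned) if ch not in "-."]
        col_map = cols[pos : pos + len(structure_seq)]
        row_idx = ri
        break
    if row_idx is None:
        raise ProfileMappingError(
            "structure sequence not found ungapped in any alignment row"
        )

    n_pos = len(structure_seq)
    freqs = np.zeros((n_pos, 20))
    coverage = np.zeros(n_pos, dtype=bool)
    aa_index = {a: k for k, a in enumerate(C.AMINO_ACIDS)}
    for p, col in enumerate(col_map):
        for s, w in zip(pairs, weights):
            k = aa_index.get(s[col])
            if k is not None:
                freqs[p, k] += w
        total = freqs[p].sum()
        if total > 0:
            freqs[p] /= total
            coverage[p] = True
    return SequenceProfile(
        freqs=freqs,
        n_sequences=len(pairs),
        weights=weights,
        coverage=coverage,
    )


def position_hydrophobicity(
    profile: SequenceProfile, scale: Optional[HydrophobicityScale] = None
) -> np.ndarray:
    """Frequency-weighted mean transfer free energy per position (kcal/mol)."""
    scale = scale or HydrophobicityScale()
    dg = np.array([scale.values[a] for a in C.AMINO_ACIDS])
    return profile.freqs @ dg
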