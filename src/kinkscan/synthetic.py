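"""Synthetic ground-truth generators.

Builds ideal α-helical backbones from standard internal coordinates (with
φ/ψ solved numerically to realize a target rise and twist), inserts kinks
of known angle, position and direction as rigid rotations of the
C-terminal half, adds seeded coordinate noise, and generates sequence
corpora with planted motifs.  These generators define the study conditions
under which the detection machinery is validated: every geometric truth
(kink position, angle, bend direction) is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from . import constants as C
from ._geom import (
    kabsch_rotation,
    normalize,
    place_atom,
    rotation_about_axis,
    screw_parameters,
)
from .structure_model import ChainModel, ResidueRecord

__all__ = [
    "HelixSpec",
    "build_ideal_helix",
    "build_helix",
    "insert_kink",
    "build_backbone",
    "random_helix_sequences",
    "helix_axis_from_trace",
    "write_pdb",
]


@dataclass
class HelixSpec:
    """Recipe for one synthetic helix.

    ``kinks`` is a list of ``(position, angle_deg, azimuth_deg)`` tuples;
    azimuth 0 bends the helix toward that position's own Cα (wobble ≈ 0
    there), azimuth 180 bends directly away from it.  ``ca_radius`` is the
    nominal Cα radius of the ideal parametrization; the realized radius is
    set by the backbone internal coordinates (≈ 2.27 Å at the default
    rise/twist) and is not an independent dial.
    """

    length: int = 30
    rise: float = C.IDEAL_RISE
    twist: float = C.IDEAL_TWIST
    ca_radius: float = C.IDEAL_CA_RADIUS
    kinks: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 5:
            raise ValueError("helix length must be >= 5")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length mismatch")
        for pos, angle, _az in self.kinks:
            if not (0.0 <= angle <= 90.0):
                raise ValueError("kink angle must be in [0, 90] degrees")
            if not (7 <= pos <= self.length - 7):
                raise ValueError(
                    f"kink position {pos} outside detectable range "
                    f"[7, {self.length - 7}]"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def build_backbone(
    phi: Sequence[float],
    psi: Sequence[float],
    sequence: Optional[str] = None,
    chain_id: str = "A",
    pdb_id: str = "synt",
    tau: float = C.ANGLE_N_CA_C,
) -> ChainModel:
    """Sequentially place N, Cα, C, O atoms from per-residue (φ, ψ).

    φ of the first residue and ψ of the last are not geometrically needed
    but must be supplied (any value) so the lists have one entry per
    residue.  ω is fixed trans; ``tau`` is the N-Cα-C angle, which flexes a
    few degrees in real helices and is the third degree of freedom the
    rise/twist solver uses.
    """
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi/psi length mismatch")
    seq = sequence or "A" * n_res

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    CC = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([C.BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - tau)
    CC[0] = CA[0] + C.BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res - 1):
        N[i + 1] = place_atom(
            N[i], CA[i], CC[i], C.BOND_C_N, C.ANGLE_CA_C_N, psi[i]
        )
        CA[i + 1] = place_atom(
            CA[i], CC[i], N[i + 1], C.BOND_N_CA, C.ANGLE_C_N_CA, C.OMEGA_TRANS
        )
        CC[i + 1] = place_atom(
            CC[i], N[i + 1], CA[i + 1], C.BOND_CA_C, tau, phi[i + 1]
        )
        # carbonyl O: sp2, in the peptide plane, anti to the next N
        v1 = normalize(CA[i] - CC[i])
        v2 = normalize(N[i + 1] - CC[i])
        O[i] = CC[i] - C.BOND_C_O * normalize(v1 + v2)
    # last O from the final psi (direction only matters cosmetically)
    O[n_res - 1] = place_atom(
        N[n_res - 1],
        CA[n_res - 1],
        CC[n_res - 1],
        C.BOND_C_O,
        C.ANGLE_CA_C_O,
        psi[n_res - 1] + 180.0,
    )

    chain = ChainModel(pdb_id=pdb_id, chain_id=chain_id)
    for i in range(n_res):
        chain.residues.append(
            ResidueRecord(
                chain_id=chain_id,
                seq_num=i + 1,
                aa=seq[i],
                name=C.ONE_TO_THREE.get(seq[i], "UNK"),
                coords_N=N[i].copy(),
                coords_CA=CA[i].copy(),
                coords_C=CC[i].copy(),
                coords_O=O[i].copy(),
                # construction values; chain termini included, so seed tests
                # are well defined from residue 0
                phi=float(phi[i]),
                psi=float(psi[i]),
            )
        )
    return chain


def helix_axis_from_trace(ca: np.ndarray):
    """Axis point/direction and helical parameters from a Cα trace.

    Treats the map Cα(i) → Cα(i+1) as one screw motion (exact for an ideal
    helix, least-squares averaged otherwise).  Returns
    ``(point, direction, radius, twist_deg, rise)`` with ``direction``
    oriented N→C.
    """
    ca = np.asarray(ca, dtype=float)
    if len(ca) < 5:
        raise ValueError("need at least 5 Cα positions")
    r, t = kabsch_rotation(ca[:-1], ca[1:])
    axis, twist, rise = screw_parameters(r, t)
    # point on the axis: solve (I - R) p = t - rise*axis in least squares
    b = t - rise * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - r, b, rcond=None)
    p = p - np.dot(p, axis) * axis + np.dot(ca.mean(axis=0), axis) * axis
    rel = ca - p
    rel -= np.outer(rel @ axis, axis)
    radius = float(np.mean(np.linalg.norm(rel, axis=1)))
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return p, axis, radius, twist, rise


@lru_cache(maxsize=32)
def _solve_phi_psi(rise: float, twist: float) -> tuple[float, float, float]:
    """(φ, ψ, τ) realizing the target rise/twist.

    Bond lengths and the other bond angles stay at standard values; the
    N-Cα-C angle τ is allowed to flex (softly penalized toward its standard
    value) because rise and twist are not independently reachable with a
    fully rigid backbone.
    """
    from scipy.optimize import least_squares

    def residuals(x):
        phi, psi, tau = x
        ch = build_backbone([phi] * 12, [psi] * 12, tau=tau)
        ca = np.array([r.coords_CA for r in ch.residues])
        _, _, _, tw, ri = helix_axis_from_trace(ca)
        return [ri - rise, tw - twist, 1e-3 * (tau - C.ANGLE_N_CA_C)]

    sol = least_squares(
        residuals,
        x0=[C.ALPHA_PHI, C.ALPHA_PSI, C.ANGLE_N_CA_C],
        xtol=1e-14,
        ftol=1e-14,
        diff_step=1e-4,
    )
    if not sol.success or max(abs(sol.fun[0]), abs(sol.fun[1])) > 1e-4:
        raise RuntimeError(
            f"could not realize rise={rise}, twist={twist} with standard "
            "backbone geometry"
        )
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def _all_coords(chain: ChainModel):
    for res in chain.residues:
        for a in ("N", "CA", "C", "O"):
            xyz = getattr(res, f"coords_{a}")
            if xyz is not None:
                yield res, a, xyz


def _apply_noise(chain: ChainModel, sd: float, seed: int) -> ChainModel:
    rng = np.random.default_rng(seed)
    for res, a, xyz in _all_coords(chain):
        setattr(res, f"coords_{a}", xyz + rng.normal(0.0, sd, size=3))
    return chain


def build_ideal_helix(spec: HelixSpec) -> ChainModel:
    """Straight ideal helix for the spec's rise/twist (kinks ignored here)."""
    phi, psi, tau = _solve_phi_psi(spec.rise, spec.twist)
    chain = build_backbone(
        [phi] * spec.length, [psi] * spec.length, sequence=spec.sequence, tau=tau
    )
    if spec.noise_sd > 0:
        _apply_noise(chain, spec.noise_sd, spec.seed)
    return chain


def insert_kink(
    chain: ChainModel, position: int, angle: float, azimuth: float = 0.0
) -> ChainModel:
    """Rigidly rotate everything C-terminal of ``position``'s Cα.

    The rotation axis passes through that Cα, perpendicular to the local
    helix axis; ``azimuth`` picks the bend direction around the axis, with
    0 bending toward the position's own Cα.  The true kink angle equals
    ``angle`` by construction.
    """
    n = len(chain.residues)
    if not (5 <= position <= n - 6):
        raise ValueError(f"kink position {position} out of range for length {n}")
    if angle == 0.0:
        return chain
    ca = np.array([r.coords_CA for r in chain.residues])
    point, d, _, _, _ = helix_axis_from_trace(ca)
    ca_k = ca[position]
    radial = ca_k - point
    radial -= np.dot(radial, d) * d
    u = normalize(radial)  # axis → Cα, the azimuth-0 bend direction
    u_bend = rotation_about_axis(d, azimuth) @ u
    rot_axis = normalize(np.cross(d, u_bend))
    R = rotation_about_axis(rot_axis, angle)

    def rotate(xyz):
        return R @ (xyz - ca_k) + ca_k

    for i, res in enumerate(chain.residues):
        if i < position:
            continue
        names = ("C", "O") if i == position else ("N", "CA", "C", "O")
        for a in names:
            xyz = getattr(res, f"coords_{a}")
            if xyz is not None:
                setattr(res, f"coords_{a}", rotate(xyz))
        if i > position:
            for a, xyz in res.extra_atoms.items():
                res.extra_atoms[a] = rotate(xyz)
    return chain


def build_helix(spec: HelixSpec) -> ChainModel:
    """Ideal helix with the spec's kinks inserted, then noise applied."""
    base = HelixSpec(
        length=spec.length,
        rise=spec.rise,
        twist=spec.twist,
        ca_radius=spec.ca_radius,
        sequence=spec.sequence,
    )
    chain = build_ideal_helix(base)
    for pos, angle, az in spec.kinks:
        insert_kink(chain, pos, angle, az)
    if spec.noise_sd > 0:
        _apply_noise(chain, spec.noise_sd, spec.seed)
    return chain


def random_helix_sequences(
    n: int,
    length_dist=13,
    aa_freqs: Optional[dict] = None,
    planted: Optional[tuple] = None,
    seed: int = 0,
):
    """Paired kinked/straight sequence corpora with known planted truth.

    Returns ``(kinked, straight)``: ``kinked`` is a list of
    ``(sequence, kink_position)`` (kink at the sequence midpoint),
    ``straight`` a list of sequences.  ``planted = (motif, offset,
    fraction)`` writes the literal ``motif`` starting at kink-relative
    ``offset`` in exactly a Bernoulli(``fraction``) subset of the kinked
    sequences and guarantees its absence at that offset in the rest, so the
    realized positional frequency equals ``fraction``.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(C.AMINO_ACIDS))
    if aa_freqs is None:
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.array([aa_freqs.get(a, 0.0) for a in C.AMINO_ACIDS])
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("aa_freqs must sum to 1")

    def draw_length():
        if isinstance(length_dist, int):
            return length_dist
        if isinstance(length_dist, dict):
            ls = np.array(sorted(length_dist))
            ps = np.array([length_dist[l] for l in ls], dtype=float)
            return int(rng.choice(ls, p=ps / ps.sum()))
        return int(rng.choice(np.asarray(length_dist)))

    def draw_seq(length):
        return "".join(rng.choice(aas, size=length, p=probs))

    kinked = []
    straight = []
    for _ in range(n):
        L = draw_length()
        seq = list(draw_seq(L))
        kpos = L // 2
        if planted is not None:
            motif, offset, fraction = planted
            start = kpos + offset
            if not (0 <= start and start + len(motif) <= L):
                raise ValueError("planted motif does not fit in the sequence")
            if rng.random() < fraction:
                seq[start : start + len(motif)] = list(motif)
            else:
                # guarantee absence of the motif at the planted offset
                while "".join(seq[start : start + len(motif)]) == motif:
                    seq[start : start + len(motif)] = list(draw_seq(len(motif)))
        kinked.append(("".join(seq), kpos))
        straight.append(draw_seq(draw_length()))
    return kinked, straight


def write_pdb(chains, path) -> None:
    """Write one or more ChainModels as a PDB file."""
    if isinstance(chains, ChainModel):
        chains = [chains]
    st = gemmi.Structure()
    st.name = chains[0].pdb_id
    model = gemmi.Model(1)
    for cm in chains:
        ch = gemmi.Chain(cm.chain_id)
        for rec in cm.residues:
            res = gemmi.Residue()
            res.name = rec.name
            res.seqid = gemmi.SeqId(rec.seq_num, rec.insertion_code or " ")
            for a, xyz in (
                ("N", rec.coords_N),
                ("CA", rec.coords_CA),
                ("C", rec.coords_C),
                ("O", rec.coords_O),
            ):
                if xyz is None:
                    continue
                atom = gemmi.Atom()
                atom.name = a
                atom.element = gemmi.Element(a[0])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                res.add_atom(atom)
            for a, xyz in rec.extra_atoms.items():
                atom = gemmi.Atom()
                atom.name = a
                atom.element = gemmi.Element(a[0])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
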