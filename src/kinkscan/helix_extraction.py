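"""Build the analyzable helix set from per-residue helix states.

Maximal helical runs are merged across 1-2 residue coil gaps, split where
a local kink angle exceeds 60°, trimmed back to five-residue "helical
seeds" at both ends, optionally trimmed to the membrane, and finally
filtered to length ≥ 13 (the shortest helix for which a kink angle exists
plus one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from ._geom import angle_between
from .structure_model import ChainModel, ResidueRecord

__all__ = [
    "Helix",
    "MembraneAnnotation",
    "merge_helical_segments",
    "split_on_large_kink",
    "is_helical_seed",
    "trim_helix_ends",
    "trim_to_membrane",
    "extract_helices",
    "helices_to_dataframe",
    "SEED_ANGLE_RANGES",
    "SEED_IDEAL_DISTANCES",
]

MIN_HELIX_LENGTH = 13
SPLIT_THRESHOLD = 60.0
SEED_DISTANCE_TOL = 0.5

# Expected Cα(1)→Cα(1+x) inter-vector angle ranges for x = 2, 3, 4 in an
# ideal alpha helix (degrees).
SEED_ANGLE_RANGES = {2: (35.0, 50.0), 3: (60.0, 80.0), 4: (45.0, 65.0)}


def _ideal_ca_distance(x: int) -> float:
    """|Cα(1)-Cα(1+x)| of the ideal parametrization (radius 2.3 Å,
    rise 1.5 Å/res, twist 100°/res)."""
    chord = 2.0 * C.IDEAL_CA_RADIUS * abs(
        np.sin(np.radians(x * C.IDEAL_TWIST / 2.0))
    )
    return float(np.hypot(chord, x * C.IDEAL_RISE))


SEED_IDEAL_DISTANCES = {x: _ideal_ca_distance(x) for x in (2, 3, 4)}


@dataclass
class Helix:
    """A contiguous run of chain residues treated as one helix."""

    chain_ref: tuple
    residues: list
    start_idx: int
    end_idx: int
    provenance: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def is_empty(self) -> bool:
        return not self.residues

    @classmethod
    def from_chain(cls, chain: ChainModel, start: int, end: int, provenance=None):
        return cls(
            chain_ref=(chain.pdb_id, chain.chain_id),
            residues=chain.residues[start : end + 1],
            start_idx=start,
            end_idx=end,
            provenance=list(provenance or []),
        )

    def subhelix(self, lo: int, hi: int, note=None) -> "Helix":
        """New Helix from local indices [lo, hi] (inclusive)."""
        h = Helix(
            chain_ref=self.chain_ref,
            residues=self.residues[lo : hi + 1],
            start_idx=self.start_idx + lo,
            end_idx=self.start_idx + hi,
            provenance=list(self.provenance),
        )
        if note:
            h.provenance.append(note)
        return h


@dataclass
class MembraneAnnotation:
    """Per-residue membrane region labels (tail / head / outside / unknown),
    keyed by (pdb_id, chain_id, seq_num, insertion_code)."""

    labels: dict = field(default_factory=dict)

    VALID = frozenset({"tail", "head", "outside", "unknown"})

    def __post_init__(self):
        bad = {v for v in self.labels.values()} - self.VALID
        if bad:
            raise ValueError(f"invalid membrane region labels: {sorted(bad)}")

    def label(self, pdb_id: str, res: ResidueRecord) -> str:
        return self.labels.get(
            (pdb_id, res.chain_id, res.seq_num, res.insertion_code), "unknown"
        )

    @classmethod
    def from_tsv(cls, path) -> "MembraneAnnotation":
        df = pd.read_csv(Path(path), sep="\t", comment="#", dtype=str).fillna("")
        labels = {}
        for row in df.itertuples(index=False):
            labels[
                (row.pdb_id, row.chain_id, int(row.seq_num), row.insertion_code)
            ] = row.region
        return cls(labels=labels)


def merge_helical_segments(chain: ChainModel) -> list[Helix]:
    """Maximal H-runs, joined across gaps of one or two non-H residues.

    Joining is transitive, applied left-to-right on the original state
    string; the gap residues are included in the merged candidate.
    """
    ss = chain.ss_string()
    runs = []
    i = 0
    while i < len(ss):
        if ss[i] == "H":
            j = i
            while j < len(ss) and ss[j] == "H":
                j += 1
            runs.append([i, j - 1])
            i = j
        else:
            i += 1
    merged: list[list] = []  # [start, end, was_merged]
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 <= 2:
            merged[-1][1] = end
            merged[-1][2] = True
        else:
            merged.append([start, end, False])
    return [
        Helix.from_chain(chain, s, e, provenance=["merged"] if m else [])
        for s, e, m in merged
    ]


def split_on_large_kink(helix: Helix, threshold_deg: float = SPLIT_THRESHOLD) -> list[Helix]:
    """Recursively divide a helix wherever a local kink angle exceeds the
    threshold; the max-angle residue starts the C-terminal fragment."""
    from .kink_geometry import local_kink_angles

    if helix.length < 12:
        return [helix]
    geom = local_kink_angles(helix)
    if np.all(np.isnan(geom.kink_angle)):
        return [helix]
    i = int(np.nanargmax(geom.kink_angle))
    if geom.kink_angle[i] <= threshold_deg:
        return [helix]
    left = helix.subhelix(0, i - 1, note=f"split_at:{helix.start_idx + i}")
    right = helix.subhelix(i, helix.length - 1, note=f"split_at:{helix.start_idx + i}")
    return split_on_large_kink(left, threshold_deg) + split_on_large_kink(
        right, threshold_deg
    )


def is_helical_seed(residues) -> bool:
    """Five consecutive residues form a helical seed.

    Requires (1) the first residue's (φ, ψ) inside the alpha region,
    (2) the angle between Cα(1)→Cα(2) and Cα(1)→Cα(1+x) inside the ideal
    ranges for x = 2, 3, 4, and (3) each |Cα(1)−Cα(1+x)| distance within
    0.5 Å of the ideal-helix value.  Missing atoms or dihedrals fail the
    test with a warning rather than raising.
    """
    if len(residues) != 5:
        raise ValueError("helical seed test needs exactly 5 residues")
    r0 = residues[0]
    cas = [r.coords_CA for r in residues]
    if any(ca is None for ca in cas):
        warnings.warn("helical seed test: missing Cα coordinate")
        return False
    if r0.phi is None or r0.psi is None:
        warnings.warn("helical seed test: undefined phi/psi on first residue")
        return False
    lo, hi = C.ALPHA_REGION_PHI
    if not (lo <= r0.phi <= hi):
        return False
    lo, hi = C.ALPHA_REGION_PSI
    if not (lo <= r0.psi <= hi):
        return False
    v1 = cas[1] - cas[0]
    for x in (2, 3, 4):
        vx = cas[x] - cas[0]
        lo, hi = SEED_ANGLE_RANGES[x]
        if not (lo <= angle_between(v1, vx) <= hi):
            return False
        if abs(float(np.linalg.norm(vx)) - SEED_IDEAL_DISTANCES[x]) > SEED_DISTANCE_TOL:
            return False
    return True


def trim_helix_ends(helix: Helix) -> Helix:
    """Iteratively remove end residues until both five-residue ends are
    helical seeds; empty result if fewer than five residues remain."""
    lo, hi = 0, helix.length - 1
    trimmed_n = trimmed_c = 0
    while hi - lo + 1 >= 5 and not is_helical_seed(helix.residues[lo : lo + 5]):
        lo += 1
        trimmed_n += 1
    while hi - lo + 1 >= 5 and not is_helical_seed(helix.residues[hi - 4 : hi + 1]):
        hi -= 1
        trimmed_c += 1
    if hi - lo + 1 < 5:
        return Helix(
            chain_ref=helix.chain_ref,
            residues=[],
            start_idx=helix.start_idx,
            end_idx=helix.start_idx - 1,
            provenance=list(helix.provenance) + ["trimmed_away"],
        )
    out = helix.subhelix(lo, hi)
    if trimmed_n:
        out.provenance.append(f"trimmed_n:{trimmed_n}")
    if trimmed_c:
        out.provenance.append(f"trimmed_c:{trimmed_c}")
    return out


def trim_to_membrane(
    helix: Helix, ann: MembraneAnnotation, max_outside: int = 5
) -> Helix:
    """Trim so that at most ``max_outside`` consecutive terminal residues lie
    outside the membrane; reject helices with no tail-region residues."""
    pdb_id = helix.chain_ref[0]
    labels = [ann.label(pdb_id, r) for r in helix.residues]

    def empty():
        return Helix(
            chain_ref=helix.chain_ref,
            residues=[],
            start_idx=helix.start_idx,
            end_idx=helix.start_idx - 1,
            provenance=list(helix.provenance) + ["membrane_trimmed"],
        )

    def is_outside(lab: str) -> bool:
        return lab in ("outside", "unknown")

    n_out = 0
    while n_out < len(labels) and is_outside(labels[n_out]):
        n_out += 1
    c_out = 0
    while c_out < len(labels) - n_out and is_outside(labels[-1 - c_out]):
        c_out += 1
    lo = max(0, n_out - max_outside)
    hi = len(labels) - 1 - max(0, c_out - max_outside)
    if lo > hi:
        return empty()
    if "tail" not in labels[lo : hi + 1]:
        return empty()
    if lo == 0 and hi == len(labels) - 1:
        return helix
    return helix.subhelix(lo, hi, note="membrane_trimmed")


def extract_helices(
    chain: ChainModel,
    ann: MembraneAnnotation | None = None,
    split_threshold: float = SPLIT_THRESHOLD,
    min_length: int = MIN_HELIX_LENGTH,
    max_outside: int = 5,
) -> list[Helix]:
    """Full extraction: merge → split(>60°) → trim ends → membrane trim →
    drop helices shorter than ``min_length`` residues."""
    out: list[Helix] = []
    for cand in merge_helical_segments(chain):
        for frag in split_on_large_kink(cand, split_threshold):
            if frag.length < 5:
                continue
            h = trim_helix_ends(frag)
            if h.is_empty():
                continue
            if ann is not None:
                h = trim_to_membrane(h, ann, max_outside)
                if h.is_empty():
                    continue
            if h.length >= min_length:
                out.append(h)
    return out


def helices_to_dataframe(helices: list[Helix]) -> pd.DataFrame:
    """One row per helix: chain reference, author numbering span, length,
    sequence and provenance."""
    rows = []
    for i, h in enumerate(helices):
        first, last = h.residues[0], h.residues[-1]
        rows.append(
            {
                "helix_id": i,
                "pdb_id": h.chain_ref[0],
                "chain_id": h.chain_ref[1],
                "start_auth": f"{first.seq_num}{first.insertion_code}",
                "end_auth": f"{last.seq_num}{last.insertion_code}",
                "length": h.length,
                "sequence": h.sequence,
                "provenance": ";".join(h.provenance),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "helix_id", "pdb_id", "chain_id", "start_auth", "end_auth",
            "length", "sequence", "provenance",
        ],
    )
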