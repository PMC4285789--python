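"""Turn per-residue angle profiles into kink calls and helix labels.

A helix's first kink sits at its largest local angle if that angle exceeds
the detection threshold (20° by default); further kinks are accepted in
descending angle order when they are at least four residues away from every
accepted kink and separated from each by a residue with angle ≤ 10°.  The
kink *residue* is then chosen from the peak residue, the one before and the
two after, as the candidate whose wobble angle is closest to 0° — the
residue on the inside of the bend — which geometrically aligns kinks
across helices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kink_geometry import HelixGeometry

__all__ = [
    "KinkCall",
    "HelixClassification",
    "find_kinks",
    "select_kink_residue",
    "classify_helix",
    "KINK_THRESHOLD",
    "STRAIGHT_THRESHOLD",
]

KINK_THRESHOLD = 20.0
STRAIGHT_THRESHOLD = 14.0
MIN_SEPARATION = 4
VALLEY = 10.0


@dataclass
class KinkCall:
    """One detected kink: the peak-angle residue, the wobble-selected kink
    residue, and the angles at both."""

    helix_ref: object
    peak_idx: int
    kink_idx: int
    angle: float
    wobble_at_kink: float


@dataclass
class HelixClassification:
    helix_ref: object
    max_angle: float
    label: str  # kinked | straight | intermediate
    kinks: list = field(default_factory=list)


def select_kink_residue(geom: HelixGeometry, peak_idx: int) -> int:
    """Among {peak-1, peak, peak+1, peak+2} with defined wobble, the index
    minimizing |wobble|; ties break toward the lower index."""
    if np.isnan(geom.kink_angle[peak_idx]):
        raise ValueError(f"kink angle undefined at residue {peak_idx}")
    candidates = [
        i
        for i in (peak_idx - 1, peak_idx, peak_idx + 1, peak_idx + 2)
        if 0 <= i < len(geom.wobble) and not np.isnan(geom.wobble[i])
    ]
    if not candidates:
        warnings.warn(
            f"no candidate with defined wobble around peak {peak_idx}; "
            "falling back to the peak residue"
        )
        return peak_idx
    return min(candidates, key=lambda i: (abs(geom.wobble[i]), i))


def find_kinks(
    geom: HelixGeometry,
    threshold: float = KINK_THRESHOLD,
    min_separation: int = MIN_SEPARATION,
    valley: float = VALLEY,
) -> list[KinkCall]:
    """Accept kinks from the angle profile.

    The first (largest-angle) kink requires an angle strictly over
    ``threshold``; each further candidate, taken in descending angle
    order, requires angle ≥ ``threshold``, distance ≥ ``min_separation``
    residues from every accepted kink, and an intervening residue with
    angle ≤ ``valley`` between it and every accepted kink.
    """
    angles = geom.kink_angle
    defined = np.flatnonzero(~np.isnan(angles))
    if len(defined) == 0:
        return []
    order = defined[np.argsort(-angles[defined], kind="stable")]
    accepted: list[int] = []
    for idx, i in enumerate(order):
        a = float(angles[i])
        if not accepted:
            if a > threshold:
                accepted.append(int(i))
            else:
                break
            continue
        if a < threshold:
            break
        if any(abs(i - j) < min_separation for j in accepted):
            continue
        ok = True
        for j in accepted:
            lo, hi = min(i, j), max(i, j)
            between = angles[lo + 1 : hi]
            if not np.any(between[~np.isnan(between)] <= valley):
                ok = False
                break
        if ok:
            accepted.append(int(i))

    calls = []
    for peak in sorted(accepted):
        kink_idx = select_kink_residue(geom, peak)
        wob = geom.wobble[kink_idx]
        calls.append(
            KinkCall(
                helix_ref=geom.helix_ref,
                peak_idx=peak,
                kink_idx=kink_idx,
                angle=float(angles[peak]),
                wobble_at_kink=float(wob) if not np.isnan(wob) else float("nan"),
            )
        )
    return calls


def classify_helix(
    geom: HelixGeometry,
    kink_threshold: float = KINK_THRESHOLD,
    straight_threshold: float = STRAIGHT_THRESHOLD,
    **find_kwargs,
) -> HelixClassification:
    """Label a helix kinked (max angle ≥ 20°), straight (≤ 14°) or
    intermediate (between the two; excluded from both comparison sets)."""
    max_angle = geom.max_angle()
    if np.isnan(max_angle):
        label = "straight"
        max_angle = 0.0
    elif max_angle >= kink_threshold:
        label = "kinked"
    elif max_angle <= straight_threshold:
        label = "straight"
    else:
        label = "intermediate"
    kinks = (
        find_kinks(geom, threshold=kink_threshold, **find_kwargs)
        if label == "kinked"
        else []
    )
    return HelixClassification(
        helix_ref=geom.helix_ref, max_angle=float(max_angle), label=label, kinks=kinks
    )
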