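"""Comparative statistics around kinks.

Everything downstream of kink calls lives here: kink-relative numbering
(offset 0 = the kink residue), positional amino-acid propensities as log2
odds against the helix-set background, motif frequency and enrichment
against resampled straight-helix segments, length-matched sampling,
Kolmogorov–Smirnov comparison of angle distributions, helical-wheel
summaries, and broken backbone hydrogen-bond rates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import constants as C
from .errors import LengthMatchError, MotifParseError
from .helix_extraction import Helix
from .kink_detection import HelixClassification, KinkCall
from .residue_annotation import SequenceProfile, assessable_i4_pairs

__all__ = [
    "KinkWindow",
    "PropensityTable",
    "MotifSpec",
    "EnrichmentRow",
    "kink_windows",
    "kink_window_from_sequence",
    "aa_propensity",
    "motif_match",
    "motif_enrichment",
    "length_matched_samples",
    "compare_angle_distributions",
    "wheel_summary",
    "hbond_break_rates",
    "SEGMENT_LENGTH",
]

OFFSETS = tuple(range(-6, 7))
SEGMENT_LENGTH = 13  # residues screened around each kink


@dataclass
class KinkWindow:
    """Residues at kink-relative offsets -6 … +6 (0 = the kink residue).

    ``positions`` maps each available offset to a one-letter amino acid;
    offsets outside the helix are absent.  ``profile_cols`` optionally maps
    offsets to 20-vectors of profile frequencies.
    """

    kink_ref: Optional[KinkCall]
    positions: dict = field(default_factory=dict)
    residue_indices: dict = field(default_factory=dict)
    profile_cols: dict = field(default_factory=dict)

    def segment(self) -> tuple[str, int]:
        """(sequence, index of offset 0) over the available offsets."""
        offs = sorted(self.positions)
        text = "".join(self.positions[o] for o in offs)
        return text, offs.index(0)

    @staticmethod
    def inside_offsets() -> tuple:
        return C.INSIDE_OFFSETS

    @staticmethod
    def outside_offsets() -> tuple:
        return C.OUTSIDE_OFFSETS


def kink_windows(
    kinks: list[KinkCall], profiles: Optional[dict] = None
) -> list[KinkWindow]:
    """One KinkWindow per kink call, clipped at the helix boundaries.

    ``profiles`` optionally maps a helix object (by identity) to its
    SequenceProfile so windows carry profile columns.
    """
    out = []
    for call in kinks:
        helix: Helix = call.helix_ref
        n = helix.length
        w = KinkWindow(kink_ref=call)
        prof: Optional[SequenceProfile] = None
        if profiles is not None:
            prof = profiles.get(id(helix))
        for off in OFFSETS:
            idx = call.kink_idx + off
            if 0 <= idx < n:
                w.positions[off] = helix.residues[idx].aa
                w.residue_indices[off] = idx
                if prof is not None:
                    w.profile_cols[off] = prof.freqs[idx]
        out.append(w)
    return out


def kink_window_from_sequence(seq: str, kink_pos: int) -> KinkWindow:
    """KinkWindow built directly from a sequence with a known kink position
    (for sequence-level corpora)."""
    w = KinkWindow(kink_ref=None)
    for off in OFFSETS:
        idx = kink_pos + off
        if 0 <= idx < len(seq):
            w.positions[off] = seq[idx]
            w.residue_indices[off] = idx
    return w


@dataclass
class PropensityTable:
    """Position × amino-acid scores with their backing counts.

    ``score`` is log2[(Nᵃᵢ/Nᵢ)/(Nᵃ/N)] (NaN where undefined); ``ratio`` is
    the raw odds ratio; ``pseudocounted`` flags cells where the 0.5
    pseudocount was applied.
    """

    score: pd.DataFrame
    ratio: pd.DataFrame
    counts: dict
    pseudocounted: pd.DataFrame


def _background_counts(background, use_profiles: bool) -> np.ndarray:
    totals = np.zeros(20)
    aa_index = {a: k for k, a in enumerate(C.AMINO_ACIDS)}
    for item in background:
        if use_profiles and isinstance(item, SequenceProfile):
            totals += item.freqs.sum(axis=0)
            continue
        seq = item if isinstance(item, str) else item.sequence
        for ch in seq:
            k = aa_index.get(ch)
            if k is not None:
                totals[k] += 1.0
    return totals


def aa_propensity(
    windows: list[KinkWindow],
    background,
    use_profiles: bool = False,
    pseudocount: float = 0.5,
) -> PropensityTable:
    """Positional propensity scores against the helix-set background.

    ``score(a, i) = log2[(Nᵃᵢ / Nᵢ) / (Nᵃ / N)]`` where Nᵃᵢ counts amino
    acid a at kink-relative offset i over the windows (profile-weighted
    when ``use_profiles``), Nᵢ the total at that offset, and Nᵃ, N the
    totals over all residues of the background set.  Zero cells receive a
    pseudocount before the ratio, keeping the log finite.
    """
    if not len(background):
        raise ValueError("background helix set is empty")
    aa_index = {a: k for k, a in enumerate(C.AMINO_ACIDS)}
    n_ai = np.zeros((len(OFFSETS), 20))
    n_i = np.zeros(len(OFFSETS))
    for w in windows:
        for oi, off in enumerate(OFFSETS):
            if use_profiles and off in w.profile_cols:
                n_ai[oi] += w.profile_cols[off]
                n_i[oi] += w.profile_cols[off].sum()
            elif off in w.positions:
                k = aa_index.get(w.positions[off])
                if k is not None:
                    n_ai[oi, k] += 1.0
                    n_i[oi] += 1.0
    bg = _background_counts(background, use_profiles)
    n_total = bg.sum()
    if n_total == 0:
        raise ValueError("background contains no countable residues")
    bg_freq = bg / n_total

    ratio = np.full((len(OFFSETS), 20), np.nan)
    pseudo = np.zeros((len(OFFSETS), 20), dtype=bool)
    for oi in range(len(OFFSETS)):
        if n_i[oi] == 0:
            continue
        for k in range(20):
            if bg_freq[k] == 0:
                continue
            num = n_ai[oi, k]
            if num == 0:
                num = pseudocount
                pseudo[oi, k] = True
            ratio[oi, k] = (num / n_i[oi]) / bg_freq[k]
    with np.errstate(invalid="ignore"):
        score = np.log2(ratio)
    cols = list(OFFSETS)
    idx = list(C.AMINO_ACIDS)
    return PropensityTable(
        score=pd.DataFrame(score.T, index=idx, columns=cols),
        ratio=pd.DataFrame(ratio.T, index=idx, columns=cols),
        counts={
            "N_ai": pd.DataFrame(n_ai.T, index=idx, columns=cols),
            "N_i": pd.Series(n_i, index=cols),
            "N_a": pd.Series(bg, index=idx),
            "N": float(n_total),
        },
        pseudocounted=pd.DataFrame(pseudo.T, index=idx, columns=cols),
    )


_SPECIAL_TEXTS = {"g_0 or g_+1", "g0 or g+1"}


@dataclass
class MotifSpec:
    """A motif expression: one-letter literals, ``x`` wildcards and
    ``[...]`` alternative classes, or the positional special case
    "G_0 or G_+1" (Glycine at kink offset 0 or +1)."""

    text: str
    tokens: list = field(default_factory=list)
    special: bool = False

    @classmethod
    def parse(cls, text: str) -> "MotifSpec":
        stripped = text.strip()
        if stripped.lower() in _SPECIAL_TEXTS:
            return cls(text="G_0 or G_+1", tokens=[], special=True)
        tokens = []
        i = 0
        while i < len(stripped):
            ch = stripped[i]
            if ch == "x":
                tokens.append(None)
                i += 1
            elif ch == "[":
                j = stripped.find("]", i)
                if j < 0:
                    raise MotifParseError(f"unclosed '[' at position {i} in {text!r}")
                group = stripped[i + 1 : j]
                if not group or any(a not in C.AMINO_ACIDS for a in group):
                    raise MotifParseError(
                        f"invalid class {group!r} at position {i} in {text!r}"
                    )
                tokens.append(group)  # order preserved for round-tripping
                i = j + 1
            elif ch in C.AMINO_ACIDS:
                tokens.append(ch)
                i += 1
            else:
                raise MotifParseError(
                    f"unexpected character {ch!r} at position {i} in {text!r}"
                )
        if not tokens:
            raise MotifParseError(f"empty motif: {text!r}")
        return cls(text=stripped, tokens=tokens, special=False)

    def to_text(self) -> str:
        if self.special:
            return self.text
        parts = []
        for tok in self.tokens:
            if tok is None:
                parts.append("x")
            elif len(tok) == 1:
                parts.append(tok)
            else:
                parts.append("[" + tok + "]")
        return "".join(parts)

    def regex(self) -> re.Pattern:
        if self.special:
            raise ValueError("the positional special motif has no regex form")
        parts = []
        for tok in self.tokens:
            if tok is None:
                parts.append(".")
            elif len(tok) == 1:
                parts.append(re.escape(tok))
            else:
                parts.append("[" + tok + "]")
        return re.compile("".join(parts))


def motif_match(spec: MotifSpec, segment: tuple[str, int]) -> bool:
    """Does the motif occur anywhere in the segment?

    ``segment`` is (sequence, index of kink offset 0).  The special motif
    matches iff Glycine occupies offset 0 or +1.
    """
    text, zero = segment
    if spec.special:
        return (zero < len(text) and text[zero] == "G") or (
            zero + 1 < len(text) and text[zero + 1] == "G"
        )
    return spec.regex().search(text) is not None


@dataclass
class EnrichmentRow:
    motif: MotifSpec
    pct_kink: float
    pct_straight_mean: float
    pct_straight_sd: float
    ratio: float  # NaN when the straight percentage is 0


def motif_enrichment(
    motifs: list,
    kink_segments: list[tuple[str, int]],
    straight_helices: list[str],
    n_resamples: int = 50,
    seed: int = 0,
) -> list[EnrichmentRow]:
    """Motif frequency in kink segments vs resampled straight segments.

    Each straight helix contributes one uniformly random 13-residue segment
    per resample; helices shorter than 13 residues are excluded with a
    warning.  Percentages are in [0, 100]; the enrichment ratio is
    pct_kink / mean(pct_straight), NaN when the denominator is 0.
    """
    specs = [m if isinstance(m, MotifSpec) else MotifSpec.parse(m) for m in motifs]
    usable = [s for s in straight_helices if len(s) >= SEGMENT_LENGTH]
    dropped = len(straight_helices) - len(usable)
    if dropped:
        warnings.warn(
            f"{dropped} straight helices shorter than {SEGMENT_LENGTH} residues excluded"
        )
    rng = np.random.default_rng(seed)
    pct_kink = []
    for spec in specs:
        hits = sum(motif_match(spec, seg) for seg in kink_segments)
        pct_kink.append(100.0 * hits / len(kink_segments) if kink_segments else 0.0)

    straight_pcts = np.zeros((n_resamples, len(specs)))
    for rs in range(n_resamples):
        segs = []
        for s in usable:
            start = int(rng.integers(0, len(s) - SEGMENT_LENGTH + 1))
            segs.append((s[start : start + SEGMENT_LENGTH], SEGMENT_LENGTH // 2))
        for mi, spec in enumerate(specs):
            hits = sum(motif_match(spec, seg) for seg in segs)
            straight_pcts[rs, mi] = 100.0 * hits / len(segs) if segs else 0.0

    rows = []
    for mi, spec in enumerate(specs):
        mean = float(straight_pcts[:, mi].mean())
        sd = float(straight_pcts[:, mi].std(ddof=1)) if n_resamples > 1 else 0.0
        ratio = pct_kink[mi] / mean if mean > 0 else float("nan")
        rows.append(
            EnrichmentRow(
                motif=spec,
                pct_kink=pct_kink[mi],
                pct_straight_mean=mean,
                pct_straight_sd=sd,
                ratio=ratio,
            )
        )
    return rows


def length_matched_samples(
    pool,
    target,
    n_samples: int = 50,
    seed: int = 0,
    length_of: Callable = None,
) -> list[list]:
    """Samples from ``pool`` whose length histogram equals ``target``'s.

    Each sample draws, for every length, exactly as many pool items of that
    length as the target has, uniformly without replacement within a sample
    (with replacement across samples).
    """
    if length_of is None:
        length_of = lambda h: h.length if hasattr(h, "length") else len(h)
    pool_by_len: dict[int, list] = {}
    for h in pool:
        pool_by_len.setdefault(length_of(h), []).append(h)
    need: dict[int, int] = {}
    for h in target:
        need[length_of(h)] = need.get(length_of(h), 0) + 1
    deficient = {
        L: (n, len(pool_by_len.get(L, [])))
        for L, n in sorted(need.items())
        if len(pool_by_len.get(L, [])) < n
    }
    if deficient:
        detail = ", ".join(
            f"length {L}: need {n}, have {have}" for L, (n, have) in deficient.items()
        )
        raise LengthMatchError(f"pool cannot match target lengths ({detail})")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_samples):
        sample = []
        for L, n in sorted(need.items()):
            idx = rng.choice(len(pool_by_len[L]), size=n, replace=False)
            sample.extend(pool_by_len[L][k] for k in idx)
        samples.append(sample)
    return samples


def compare_angle_distributions(a, b, per_length: bool = False) -> pd.DataFrame:
    """Two-sample Kolmogorov–Smirnov comparison of maximum-angle sets.

    ``a`` and ``b`` are sequences of angles, of (length, angle) pairs, or
    of HelixClassification objects.  With ``per_length`` the comparison is
    stratified by helix length (strata with fewer than 2 observations on
    either side are skipped); otherwise a single pooled row is returned.
    """

    def normalize(xs) -> pd.DataFrame:
        rows = []
        for x in xs:
            if isinstance(x, HelixClassification):
                rows.append((x.helix_ref.length if x.helix_ref else np.nan, x.max_angle))
            elif np.isscalar(x):
                rows.append((np.nan, float(x)))
            else:
                rows.append((int(x[0]), float(x[1])))
        return pd.DataFrame(rows, columns=["length", "angle"])

    da, db = normalize(a), normalize(b)
    if len(da) == 0 or len(db) == 0:
        raise ValueError("both helix sets must be nonempty")
    out = []
    if per_length:
        for L in sorted(set(da["length"].dropna()) & set(db["length"].dropna())):
            xa = da.loc[da["length"] == L, "angle"]
            xb = db.loc[db["length"] == L, "angle"]
            if len(xa) < 2 or len(xb) < 2:
                continue
            res = stats.ks_2samp(xa, xb)
            out.append((L, len(xa), len(xb), res.statistic, res.pvalue))
    else:
        res = stats.ks_2samp(da["angle"], db["angle"])
        out.append(("pooled", len(da), len(db), res.statistic, res.pvalue))
    return pd.DataFrame(out, columns=["stratum", "n_a", "n_b", "D", "pvalue"])


def wheel_summary(
    windows: list[KinkWindow], value_fn: Callable[[KinkWindow, int], Optional[float]]
) -> pd.DataFrame:
    """Mean ± 2 s.d. of a per-residue scalar at each kink-relative offset.

    ``value_fn(window, offset)`` returns the scalar or None where
    undefined.  The wheel angle column maps offset → 100°·offset (mod 360)
    for helical-wheel display.
    """
    rows = []
    for off in OFFSETS:
        vals = []
        for w in windows:
            if off in w.positions:
                v = value_fn(w, off)
                if v is not None and not (isinstance(v, float) and np.isnan(v)):
                    vals.append(float(v))
        if vals:
            arr = np.array(vals)
            sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
            rows.append((off, (100.0 * off) % 360.0, arr.mean(), 2.0 * sd, len(arr)))
        else:
            rows.append((off, (100.0 * off) % 360.0, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["offset", "wheel_angle_deg", "mean", "two_sd", "n"]
    )


def hbond_break_rates(
    classified: list[HelixClassification],
    chains: dict,
    hbonds_by_chain: dict,
    scope: str = "whole_helix",
):
    """Fraction of assessable residues lacking their i+4→i backbone bond.

    ``chains`` maps (pdb_id, chain_id) → ChainModel and ``hbonds_by_chain``
    maps the same keys to backbone HBondRecord lists.  ``whole_helix``
    counts every residue of each kinked helix whose offset-4 partner is
    also inside the helix; ``kink_window`` restricts to the 13 residues
    around each kink (offsets clipped at the helix edge).  Also reports
    i+3→i and i+5→i bond presence by kink-relative offset.
    """
    if scope not in ("whole_helix", "kink_window"):
        raise ValueError(f"unknown scope {scope!r}")
    broken = assessed = 0
    offset_rows = {off: {"n": 0, "broken_i4": 0, "i3": 0, "i5": 0} for off in OFFSETS}
    for cls in classified:
        if cls.label != "kinked":
            continue
        helix: Helix = cls.helix_ref
        key = helix.chain_ref
        chain = chains[key]
        records = hbonds_by_chain[key]
        i4 = {r.acceptor_idx for r in records if r.kind == "bb_i4"}
        i3 = {r.acceptor_idx for r in records if r.kind == "bb_i3"}
        i5 = {r.acceptor_idx for r in records if r.kind == "bb_i5"}
        assessable = set(assessable_i4_pairs(chain))
        lo, hi = helix.start_idx, helix.end_idx

        if scope == "whole_helix":
            acceptor_set = {
                i for i in range(lo, hi - 3) if i in assessable
            }
            assessed += len(acceptor_set)
            broken += sum(1 for i in acceptor_set if i not in i4)
        else:
            for call in cls.kinks:
                kink_chain_idx = lo + call.kink_idx
                for off in OFFSETS:
                    i = kink_chain_idx + off
                    if not (lo <= i <= hi - 4):
                        continue
                    if i not in assessable:
                        continue
                    row = offset_rows[off]
                    row["n"] += 1
                    row["broken_i4"] += i not in i4
                    row["i3"] += i in i3
                    row["i5"] += i in i5
                    assessed += 1
                    broken += i not in i4
    by_offset = pd.DataFrame(
        [
            {
                "offset": off,
                "n": r["n"],
                "broken_i4_rate": r["broken_i4"] / r["n"] if r["n"] else np.nan,
                "i3_rate": r["i3"] / r["n"] if r["n"] else np.nan,
                "i5_rate": r["i5"] / r["n"] if r["n"] else np.nan,
            }
            for off, r in offset_rows.items()
        ]
    )
    return {
        "broken_i4_fraction": broken / assessed if assessed else 0.0,
        "n_assessed": assessed,
        "by_offset": by_offset if scope == "kink_window" else None,
    }
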