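# kinkscan

Detection and characterization of **kinks in protein α-helices** — localized
discontinuities where the axis of a helix changes direction — together with
the comparative statistics used to study them: positional amino-acid
propensities, sequence-motif enrichment, hydrogen-bond break rates,
hydrophobicity/solvent-accessibility patterns around kinks, and
length-matched comparison of helix sets. It is written for structural
bioinformaticians analyzing helix distortions in soluble or membrane
proteins from PDB/mmCIF structures.

## The method

The local axis of a helix is estimated by least-squares **cylinder fits to
sliding six-residue windows** of backbone atoms (N, Cα, C, O). The *kink
angle* at residue *i* is the angle between the axes of the two disjoint
windows flanking it,

&nbsp;&nbsp;&nbsp;&nbsp;θᵢ = ∠( axis(i−6 … i−1), axis(i … i+5) ),

so a helix must have at least 12 residues for any angle to be defined. A
helix is called **kinked** when its maximum angle exceeds 20° and
**straight** when it stays ≤ 14°; further kinks require an angle ≥ 20° at
least four residues from every accepted kink, with an intervening residue
≤ 10°. The **wobble angle** then aligns kinks geometrically: projecting the
C-terminal axis onto the plane perpendicular to the N-terminal axis and
comparing it with the perpendicular from the axis to a residue's Cα gives
each candidate's angular position around the bend; the kink *residue* is
the candidate (peak − 1 … peak + 2) whose wobble is closest to 0°, i.e. the
residue on the inside of the bend.

Upstream, helices are built from DSSP-style H states (internal
Kabsch–Sander hydrogen-bond energies or a DSSP output file): runs merged
across 1–2 residue coil gaps, split at angles > 60°, trimmed until both
five-residue ends form ideal-helix "seeds", optionally trimmed to a
membrane annotation, and filtered to ≥ 13 residues. Downstream, positions
around each kink are numbered −6 … +6 with the kink residue as 0, and the
propensity of amino acid *a* at offset *i* is the log-odds

&nbsp;&nbsp;&nbsp;&nbsp;score(a, i) = log₂[ (Nᵃᵢ / Nᵢ) / (Nᵃ / N) ]

against the helix-set background. Everything is validated on a built-in
synthetic generator that constructs ideal helical backbones from internal
coordinates and inserts kinks of exactly known angle, position and bend
direction.

## Worked example

```bash
kinkscan simulate --n 8 --out-dir demo/in --seed 5     # synthetic corpus
kinkscan annotate demo/in demo/out                     # kink calls as TSV
kinkscan compare demo/out demo/out demo/cmp            # set comparison
```

prints

```
wrote 8 synthetic helices to demo/in
annotated 8 files: 8 helices, 4 kinks
compared 8 target vs 8 pool helices (50 length-matched samples)
```

`demo/in/ground_truth.tsv` records each helix's planted kink (position,
angle, azimuth); the per-structure `*_kinks.tsv` tables then hold the
detected calls. For `syn0001` — a 29-residue helix with a 22.2° kink
planted at residue 15 (noise σ = 0.15 Å) — the call table reads

```
helix_uid       peak_idx  kink_idx  kink_auth  angle    wobble
syn0001:A:0     15        15        17         22.8471  32.0527
```

— the peak-angle residue is exactly the planted position, the measured
angle is within 0.7° of the planted one, and author numbering 17 reflects
the residues end-trimming removed before the helix start. In library form:

```python
from kinkscan import HelixSpec, build_helix, local_kink_angles, classify_helix

chain = build_helix(HelixSpec(length=30, kinks=[(15, 40.0, 0.0)]))
cls = classify_helix(local_kink_angles(chain))
print(cls.label, round(cls.max_angle, 1), cls.kinks[0].kink_idx)
# kinked 38.5 15
```

(The measured 38.5° for a planted 40° reflects the sharp rigid-rotation
kink of the generator: the six-residue windows adjacent to the kink mix
residues from both sides, so recovered angles carry a ±5° contract, not
exactness.)

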