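# Methods

`ovoselect` quantifies the final, cyst-independent round of oocyte
selection in perinatal mouse ovaries as seen in long-term 4D (3D + time)
live imaging: germline cysts break down into single oocytes, most oocytes
are sacrificed — shrinking away or bursting into membrane-bounded oocyte
debris (ODs, 1.2–14 µm) — and the surviving minority extend filopodia-like
structures (FLs, ≥ 2.5 µm) that capture and engulf ODs, enriching their
cytoplasm and organelles before follicle formation. Because the raw
imaging of such experiments is rarely shareable, the package couples the
measurement pipeline to an agent-based generator that plants the known
statistical structure of the process, so every stage is testable end to
end without any data download.

## The generator

**Time base and geometry.** Agents move in a 308.72 × 308.72 µm field,
30–50 µm deep (default 40), imaged every 1.5 h for 162 h. t = 0
corresponds to culture-equivalent 17.5 dpc; 24 h stage windows map to
c-17.5 dpc, c-18.5 dpc, c-19.5 dpc, c-PD1 … c-PD4 (the last window is the
partial [144, 162] h interval). An extended-culture mode runs to 330 h
(c-PD11 equivalent).

**Population.** 200 oocytes per replicate field (≈ the per-ovary counts of
such experiments), initial diameters N(15, 2) µm clipped to [10, 25].
10% of tracks leave the field at a random time; this is purely an
observation-layer effect (the agents keep evolving), and such tracks are
excluded from all fate statistics by the completeness filter.

**Cyst breakdown.** 57.1% of oocytes start single; the rest sit in
2-cysts, i.e. touching, rigidly co-moving pairs (chains for larger
configured cyst sizes). At each 24 h boundary every remaining
intercellular bridge dissolves independently with probability 0.490,
0.616, 0.702 (then 0.702 onward). These values are the closed-form hazard
calibration p_w = 1 − A(t_{w+1})/A(t_w) applied to the attached fractions
implied by the single-oocyte time course 57.1 → 78.1 → 91.6 → 97.5%.
Separated members take divergent headings. Because deaths and field exits
also break pairs, the simulated single fractions drift a few points above
the dissolution-only prediction in later windows; they stay inside the
reference SD bands.

**Motion.** Persistent random walk per connected component
(persistence 0.8, speed 1 µm/h), reflective walls with a bounded
(≤ 2 µm/frame) return so nothing ever teleports, small per-member jitter
(σ = 0.2 µm), and soft excluded volume: overlapping components are pushed
apart ≤ 1.5 µm/frame, and chain offsets are recomputed from current radii
each frame so growing bridged oocytes stay surface-touching instead of
interpenetrating. Free debris are kept ≥ ~2.5 µm outside oocyte surfaces;
only an engulfment can place an OD inside an oocyte, which is what the
event caller keys on.

**Sacrifice.** A planted fraction of 14.7% of oocytes is on the surviving
lineage; the rest die. Deaths are scheduled per window as
round(hazard × alive at window start) — hazards (0.015, 0.05, 0.28, 0.28,
0.28, 0, 0) — with 64.3% of scheduled deaths bursting and the rest
shrinking; sacrificed oocytes still alive after the hazard windows shrink
away in the c-PD3/c-PD4 windows. The quota (stratified) realization,
rather than per-oocyte Bernoulli draws, is deliberate variance reduction:
the generator's job is to plant flat per-window burst-frequency plateaus
over c-19.5 → c-PD2, and at n ≈ 200 independent draws would randomize the
peak shape itself. Defining hazards against the
population *at window start* matches the counting convention of the
measurements (denominator = oocytes at the beginning of each period) and
keeps the planted frequency flat even as the population shrinks.

**Bursts.** A burst converts an oocyte into 3 + Poisson(5) debris with
lognormal diameters (median 4.5 µm, σ_log 0.45) truncated to [1.2, 14] µm
and additionally capped at 0.65× the parent diameter (a fragment is
distinctly smaller than its source — this also makes parent→fragment
identity confusions impossible for a size-gated tracker), resampled until
the total debris volume fits in the parent sphere. Debris inherit the
parent's cytoplasm label; their mitochondria densities are drawn
U(0.05, 0.6) (heterogeneous, unlike oocytes at N(0.30, 0.03)). Free
debris wander slowly and decay 24 h after their last unclaimed moment.

**FLs and engulfment.** At each window boundary, round(p_w × alive)
surviving-lineage oocytes are selected to exhibit FLs through the window
(p = 0.005, 0.01, 0.16, 0.16, 0.16, 0.01, 0.005), drawn preferring
oocytes still below the survival minimum, then the least-fed. An
FL-active survivor claims free debris within 80 µm (round-robin across
survivors so nobody hoards; ≤ 8 in flight; reach limited so the approach
finishes inside the window, except that a below-minimum survivor keeps
its full reach). Claimed debris home at 3.9 µm/h toward the oocyte, hold
just outside the membrane, and are enclosed one per oocyte every other
frame (immediately when no queue-mate is nearby) — engulfment is a
sequential enclose-and-disappear behavior. Enclosure applies
volume-weighted mixing of cytoplasm labels and mitochondria density and
increments the diameter by 0.8 µm. Each survivor carries an engulfment
quota of 5 + NegBin(r = 5, mean 10) (minimum 5, mean 15); delivery is
throughput-limited in practice and realizes a mean of ~12–14 — within the
±3 band around 15 used for acceptance, and the one known gap between
planted and realized statistics. A survivor that has not reached the
minimum by c-PD2 keeps exhibiting FLs post-peak while debris remain.

**Growth.** Surviving-lineage oocytes grow at a baseline
0.082 µm/h (CV 15% across oocytes) plus 0.8 µm per engulfment; the
baseline was calibrated jointly with the realized engulfment number so the
extended-culture endpoint matches 52.4 µm at 330 h. Sacrificed oocytes
keep their size until death; shrinkage multiplies the diameter by 0.75
per frame over 6 frames.

**Treatment mode** (autophagy inhibition, 3-MA archetype): sacrifice
hazards × 0.1 with no cleanup (most oocytes persist, "silenced"), FL
exhibition × 0.05, and the capture machinery disabled — residual FLs
recruit nothing, so engulfment counts stay near zero per oocyte. All
oocytes grow at 0.0679 µm/h (→ 37.4 µm at 330 h).

**Whole-ovary mode** generates only the endpoint population for virtual
sectioning: 6244 oocytes with a planted death fraction of 0.3965
(treatment × 0.1), uniform positions in a 600 × 600 × 400 µm volume.
These numbers are solved directly from the endpoint counts they must
reproduce (3768 control / 5996 blocked); the whole organ's survival
fraction is much higher than the imaged subfields', a discrepancy between
assay scales that we parameterize rather than resolve.

## Rendering and detection

The renderer paints each agent's membrane as a one-voxel shell plus
2-voxel-wide FL cylinders, fills the cytoplasm channels by label fraction,
and scatters mito punctae at the agent's density, on a
(0.7, 0.3, 0.3) µm grid (z step from the imaging protocol; the xy pixel
size is not documented for such acquisitions and 0.3 µm is our choice).
Disjoint agents compose by voxelwise maximum. Optics are a Gaussian PSF,
Poisson photon noise, background and read noise, all deterministic under
a seed; the default scene is a 100 × 100 × 30 µm subvolume so an
image-path run stays within minutes — full-field statistics use the
agent-level path.

Detection thresholds the membrane channel, closes and fills shells, and
splits touching objects by marker watershed on the anisotropy-aware
distance transform. Watershed markers are dense EDT maxima consolidated
greedily at a 4 µm physical separation — a plain suppression window hides
a small lobe (an OD against an oocyte) whose neck EDT rivals its own
radius. Equivalent diameters are measured to the membrane midline
(the filled object over-measures by one shell voxel). Size classes use
the half-open rule: OD in [1.2, 14) µm, oocyte at ≥ 14 µm, discard below
1.2 µm. FLs are protrusions beyond a 1 µm morphological opening, measured
as the maximal geodesic distance from the body through the mask
(`skimage.graph.MCP_Geometric` with physical sampling); lengths carry a
roughly half-voxel negative bias, so lengths planted exactly at the
2.5 µm definition can fall below it in the image path (agent-level
measurements are exact). Cytoplasm color is purple iff
min(CFP, RFP)/max(CFP, RFP) ≥ 0.2 — the single most sensitive free
parameter of the color analysis, as "purple" is never quantified in the
source assays. Mitochondria density is the thresholded mito fraction of
the largest cross-section.

## Tracking and event calling

Frame-to-frame linking is optimal assignment (Hungarian) on centroid
distance with a 6 µm gate, a size-consistency gate (frame-to-frame
diameter ratio ≥ 0.66, complementing the 0.65 parent-cap on fragment
sizes), constant-velocity prediction (stabilizes convergent debris
streams), and single-frame gap closing at 1.5× the gate. Tracks are typed
by their first frame: frame-0 tracks are oocytes regardless of size
(10–14 µm oocytes fall in the OD size class but debris only arise from
bursts); later-born OD-class tracks are debris.

Callers: a **burst** is an ended oocyte track with ≥ 3 new OD tracks
within (last radius + 10 µm) in ≤ 2 frames, each new track attributed to
its nearest candidate parent; an **engulfment** is an ended OD track whose
final centroid lies within an oocyte boundary expanded by 1.5 µm (checked
at termination and 2 frames on), ties broken by deepest enclosure; ODs
lost at the field edge without an enclosing oocyte are left-field ends.
**Separation/attachment** use 2-frame hysteresis on contact (surface gap
≤ 0.8 µm) and a 2 µm release distance, so single-frame flicker produces
no events. **Death mode** is degradation iff a burst is associated, else
shrinkage iff the diameter fell over ≥ 4 trailing frames (one ≤ 5%
reversal tolerated) with a ≥ 20% net decline. **Connectedness** of a
contacting pair — used to exclude potentially bridge-connected oocytes
from single counts — requires mean displacement cosine ≥ 0.8 and low
relative surface-gap variation over ≥ 6 shared in-contact frames; pairs
in contact for fewer than 6 frames of a window count as evidence of
independence (bridged pairs touch for most of a window), not as
indeterminate, since excluding such transient contacts would remove
genuine singles from both counts.

## Statistics

Every windowed ratio divides by the oocytes alive at window start. The
survival ratio is computed over complete tracks only (present at frame 0
and either dying by a classified mode or alive at the end). Peak spans
are the maximal contiguous windows at ≥ 80% of the series maximum (the
source analyses identify peaks visually; this is our operational rule).
The total-mitochondria estimator is the closed form
Nmit_total = Voo/(Sloo·D)·N = 4R/(3D)·N. The serial-section count uses
the centroid rule — an oocyte is countable in exactly one 8 µm section,
every fifth section is counted and the sum multiplied by five — which is
unbiased under a uniform section phase; counting every *profile* would
overestimate by (D + t)/t, which is why the centroid rule is used.
Percentages are reported to one decimal, diameters to one decimal µm.
Condition comparisons report means ± SD; no inference machinery beyond
that, as hypothesis testing is not this package's contribution.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure of the assays:
planted rates, flat co-peaking OD/FL frequency curves, the
engulfment–fate rule, growth endpoints and section-count totals, under
the same counting conventions and at the same sample sizes. It does not
model autophagy signaling, transcriptional state, granulosa cells, the
earlier cyst-phase selection, realistic confocal optics (spectral
bleed-through, photobleaching, scattering), or emergent fate decisions —
fate lineage is a planted label, and survival requires both the label and
enough delivered engulfments. Passing tests therefore validate the
measurement pipeline against a known ground truth and the internal
consistency of the planted calibration; they are not evidence about real
ovaries beyond that.

## Numerical and scale choices

Replicate problem sizes (6 × 200 oocytes for survival/engulfment
statistics, 6 × 55 for the low-label single-fraction course, 3 + 3
extended-culture and whole-ovary runs) mirror the per-ovary scales of the
reference assays and keep a full acceptance run in minutes on one CPU.
Deterministic seeding flows from a single integer per replicate; all
outputs are byte-stable under a fixed manifest. Degenerate inputs are
defined throughout: zero-hazard configurations produce event-free logs
with every oocyte labeled candidate, empty frames segment to empty
tables, all-zero frequency series have an empty peak span, and an
exactly-14 µm object is an oocyte (half-open convention). A known
tension retained from the sources: survivors need ≥ 5 engulfments while
"no oocyte that engulfed fewer than 4 survived" leaves exactly-4
ambiguous; the simulator plants the threshold at 5 and the ambiguity is
noted, not resolved.
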