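# Methods

This note documents the models and procedures implemented in kinpocket,
the parameters that matter, the design decisions taken where several
reasonable choices existed, and what the synthetic test system does and
does not demonstrate about real kinase structures.

## Pocket numbering and sequence mapping

The binding site of the kinase catalytic domain is modeled as 85 fixed
pocket positions grouped into regions (β1 = I, G-rich loop = g.l, β2/β3 =
II/III, αC, β-sheet loop b.l, IV, V, gatekeeper GK at position 45, hinge
46–48, linker, αD, αE, VI, catalytic loop c.l 68–75, VII, VIII, xDFG
80–83 with the aspartate at 81 and phenylalanine at 82, and the start of
the activation loop a.l 84–85). The region table (`data/region_table.csv`)
is a versioned data file mapping each slot to its region and to a column
of the bundled master profile; labels render as `aa.region.index`.

Structures are mapped by pairwise alignment of the chain sequence against
the master consensus: BLOSUM62, gap open 11 / extend 1, free terminal
gaps on both sides (glocal), first-optimal traceback for determinism. An
alignment score below a configurable floor (default 80) is rejected as
"not a kinase domain". Slots whose master column aligns to nothing are
explicit gaps; more than 42 gaps (half the pocket) aborts the structure.
Gap placement at the boundary of a deletion flanked by identical residues
is alignment-degenerate; tests assert gap counts and regions, not exact
degenerate boundaries. Mutations are reported against an 85-character
reference pocket sequence; missing side-chain atoms against the standard
heavy-atom complement per residue type.

The bundled master profile is synthetic: a 121-residue catalytic-domain
sequence carrying the canonical motifs (GxGxxG glycine-rich loop, β3
lysine, αC glutamate at slot 24, threonine gatekeeper at 45, hinge,
HRD catalytic loop, ADFG at slots 80–83) with short filler segments
between the discontinuous pocket blocks. Real master alignments can be
swapped in by replacing the two data files.

## Master structural frame

All spatial annotation happens in a common coordinate frame fixed by a
synthetic master scaffold (`kinpocket.scaffold`): each region is a rigid
Cα segment (3.8 Å spacing) arranged so the pocket forms a cleft around
the origin — hinge wall at +x, G-loop roof at +z, catalytic loop floor at
−z, αC and the xDFG motif in the back (−x). Backbone and side-chain
positions are generated analytically; the scaffold is geometric, not
physical (no energetics, idealized rings and chains), which is explicit
and intended: it provides exact, reproducible ground truth, not realism.
Side chains point away from the cavity by default so the ligand cavity
stays clean; pocket-lining residues (gatekeeper, b.l valine 36, αC
glutamate 24) and any residue carrying a designed contact point inward.

Consequences for interpretation: passing tests demonstrate the
correctness of the mapping, superposition, fingerprint, classification
and query machinery under controlled geometry. They do not measure
robustness to crystallographic disorder, alternative rotamer packing,
register errors in hard alignments, or the conformational diversity of
real kinases — those require real-structure validation, for which the
pipeline accepts ordinary PDB/mmCIF input.

## Superposition and quality score

The rigid fit minimizes least-squares deviation (SVD-based, reflections
excluded) over backbone atoms (N, Cα, C, O) of the anchor slots: the
catalytic loop, the xDFG motif and the hinge — the regions that move
least across activation states. Gapped anchor slots are skipped; fewer
than three anchor residues is an error. The pocket RMSD is evaluated over
the backbone of all mapped slots after applying the anchor transform.

The quality score is a linear-penalty composite on [0, 10]:
`10 − w1·max(0, r_anchor − r0) − w2·max(0, r_pocket − r1) −
w3·n_missing_residues − w4·n_missing_atoms`, clamped, with defaults
w = (4, 1, 0.4, 0.1), r0 = 0.8 Å, r1 = 2.2 Å (all configurable). The
offsets equal typical anchor/pocket RMSD levels of well-behaved
structures, so ordinary fits are penalty-free; weights were chosen so
that ~25 missing residues alone exhaust the scale. The functional form is
this package's own specification; only the 0–10 range, monotonicity and
the ingredient list are treated as contractual.

## Interaction fingerprints

Seven types per residue, protein perspective first: hydrophobic, aromatic
face-to-face, aromatic edge-to-face, H-bond protein-donor→ligand-acceptor,
H-bond protein-acceptor←ligand-donor, ionic protein-positive→ligand-
negative, ionic protein-negative→ligand-positive. Default geometry
(configurable, frozen for the golden tests):

- hydrophobic: any apolar pair ≤ 4.5 Å (apolar = C without N/O/F
  neighbour, plus S; protein side from a per-residue table);
- aromatic F2F: ring-centroid distance ≤ 4.0 Å, inter-plane angle ≤ 30°;
  E2F: ≤ 5.0 Å and 60–90° (SVD plane normals; plane angle folded to
  [0, 90]°);
- H-bond: donor-heavy to acceptor-heavy ≤ 3.5 Å and idealized-hydrogen
  angle ≥ 120°, computed as the angle antecedent–donor–acceptor maximized
  over the donor's heavy-atom antecedents (backbone N uses Cα and the
  preceding carbonyl C); donors without resolved antecedents (waters)
  fall back to the distance criterion;
- ionic: opposite formal-charge group centers ≤ 4.5 Å (carboxylates
  centred on the carboxyl carbon, guanidinium on CZ, ammonium on N).

Both H-bond directions may fire for bifunctional groups. Fingerprints are
always 595 bits; gaps insert seven zeroes; apo structures yield a flagged
all-zero fingerprint, and two all-zero fingerprints have similarity 1 by
convention. Water-mediated contacts are not part of the 595 bits — they
are evaluated separately in the water-cluster pass.

The vectorized detector is verified bit-for-bit against an independent
brute-force checker (plain loops, Newell plane normals) on 200 random toy
complexes; the two implementations share only the typing tables.

## Ligand curation

Hetero groups become typed molecules before fingerprinting. With a
chemical-component dictionary entry, bond orders and formal charges are
taken from it, matched by atom name (name mismatches fall back to
geometric perception with a warning); without one, connectivity and bond
orders are perceived from geometry. Protonation is rule-based at pH 7.4
— carboxylates and acidic phosphate oxygens deprotonated, aliphatic
amines and amidine/guanidine groups protonated, amides untouched — and
idempotent; no pKa calculation is attempted, which suffices for
ionic/H-bond typing. Entity classification routes each hetero group in
fixed order: water (HOH/DOD/WAT), ion (single-atom metal/halide),
cofactor (configurable component list), organometallic (metal + carbon),
else ligand; ligands with any heavy atom within 4.0 Å of a pocket-residue
heavy atom are orthosteric, the rest allosteric. The pocket's 85 residues
jointly span the front cleft, gate area and back cleft, so contact with
any of them defines the catalytic cleft here.

## Conformation classification

DFG: three descriptors — the Shrake–Rupley accessible surface area of
D.xDFG.81 (probe 1.4 Å, 960 deterministic Fibonacci-lattice sphere
points, computed in the context of all pocket residues) and the
y-components of the (Cγ − Cα) vectors of slots 81 and 82 in the master
frame (the y axis is the lateral axis of the frame; the DFG-in/out flip
reverses the sign of the phenylalanine component). A CART tree (depth
≤ 3) is trained on a labeled corpus with 10-fold stratified
cross-validation and frozen to `data/dfg_tree.json`; classification at
run time is reproducible from the JSON alone. On the bundled synthetic
corpus the fitted tree splits on the aspartate vector only — the three
classes are already separable there; the ASA and phenylalanine features
remain part of the descriptor contract and are reported with every
record.

αC: thresholds on the Cα(F.xDFG.82)–Cα(E.aC.24) distance, t1 = 7.2 Å and
t2 = 9.3 Å with inclusive boundaries (≤), fitted on the synthetic corpus
whose three αC states are generated at 5.8–7.0 Å, 7.6–9.0 Å and
9.8–12.5 Å; stored in config. Coordinate noise near a band edge can cross
a threshold, so corpus agreement is high but intentionally not asserted
perfect.

G-rich loop: angle at the hinge centroid between the G-loop and
catalytic-loop centroids; centroid–centroid distance; and the signed
dihedral between the two loops' principal axes about the
centroid–centroid axis (backbone atoms; principal-axis sign fixed by the
N→C direction). The master-frame triple is frozen as a golden value.

## Subpockets and waters

Subpocket model: probes on a 0.5 Å grid anchored at the master hinge
centroid, spanning the padded envelope of the training ligands. Per
label, a probe scores the number of *distinct ligands* of the positive
set versus the negative set with an atom within 1.0 Å; probes with
positive:negative ratio ≥ 3 and ≥ 3 positive ligands are retained, top
200 per label (ratio, then contact count, then grid order). Counting
ligands rather than atoms prevents single molecules or rarely-visited
grid corners from minting spurious probes. Assignment flags a label when
any ligand heavy atom lies within 1.0 Å of one of its probes; a flagged
subpocket propagates to its major region (post-hoc hierarchy). Labels
overlap freely (flags are independent, non-exclusive). No probe file is
bundled; `default_subpocket_model()` trains deterministically from the
seeded synthetic corpus, and models round-trip to MOL2 point files plus
JSON metadata so externally trained probe sets can be dropped in.

The synthetic training corpus places ligand atom blobs well inside
(≤ 0.65 r) spheres marking the twelve subpockets, with sphere centres
separated by ≥ 3.3 Å; ground-truth labels are read back from the
geometry. Examples are therefore unambiguous binders or non-binders of
each subpocket — mirroring the role of manual annotations — and residual
held-out error comes from probe-grid dilation at region boundaries.

Water clusters: 13 centroids (I1–I11 and the DFG-out-specific O1/O2)
derived by average-linkage clustering of master-frame water observations,
frozen to `data/water_clusters.json`. Cluster naming is kept stable
across re-derivations by inheriting the label of the nearest reference
centroid (the versioned file); a cluster is DFG-out-specific when ≥ 90%
of its members come from DFG-out structures. Waters are assigned to the
nearest centroid within 1.5 Å (ties resolved by label order, unassigned
waters dropped) and their H-bond pattern with ligand and protein is
evaluated with the fingerprint H-bond rule, the water oxygen acting as
both donor (distance-only, no antecedents) and acceptor.

## Query engine

A query is a conjunction of optional clauses: pocket composition (slot →
allowed residues), DFG/αC classes, subpocket presence/absence, water
presence/absence, an interaction pattern (per-slot present/absent/any),
fingerprint similarity to a reference (Tanimoto), ligand similarity or
dissimilarity (Morgan radius-2/2048 or 166-key MACCS), substructure
(SMARTS), tautomer-aware exact-ligand match (canonical-tautomer
comparison; approximate by nature), physicochemical presets or manual
ranges, and quality/resolution bounds. Property presets: rule-of-five
(MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10), rule-of-three (MW ≤ 300,
logP ≤ 3, HBD ≤ 3, HBA ≤ 3, rotatable ≤ 3), fragment-like (adds a 120 Da
floor), lead-like (200–460 Da, logP −4.0 … 4.2, rotatable ≤ 10); logP is
the Crippen atomic-contribution estimate. Results are ordered by
descending fingerprint similarity when a similarity clause exists,
otherwise by entry id; ties break lexicographically. Export is RFC-4180
CSV with a stable column order; records persist as one JSON per entry.

## Synthetic fixtures

`generate_complex` grows a complex from a declarative spec: pocket
substitutions, DFG class, target αC distance, G-loop lift, designed
contacts, deleted slots, truncated atoms, coordinate noise, an arbitrary
rigid pose, waters at named sites, inert subpocket-occupancy atoms and
decoy entities (ion, cofactor stub, remote allosteric copy). Each
designed contact is one ligand fragment placed analytically to satisfy
its rule with margin (H-bond at 2.9 Å, hydrophobic at 4.0 Å, rings at
3.6/4.3 Å, ionic at 4.0 Å); fragments join through carbon stems carrying
a fluorine, which makes them inert under every interaction rule, so
fragment chemistry never leaks into undesigned bits. Fixture ligands are
topological molecules whose inter-fragment bond lengths are not physical;
their explicit topology ships in a generated component dictionary
(distance-based bond perception is not applicable to them, and the
in-memory `FixtureComplex.dictionary()` serves the same entries).

At generation time every designed bit is verified to realize against the
package's own rule engine; extra bits are tolerated only as incidental
hydrophobic packing and are recorded in the manifest. The manifest's
expected fingerprint is computed on the final (noisy, posed) coordinates,
so the independent content of the self-consistency suite is the file
round-trip: parsing, alignment, numbering, superposition and entity
routing must reproduce the in-memory ground truth exactly. Rule-level
correctness is covered separately by the brute-force oracle comparison.

Corpora: the conformation corpus stratifies the three DFG classes and
three αC bands with 0.25 Å coordinate noise and random rigid poses (the
noise level keeps class margins of ≥ 1.5 Å in the vector descriptors,
representing clearly resolved structures); the subpocket corpus samples
1–3 occupied subpockets per ligand; the water corpus populates each
conserved site in 75% of structures, O1/O2 only in DFG-out ones.

## Problem sizes and numerical choices

Default experiment sizes — 300 structures for classifier
cross-validation, 120 ligands (80/20 split) for the subpocket model, 60
structures for water-cluster derivation, 200 toy complexes for the oracle
comparison, 100 replicates for noise-RMSD recovery — are large enough
that the measured rates are stable across seeds while the whole
acceptance computation stays inexpensive. Deterministic tie-breaks are
used throughout (first-optimal alignment traceback, lowest label index
for water ties, grid order for probe ties, entry-id order for query
ties). Degenerate inputs raise typed errors (`errors.py`) rather than
returning partial results: unparseable files, no protein chains, pockets
more than half gapped, fewer than three anchors, undefined conformational
descriptors, empty probe models, malformed query clauses.

## Known limitations

- The master profile, master frame, decision-tree thresholds, subpocket
  spheres and water sites are synthetic; numbers measured on them
  (classifier accuracy, recovery rates) characterize the machinery, not
  any real kinase corpus. Real master data can replace the bundled files
  without code changes.
- Interaction typing is heavy-atom geometric; halogen bonds, cation-π and
  metal coordination are outside the seven-type vocabulary by design.
- Protonation is rule-based; unusual tautomers/pKa shifts are not
  modeled, and the tautomer-aware exact match is approximate.
- The aligner assumes a single catalytic domain per chain; multi-domain
  constructs rely on the glocal end-gap handling and the score floor.
- Orthosteric/allosteric classification is a distance rule to pocket
  residues; cryptic or interface sites are all "allosteric".
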