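# Methods

## Structure model and PDB subset

Structures are read from fixed-column PDB text: `ATOM`/`HETATM` records
of the first model only. Hydrogens and deuteriums are discarded (the
crystal structures this pipeline targets lack them, and all distance
rules are heavy-atom rules), as are waters. Alternate locations keep the
highest-occupancy copy, first-wins on ties. MSE is remapped to MET;
other non-standard HETATM residues get `kind=other` and are excluded
from contact typing, except residues named like nucleotides
(DA/DC/DG/DT/DU and the ribo forms), which become `kind=nucleic` and are
eligible as DNA. Author residue numbering is used everywhere, with
1-based inclusive spans, because segment names such as NF-YB-51-57 and
QQS-41-59 are author-numbered inclusive ranges; insertion codes are kept
as suffix tokens for uniqueness and spans compare on the integer part.
Missing element columns are inferred from the atom label. Out of scope:
mmCIF, NMR ensembles, symmetry expansion, occupancy-weighted
coordinates.

## Residue classes and interaction chemistry

The six polarity/hydrophobicity classes partition the twenty standard
amino acids: aliphatic {G,A,V,L,I,M}, negative {D,E}, positive {K,R,H},
polar {S,T,N,Q,C}, aromatic {F,W,Y}, proline {P}. Glycine is counted
aliphatic (it has no polar side-chain atom). Cysteine is polar, with SG
treated as a sulfur hydrogen-bond donor. Histidine is deliberately
promiscuous — positive class, cation centre, aromatic ring, donor and
acceptor — because no protonation state is assigned; typed contact
records let users filter downstream.

Per-type atom groups:

| type        | measured between                                             |
|-------------|--------------------------------------------------------------|
| hydrophobic | side-chain carbon atoms (plus Met SD) of both residues       |
| ionic       | charged-group heavy atoms (Asp OD1/OD2, Glu OE1/OE2, Lys NZ, Arg NE/CZ/NH1/NH2, His ring N/C) of a negative/positive pair |
| hbond       | donors (backbone N; side-chain N/O/S bearing H in the parent amino acid) vs. acceptors (backbone O; side-chain lone-pair bearers, incl. Met SD) |
| cation-π    | cation centre (Lys NZ; Arg guanidinium centroid; His ring centroid) vs. aromatic ring centroid (Phe/Tyr 6-ring, Trp 9 ring atoms, His 5-ring) |

Hydrophobic contacts use side chains only; backbone N/O participate in
hydrogen bonds. Residues with missing side-chain atoms are processed
from the atoms present, with a logged warning.

## Contact typing

Cutoffs (Å, defaults): hydrophobic 5.0, ionic 6.0, cation-π 6.0,
hydrogen bond 3.5 for O/N donors and 4.0 for sulfur, DNA contact 5.0.
The sulfur threshold also applies when the *acceptor* atom is sulfur
(Met SD); this is a config switch (`sulfur_acceptor_extends`, default
on), since the printed rule keys only on the donor. No angular criterion
is applied to hydrogen bonds — fidelity to the stated distance rule is
preferred over stereochemical strictness. A residue pair may carry
several types at once (a salt bridge is both ionic and hydrogen-bonded);
records are type-resolved and collapsible. Each contact stores the
minimal qualifying distance of its type. Sides of a map must be
disjoint; only inter-set pairs are evaluated. DNA flags are per residue:
any heavy atom within the DNA cutoff of any DNA heavy atom.

Comparative maps translate the first map's residues through a
user-supplied one-to-one mapping (a helper builds one from the best
ungapped alignment of two chains' sequences, since no mapping procedure
between differently numbered homologous structures is prescribed). A
contact is shared only if the mapped pair *and the type* agree; a pair
hydrophobic in one structure and ionic in the other is not shared.
Contacts on unmapped residues are structure-specific by definition, so
|shared| + |only_a| = |map_a| and |shared| + |only_b| = |map_b| hold
identically.

Interface character summarizes, per side, contacting-residue class
counts and the fraction of hydrophobic-type contacts; a side is
"predominantly hydrophobic" above 50 %.

## Motifs

Pattern dialect: bare letter = fixed position, `[X/Y/...]` = alternative
set (≥ 2 distinct residues; single residues are written bare, making
parse/render a strict round trip), `-` = single-position wildcard. Under
this reading REQEIYV matches `R[E/D]Q[D/E]-[Y/F/W][L/V]` exactly.
Sequence `X` is matched by wildcards only — conservative matching for
ambiguous residues.

Consensus derivation is column-wise over an ungapped block: one distinct
residue → fixed letter; ≤ `max_alternatives` (default 3) → alternative
set ordered by column frequency then alphabetically (deterministic
text); otherwise wildcard. Columns containing `X` become wildcards so
that every input row matches the derived pattern, which holds by
construction. Database scans drop any record matching an exclusion
pattern anywhere; exclusion patterns (e.g. histone-like motifs) are
user-supplied — no default list is shipped because the filter has no
canonical operational definition. Segment alignment is ungapped sliding
with per-column scores 2 (identity), 1 (same polarity class, when
class-aware), 0 otherwise; ties resolve to the smallest offset.

Two recorded oddities of the printed QQS motifs: VARLKMRVI is called a
10-aa motif but has 9 letters (span 41–49 has 9 residues; treated as 9
here), and a strict positional reading of `[V/I]-R[L/I]M[K/R]-[I/V/L]`
(8 positions) does not literally match VARLKMRVI. The pipeline derives
its consensus from the block it is given and never asserts that pattern
against its source peptide.

## Fragment registry

Constructs live in a TSV (id, parent, 1-based inclusive span, partner,
outcome, note) so new proteins can be added without code changes. The
default registry holds the QQS truncation series with MBP pull-down
outcomes as canonical; the GST-bait reciprocal anomaly for the 12-aa
N-terminal peptide (attributed to bait masking) is a note, not an
outcome. Minimal binding regions are the spans of binding fragments not
wholly contained in any non-binding fragment, reduced to the minimal
elements under span containment — a binding span that properly contains
another surviving binding span is dropped, because the smaller fragment
localizes the interaction. For AtNF-YC4 this yields regions 1–12 and
41–59. `partition_total` validates contiguous non-overlapping tilings
and reports the offending boundary otherwise.

## Binding-site transfer

Transfer is positional, not energetic: each contact of an aligned
segment residue (optionally filtered to partner chains, default the
NF-YC role) is copied — type, distance and comparative membership
verbatim — onto the corresponding peptide position. A warning is logged
when the peptide residue's polarity class differs from the source
residue's. Contacts of segment residues outside the aligned window are
skipped with a note. `peptide_start` renumbers proposals into
parent-protein coordinates, making transfer equivariant under numbering
shifts. The linker report gives both motif spans and the inter-motif
span (last N-motif position + 1 to first C-motif position − 1); for QQS
motifs at 5–11 and 41–49 on the 59-residue protein that is 12–40,
29 residues.

## Synthetic data

`make_toy_structure` builds residues from synthetic idealized side-chain
templates laid out along a local x axis, with each interaction type's
anchor atom (or group centroid) at the maximal-x tip. Side B is
mirrored, and the anchor pair is placed at the exact target separation;
since every other atom lies behind its anchor plane, the anchor pair is
the global minimum-distance atom pair and the type-defining group
distance equals the target by construction. Each planted pair occupies
its own cell 30 Å from all others; decoy pairs are separated ≥ 7.5 Å
(beyond every cutoff plus margin). The generator verifies that exactly
the requested type is realized and raises otherwise (e.g. an ionic pair
planted at 2.5 Å would also hydrogen-bond). The optional DNA stub is a
4-nucleotide chain with one extra protein residue placed exactly 4.0 Å
from its 5'-most phosphate. Paired fixtures rebuild "absent" pairs
beyond every cutoff so both structures share a residue layout and the
identity mapping applies.

What these fixtures do *not* emulate: real packing density (one
interaction per residue pair, no secondary contacts), realistic backbone
geometry or secondary structure, crystallographic noise, missing atoms
and alternate conformations beyond what tests construct explicitly.
Passing tests therefore demonstrate correctness of the rules and
plumbing, not robustness to pathological experimental data.

`make_motif_db` plants realized motif windows at recorded positions and
redraws background letters until no accidental match of any involved
pattern remains, so expected hit sets are exact. `make_alignment_block`
samples rows position-wise, fully witnessing every alternative set
(requiring rows ≥ largest set); wildcard columns may legitimately come
back as sets when few distinct letters were sampled, so the realized
column sets are recorded in the truth. All generators are pure functions
of (arguments, seed): identical calls give byte-identical output.

## Pipeline and numerical choices

The `run` pipeline chains select → contact maps (per structure and
segment) → compare → align → transfer → linker report → interface
character, writing every intermediate TSV plus a run log holding the
package version, seed and a config echo sufficient to reconstruct the
run. Distances print with 3 decimals and rows are deterministically
sorted, so identical configs give byte-identical outputs. Chain roles
(NF-YA/NF-YB/NF-YC/DNA) are user-supplied per structure — deposited
entries do not name subunits consistently. All randomness funnels
through the config seed; deterministic stages ignore it. Exit codes: 0
success, 2 config error, 3 data error.

Problem sizes in the shipped checks — 100 random 8-residue interfaces
for oracle equivalence, 25 planted fixtures for recovery rates, 1000
random cutoff perturbations for monotonicity, 1000 random
pattern/sequence pairs for scan agreement — were chosen to exercise
every rule combination while keeping the whole suite in a few seconds.

## Known limitations

Distance-only hydrogen bonds admit geometrically implausible pairs; no
solvent accessibility, buried-surface area or energetics; ungapped
alignment only (by design — the transferred motifs are short and
contiguous); no structure prediction for the candidate peptide itself;
minimal-binding-region derivation assumes fragment outcomes are
consistent (a fragment binding while every sub-fragment fails would
reduce to its own span, not a localized site).
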