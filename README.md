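# nfymap

Typed interface contact maps, degenerate consensus-motif scanning and
binding-site transfer for NF-Y transcription-factor complexes.

## The problem

NF-Y is a heterotrimeric transcription factor (NF-YA/NF-YB/NF-YC) that
binds the CCAAT promoter box; NF-YB and NF-YC dimerize through
histone-fold domains. The *Arabidopsis thaliana* orphan protein QQS — 59
residues, no homologs outside the species — binds NF-YC subunits, and its
two interacting peptides (QQS-1-12 and QQS-41-59) resemble motifs in the
NF-YB N-terminal region near the histone-binding domain. `nfymap`
implements the structural-bioinformatics side of that inference:

* **Contact typing.** Residue–residue interactions across an interface
  are detected from heavy-atom (or group-centroid) minimum distances:
  hydrophobic ≤ 5 Å between side-chain carbons, ionic ≤ 6 Å between
  charged-group atoms of oppositely charged residues, cation-π ≤ 6 Å
  between a cation centre and an aromatic ring centroid, and hydrogen
  bonds ≤ 3.5 Å (O/N donor) or ≤ 4.0 Å (S). Residues within 5 Å of any
  DNA heavy atom are flagged.
* **Cross-structure comparison.** Two maps over homologous complexes are
  partitioned through a one-to-one residue mapping into shared /
  first-only / second-only contacts (the solid/broken/dashed convention
  of interface diagrams).
* **Motifs.** Degenerate consensus patterns in a PROSITE-like dialect
  (`R[E/D]Q[D/E]-[Y/F/W][L/V]`, where `-` is a single-position wildcard)
  are derived column-wise from ungapped alignment blocks and scanned over
  FASTA databases with exclusion filters (e.g. histone-like motifs).
* **Fragment registry.** The QQS truncation series and its pull-down
  outcomes are shipped as an editable TSV registry with span arithmetic
  and minimal-binding-region derivation.
* **Binding-site transfer.** Contacts made by NF-YB interface segments
  (NF-YB-51-57, NF-YB-62-70) are transferred onto a peptide aligned to
  the segment, proposing where the peptide binds NF-YC, plus a linker
  report for the two-site topology.
* **Synthetic data.** Every stage is testable offline: PDB fixtures with
  planted typed contacts at exact distances, FASTA databases with planted
  motifs, and alignment blocks with known consensus — each with an exact
  truth table.

## Worked example

Generate a synthetic interface with six planted interactions and map it:

```sh
$ nfymap simulate --kind structure --seed 7 --out toy.pdb
$ nfymap contacts --structure toy.pdb --segment A:all --side-b B:all
structure_id  chain_a  seq_a  resname_a  chain_b  seq_b  resname_b  type         distance_angstrom ...
toy           A        1      LEU        B        1      LEU        hydrophobic  4.500
toy           A        2      ILE        B        2      VAL        hydrophobic  4.000
toy           A        3      LYS        B        3      GLU        ionic        5.500
toy           A        4      ARG        B        4      ASP        ionic        5.000
toy           A        5      SER        B        5      ASP        hbond        3.000
toy           A        6      LYS        B        6      PHE        cation_pi    5.000
```

Exactly the six planted pairs are recovered, each at its construction
distance; the ten decoy pairs (placed beyond every cutoff) are absent.

Align the QQS N-terminal motif peptide to an NF-YB-like segment with
class-aware scoring (2 per identity, 1 per shared polarity class):

```sh
$ nfymap align --peptide REQEIYV --target GGGGRDQDAWLGGGG
target_start=5 score=9
labels=identity,class,identity,class,class,class,class
```

The peptide lands on `RDQDAWL`: R and Q are identities, every other
column conserves the polarity class (E~D negative, I~A aliphatic, Y~W
aromatic, V~L aliphatic).

Query the construct registry for the pull-down outcomes against
AtNF-YC4:

```sh
$ nfymap fragments --partner AtNF-YC4
id         start  end  outcome     note
QQS-1-12   1      12   binds       MBP pull-down; GST reciprocal failed, ...
QQS-11-59  11     59   binds       MBP and GST pull-downs
QQS-13-47  13     47   no_binding  MBP pull-down
QQS-41-59  41     59   binds       MBP and GST pull-downs
QQS-48-59  48     59   no_binding  MBP pull-down
minimal_binding_regions  1-12, 41-59
```

The three binding fragments reduce to two minimal binding regions,
residues 1–12 and 41–59 of the 59-residue protein, separated by the
29-residue linker 12–40 reported by the pipeline's linker stage.

The full pipeline (`nfymap run --config config.yaml`) chains segment
selection, per-structure contact maps with DNA flags, comparative maps,
peptide alignment, contact transfer and the linker report, writing every
intermediate as TSV plus a reproducible run log.

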