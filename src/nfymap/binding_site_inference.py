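"""Transfer of interface contacts onto an aligned candidate peptide.

Given the contacts made by an NF-YB interface segment (e.g. NF-YB-51-57
or NF-YB-62-70) and an ungapped alignment of a candidate peptide to that
segment, each contact of an aligned segment residue is mapped onto the
corresponding peptide position, proposing binding sites for the peptide
on the partner subunit (by default NF-YC).  The transfer is positional:
interaction types and distances are copied verbatim from the source map,
and a warning is logged when the peptide residue's polarity class differs
from the source residue's, since the contact chemistry is then only a
hypothesis.

:func:`linker_report` summarizes the two-site topology: the spans of the
N- and C-terminal binding motifs on the peptide and the intervening
linker (for QQS, positions 12-40, a 29-residue loop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

from .contact_map import ComparativeMap, ContactMap, ResidueId, TypedContact
from .motif import SegmentAlignment, SequenceRecord
from .residue_chemistry import classify_letter, classify_residue
from .structure_io import ResidueSet

logger = logging.getLogger(__name__)

__all__ = ["BindingSiteEntry", "BindingSiteProposal", "LinkerReport",
           "transfer_sites", "linker_report", "write_proposal_tsv"]


@dataclass(frozen=True)
class BindingSiteEntry:
    peptide_pos: int  # in peptide numbering (peptide_start-based)
    peptide_res: str  # one-letter
    source: ResidueId  # segment residue whose contact is transferred
    partner: ResidueId
    type: str
    membership: str  # both | a_only | b_only
    distance: float


@dataclass
class BindingSiteProposal:
    peptide_id: str
    entries: tuple[BindingSiteEntry, ...]
    segment_keys: tuple[tuple[str, int, str], ...]
    skipped: tuple[str, ...] = ()  # log notes for unaligned/untranslatable contacts

    def positions(self) -> tuple[int, ...]:
        return tuple(sorted({e.peptide_pos for e in self.entries}))

    def span(self) -> tuple[int, int] | None:
        pos = self.positions()
        return (pos[0], pos[-1]) if pos else None


def _iter_contacts(cmap: Union[ContactMap, ComparativeMap]):
    """Yield (contact, membership) with residues in first-structure coordinates.

    For a plain map every contact is its own evidence and membership is
    reported as ``both``.  For a comparative map, second-structure-only
    contacts are translated back through the inverse residue mapping
    where possible; untranslatable ones are yielded with membership
    ``b_only!untranslated`` so callers can skip and log them.
    """
    if isinstance(cmap, ContactMap):
        for c in cmap.contacts:
            yield c, "both"
        return
    inverse = {v: k for k, v in cmap.mapping.items()}
    for ca, _cb in cmap.shared:
        yield ca, "both"
    for c in cmap.only_a:
        yield c, "a_only"
    for c in cmap.only_b:
        ka, kb = inverse.get(c.res_a.key), inverse.get(c.res_b.key)
        if ka is None or kb is None:
            yield c, "b_only!untranslated"
            continue
        yield TypedContact(ResidueId(*ka, c.res_a.name), ResidueId(*kb, c.res_b.name),
                           c.type, c.distance, c.source), "b_only"


def transfer_sites(alignment: SegmentAlignment, peptide: SequenceRecord,
                   segment: ResidueSet, cmap: Union[ContactMap, ComparativeMap],
                   partner_filter: set[str] | None = None,
                   peptide_start: int = 1) -> BindingSiteProposal:
    """Map a segment's interface contacts onto the aligned peptide.

    ``alignment`` places the peptide on the segment's own sequence (the
    alignment target must index the segment residues in order).  Contacts
    whose partner chain is outside ``partner_filter`` are dropped;
    contacts of segment residues outside the aligned window are skipped
    with a note.  ``peptide_start`` sets the numbering of peptide
    position 1 (e.g. 5 for QQS-5-11), so proposals report parent-protein
    coordinates.
    """
    seg_keys = segment.keys
    if isinstance(cmap, ContactMap):
        side_keys = set(cmap.side_a.keys) | set(cmap.side_b.keys)
        if not set(seg_keys) <= side_keys:
            raise ValueError("segment residues are not a side of the contact map")
    index_of = {key: i for i, key in enumerate(seg_keys)}

    lo = alignment.offset
    hi = alignment.offset + len(peptide.seq)  # exclusive segment index bound

    entries: list[BindingSiteEntry] = []
    skipped: list[str] = []
    for contact, membership in _iter_contacts(cmap):
        if membership == "b_only!untranslated":
            skipped.append(f"untranslatable second-structure contact "
                           f"{contact.res_a.chain}{contact.res_a.token}-"
                           f"{contact.res_b.chain}{contact.res_b.token} ({contact.type})")
            continue
        if contact.res_a.key in index_of:
            source, partner = contact.res_a, contact.res_b
        elif contact.res_b.key in index_of:
            source, partner = contact.res_b, contact.res_a
        else:
            continue  # contact not on the segment
        if partner_filter is not None and partner.chain not in partner_filter:
            continue
        j = index_of[source.key]
        if not (lo <= j < hi):
            skipped.append(f"segment residue {source.chain}{source.token} not covered "
                           f"by the peptide alignment; contact to "
                           f"{partner.chain}{partner.token} ({contact.type}) skipped")
            continue
        pep_idx = j - lo  # 0-based within peptide
        pep_letter = peptide.seq[pep_idx]
        if classify_letter(pep_letter) != classify_residue(source.name):
            logger.warning("peptide %s position %d (%s) differs in class from source "
                           "residue %s %s%s", peptide.id, pep_idx + peptide_start,
                           pep_letter, source.name, source.chain, source.token)
        entries.append(BindingSiteEntry(
            pep_idx + peptide_start, pep_letter, source, partner,
            contact.type, membership, contact.distance))
    for note in skipped:
        logger.info(note)

    entries.sort(key=lambda e: (e.peptide_pos, e.partner.chain, e.partner.seq,
                                e.partner.icode, e.type))
    return BindingSiteProposal(peptide.id, tuple(entries), seg_keys, tuple(skipped))


@dataclass
class LinkerReport:
    peptide_id: str
    motif_n_span: tuple[int, int]
    motif_c_span: tuple[int, int]
    linker_span: tuple[int, int] | None  # None when motifs are adjacent
    linker_length: int
    peptide_length: int


def linker_report(proposal_n: BindingSiteProposal, proposal_c: BindingSiteProposal,
                  peptide_length: int) -> LinkerReport:
    """Two-site topology: motif spans and the inter-motif linker.

    The linker runs from one past the last N-motif position to one before
    the first C-motif position.  Proposals must be on the same peptide
    and occupy disjoint spans.
    """
    if proposal_n.peptide_id != proposal_c.peptide_id:
        raise ValueError("proposals are on different peptides")
    span_n, span_c = proposal_n.span(), proposal_c.span()
    if span_n is None or span_c is None:
        raise ValueError("cannot report a linker for an empty proposal")
    if span_n[0] > span_c[0]:
        span_n, span_c = span_c, span_n
    if span_n[1] >= span_c[0]:
        raise ValueError(f"proposal spans overlap: {span_n} vs {span_c}")
    start, end = span_n[1] + 1, span_c[0] - 1
    length = max(0, end - start + 1)
    linker = (start, end) if length > 0 else None
    return LinkerReport(proposal_n.peptide_id, span_n, span_c, linker,
                        length, peptide_length)


def write_proposal_tsv(proposal: BindingSiteProposal) -> str:
    header = ("peptide_id\tpeptide_pos\tpeptide_res\tsource_chain\tsource_seq"
              "\tsource_resname\tpartner_chain\tpartner_seq\tpartner_resname"
              "\ttype\tmembership\tdistance_angstrom")
    lines = [header]
    for e in proposal.entries:
        lines.append(
            f"{proposal.peptide_id}\t{e.peptide_pos}\t{e.peptide_res}"
            f"\t{e.source.chain}\t{e.source.token}\t{e.source.name}"
            f"\t{e.partner.chain}\t{e.partner.token}\t{e.partner.name}"
            f"\t{e.type}\t{e.membership}\t{e.distance:.3f}")
    return "\n".join(lines) + "\n"
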