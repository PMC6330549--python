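"""Registry of peptide constructs and their pull-down binding outcomes.

The packaged default registry records the QQS truncation series used to
map the QQS/NF-YC interaction (QQS-1-12, QQS-11-59, QQS-13-47,
QQS-41-59, QQS-48-59 on the 59-residue parent) together with per-partner
outcomes, plus the human NF-YC N-terminal construct (aa 1-145).  It is a
plain TSV so other constructs can be added without touching code.

Outcome semantics: ``binds`` / ``no_binding`` / ``not_tested``.  Where a
reciprocal assay disagreed (the GST-bait anomaly for the 12-aa N-terminal
peptide, attributed to bait masking), the MBP result is the canonical
outcome and the disagreement lives in the free-text note.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = ["FragmentConstruct", "FragmentRegistry", "BindingSummary"]

OUTCOMES = ("binds", "no_binding", "not_tested")


@dataclass
class FragmentConstruct:
    id: str
    parent: str
    start: int  # 1-based inclusive
    end: int
    outcomes: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class BindingSummary:
    partner: str
    rows: pd.DataFrame  # id, start, end, outcome, note
    binding_ids: tuple[str, ...]
    minimal_regions: tuple[tuple[int, int], ...]


class FragmentRegistry:
    """Fragment constructs keyed by id, with parent-protein lengths."""

    def __init__(self, parents: dict[str, int | None],
                 fragments: list[FragmentConstruct]):
        self.parents = dict(parents)
        self.fragments: dict[str, FragmentConstruct] = {}
        for frag in fragments:
            if frag.id in self.fragments:
                raise ValueError(f"duplicate fragment id {frag.id!r}")
            self._validate(frag)
            self.fragments[frag.id] = frag

    def _validate(self, frag: FragmentConstruct) -> None:
        if frag.parent not in self.parents:
            raise ValueError(f"{frag.id}: unknown parent {frag.parent!r}")
        if not (1 <= frag.start <= frag.end):
            raise ValueError(f"{frag.id}: invalid span {frag.start}-{frag.end}")
        plen = self.parents[frag.parent]
        if plen is not None and frag.end > plen:
            raise ValueError(f"{frag.id}: end {frag.end} beyond parent length {plen}")
        for outcome in frag.outcomes.values():
            if outcome not in OUTCOMES:
                raise ValueError(f"{frag.id}: unknown outcome {outcome!r}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_tsv(cls, fragments_tsv: Union[str, Path, io.TextIOBase],
                 parents_tsv: Union[str, Path, io.TextIOBase]) -> "FragmentRegistry":
        parents: dict[str, int | None] = {}
        for row in _read_tsv(parents_tsv):
            length = row.get("length", "")
            parents[row["id"]] = int(length) if length else None

        frags: dict[str, FragmentConstruct] = {}
        for row in _read_tsv(fragments_tsv):
            fid = row["id"]
            span = (row["parent"], int(row["start"]), int(row["end"]))
            frag = frags.get(fid)
            if frag is None:
                frag = FragmentConstruct(fid, *span)
                frags[fid] = frag
            elif (frag.parent, frag.start, frag.end) != span:
                raise ValueError(f"conflicting definitions for fragment {fid!r}")
            partner = row.get("partner", "") or ""
            if partner:
                frag.outcomes[partner] = row.get("outcome", "not_tested") or "not_tested"
                note = row.get("note", "") or ""
                if note:
                    frag.notes[partner] = note
        return cls(parents, list(frags.values()))

    @classmethod
    def load_default(cls) -> "FragmentRegistry":
        data = resources.files("nfymap").joinpath("data")
        with resources.as_file(data.joinpath("qqs_fragments.tsv")) as fp, \
                resources.as_file(data.joinpath("parents.tsv")) as pp:
            return cls.from_tsv(fp, pp)

    # -- queries ------------------------------------------------------

    def __getitem__(self, fragment_id: str) -> FragmentConstruct:
        try:
            return self.fragments[fragment_id]
        except KeyError:
            raise KeyError(f"unknown fragment id {fragment_id!r}") from None

    def fragment_length(self, fragment_id: str) -> int:
        return self[fragment_id].length

    def partition_total(self, ids: list[str]) -> int:
        """Total length of fragments that tile a parent contiguously.

        Raises if the fragments overlap, leave a gap, or span multiple
        parents; returns the summed length (equal to the parent length
        when the ids tile the whole parent)."""
        frags = [self[i] for i in ids]
        parents = {f.parent for f in frags}
        if len(parents) != 1:
            raise ValueError(f"fragments span multiple parents: {sorted(parents)}")
        frags.sort(key=lambda f: f.start)
        for prev, nxt in zip(frags, frags[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"overlap between {prev.id} and {nxt.id} at {nxt.start}-{prev.end}")
            if nxt.start > prev.end + 1:
                raise ValueError(
                    f"gap between {prev.id} and {nxt.id} at {prev.end + 1}-{nxt.start - 1}")
        return sum(f.length for f in frags)

    def binding_summary(self, partner: str) -> BindingSummary:
        """Outcomes of every fragment tested against ``partner`` and the
        derived minimal binding regions.

        Minimal regions are the spans of binding fragments that are not
        wholly contained in any non-binding fragment, reduced to the
        minimal elements under span containment (a binding span that
        properly contains another surviving binding span is dropped, as
        the smaller fragment localizes the interaction)."""
        tested = [f for f in self.fragments.values()
                  if f.outcomes.get(partner) in ("binds", "no_binding")]
        rows = pd.DataFrame(
            [(f.id, f.start, f.end, f.outcomes[partner], f.notes.get(partner, ""))
             for f in sorted(tested, key=lambda f: (f.start, f.end))],
            columns=["id", "start", "end", "outcome", "note"],
        )
        binding = [f for f in tested if f.outcomes[partner] == "binds"]
        nonbinding_spans = [f.span for f in tested if f.outcomes[partner] == "no_binding"]

        surviving = [f for f in binding
                     if not any(n[0] <= f.start and f.end <= n[1] for n in nonbinding_spans)]
        minimal = []
        for f in surviving:
            contains_other = any(
                g is not f and f.start <= g.start and g.end <= f.end
                and f.span != g.span
                for g in surviving)
            if not contains_other:
                minimal.append(f.span)
        minimal = tuple(sorted(set(minimal)))
        binding_ids = tuple(sorted(f.id for f in binding))
        return BindingSummary(partner, rows, binding_ids, minimal)


def _read_tsv(source: Union[str, Path, io.TextIOBase]) -> list[dict]:
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return list(csv.DictReader(fh, delimiter="\t"))
    return list(csv.DictReader(source, delimiter="\t"))
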