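"""Raw small-RNA read cleanup with an exact removal ledger.

A raw library is reduced to a mappable read set by a fixed chain of
filters: 3' adapter trimming, length bounds, low-complexity ("junk")
screening, and contaminant subtraction against ncRNA (Rfam-style) and
repeat (Repbase-style) sets.  Every read ends up in exactly one
category, so the per-category ledger partitions the raw total -- the
same accounting layout a sequencing report prints as its
"sequences / unique sequences" table.

Category precedence is fixed (adapter -> length -> junk -> rfam ->
repbase): a read that would match several filters is charged to the
first one.
"""

from __future__ import annotations

import copy
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .seqs import VALID_BASES, revcomp

log = logging.getLogger(__name__)

#: removal categories, in the order the filter chain applies them
REMOVAL_REASONS = ("no_3adt", "too_short", "too_long", "junk", "rfam", "repbase")

_LEDGER_LABELS = {
    "no_3adt": "Number of reads removed because 3ADT was not found",
    "too_short": "Number of reads removed because of <15 bases",
    "too_long": "Number of reads removed because of >30 bases",
    "junk": "Junk reads",
    "rfam": "RFam",
    "repbase": "Repbase",
}


@dataclass
class ReadRecord:
    """A (possibly collapsed) small-RNA read and its filtering fate."""

    read_id: str
    sequence: str
    count: int = 1
    kept: bool = True
    removal_reason: str = "none"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.count < 1:
            raise ValueError(f"read {self.read_id}: count must be >= 1")

    def removed(self, reason: str) -> "ReadRecord":
        if reason not in REMOVAL_REASONS:
            raise ValueError(f"unknown removal reason: {reason}")
        rec = copy.copy(self)  # plain copy: the sequence may be a trimmed-empty insert
        rec.kept = False
        rec.removal_reason = reason
        return rec


@dataclass
class FilterReport:
    """Per-category removal ledger for one library.

    ``removed``/``removed_unique`` map each removal reason to total read
    counts and distinct-sequence counts.  Invariants: the categories are
    disjoint, ``raw_total = mappable_total + sum(removed.values())`` and
    ``surviving_15_30`` is the total left after the adapter, length and
    junk steps (i.e. before contaminant subtraction).
    """

    raw_total: int = 0
    raw_unique: int = 0
    removed: dict = field(default_factory=dict)
    removed_unique: dict = field(default_factory=dict)
    surviving_15_30: int = 0
    mappable_total: int = 0
    mappable_unique: int = 0

    def __post_init__(self) -> None:
        for reason in REMOVAL_REASONS:
            self.removed.setdefault(reason, 0)
            self.removed_unique.setdefault(reason, 0)

    def validate(self) -> None:
        total = self.mappable_total + sum(self.removed.values())
        if total != self.raw_total:
            raise ValueError(
                f"ledger does not partition the raw total: {total} != {self.raw_total}"
            )
        surv = self.raw_total - sum(
            self.removed[r] for r in ("no_3adt", "too_short", "too_long", "junk")
        )
        if surv != self.surviving_15_30:
            raise ValueError(
                f"surviving_15_30 inconsistent: {surv} != {self.surviving_15_30}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("Raw reads", self.raw_total, self.raw_unique)]
        for reason in REMOVAL_REASONS:
            rows.append(
                (_LEDGER_LABELS[reason], self.removed[reason], self.removed_unique[reason])
            )
        rows.append(("Mappable sequences", self.mappable_total, self.mappable_unique))
        return pd.DataFrame(rows, columns=["Category", "Sequences", "Unique sequences"])


def surviving_after_cleanup(
    raw_total: int, no_3adt: int, too_short: int, junk: int, too_long: int = 0
) -> int:
    """Reads left in the 15-30 nt range after adapter/length/junk removal.

    Pure ledger arithmetic: raw - no_3adt - too_short - too_long - junk.
    """
    return raw_total - no_3adt - too_short - too_long - junk


def collapse(records: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Merge identical sequences, summing counts (order of first appearance)."""
    merged: dict[str, ReadRecord] = {}
    for rec in records:
        prev = merged.get(rec.sequence)
        if prev is None:
            merged[rec.sequence] = copy.copy(rec)
        else:
            prev.count += rec.count
    return list(merged.values())


def trim_3p_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> ReadRecord:
    """Locate the 3' adapter and return the insert upstream of it.

    The adapter's prefix (at least ``min_overlap`` bases, up to the full
    adapter or the end of the read) is aligned at every read offset; the
    leftmost (5'-most) alignment within the mismatch rate wins, so the
    shortest insert is returned when the adapter occurs more than once.
    Reads in which no acceptable match exists are flagged ``no_3adt``.
    """
    if min_overlap < 6:
        raise ValueError("min_overlap must be >= 6")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    seq = read.sequence
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"read {read.read_id}: non-ACGTN characters {bad}")
    for start in range(0, len(seq) - min_overlap + 1):
        m = min(len(adapter), len(seq) - start)
        window = seq[start : start + m]
        allowed = int(max_mismatch_rate * m)
        mismatches = 0
        for a, b in zip(window, adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            insert = seq[:start]
            if insert:
                return replace(read, sequence=insert)
            # adapter-only read: keep a zero-length insert as a transient
            # state; the length filter charges it to too_short.
            rec = replace(read)
            rec.sequence = ""
            return rec
    return read.removed("no_3adt")


def filter_by_length(
    records: Iterable[ReadRecord], min_len: int = 15, max_len: int = 30
) -> list[ReadRecord]:
    """Remove inserts outside [min_len, max_len] (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    out = []
    for rec in records:
        if not rec.kept:
            out.append(rec)
        elif len(rec.sequence) < min_len:
            out.append(rec.removed("too_short"))
        elif len(rec.sequence) > max_len:
            out.append(rec.removed("too_long"))
        else:
            out.append(rec)
    return out


def is_junk(seq: str, max_n_fraction: float = 0.1, min_distinct_bases: int = 3) -> bool:
    """Low-complexity screen: too many N's, or a homopolymer/dimer artifact."""
    if not seq:
        return True
    if seq.count("N") / len(seq) > max_n_fraction:
        return True
    return len(set(seq) - {"N"}) < min_distinct_bases


def remove_junk(
    records: Iterable[ReadRecord],
    max_n_fraction: float = 0.1,
    min_distinct_bases: int = 3,
) -> list[ReadRecord]:
    return [
        rec.removed("junk")
        if rec.kept and is_junk(rec.sequence, max_n_fraction, min_distinct_bases)
        else rec
        for rec in records
    ]


class ContaminantIndex:
    """Exact-substring lookup against contaminant sequences, both strands.

    A read "matches" a contaminant when it occurs verbatim as a substring
    of the contaminant or of its reverse complement.  Substring sets are
    built lazily per read length.
    """

    def __init__(self, sequences: Sequence[str]):
        self._texts = []
        for s in sequences:
            s = s.upper().replace("U", "T")
            self._texts.append(s)
            self._texts.append(revcomp(s))
        self._by_length: dict[int, frozenset] = {}

    def __bool__(self) -> bool:
        return bool(self._texts)

    def _substrings(self, k: int) -> frozenset:
        cached = self._by_length.get(k)
        if cached is None:
            subs = set()
            for t in self._texts:
                for i in range(len(t) - k + 1):
                    subs.add(t[i : i + k])
            cached = self._by_length[k] = frozenset(subs)
        return cached

    def __contains__(self, read_seq: str) -> bool:
        if not self._texts or not read_seq:
            return False
        return read_seq in self._substrings(len(read_seq))


def remove_contaminants(
    records: Iterable[ReadRecord],
    rfam: ContaminantIndex | Sequence[str],
    repbase: ContaminantIndex | Sequence[str],
) -> list[ReadRecord]:
    """Drop reads matching ncRNA/repeat sets; rfam takes precedence."""
    if not isinstance(rfam, ContaminantIndex):
        rfam = ContaminantIndex(rfam)
    if not isinstance(repbase, ContaminantIndex):
        repbase = ContaminantIndex(repbase)
    if not rfam:
        log.warning("empty Rfam contaminant set: ncRNA filtering is a no-op")
    if not repbase:
        log.warning("empty Repbase contaminant set: repeat filtering is a no-op")
    out = []
    for rec in records:
        if rec.kept and rec.sequence in rfam:
            out.append(rec.removed("rfam"))
        elif rec.kept and rec.sequence in repbase:
            out.append(rec.removed("repbase"))
        else:
            out.append(rec)
    return out


def build_accounting(records: Iterable[ReadRecord]) -> FilterReport:
    """Aggregate fully-filtered records into the removal ledger."""
    removed = Counter()
    removed_unique = Counter()
    raw_total = raw_unique = 0
    mappable_total = mappable_unique = 0
    seen: set[str] = set()
    for rec in records:
        raw_total += rec.count
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            raw_unique += 1
            unique = 1
        else:  # pragma: no cover - collapsed inputs are distinct by construction
            unique = 0
        if rec.kept:
            if rec.removal_reason != "none":
                raise ValueError(f"read {rec.read_id}: kept but flagged {rec.removal_reason}")
            mappable_total += rec.count
            mappable_unique += unique
        else:
            removed[rec.removal_reason] += rec.count
            removed_unique[rec.removal_reason] += unique
    report = FilterReport(
        raw_total=raw_total,
        raw_unique=raw_unique,
        removed=dict(removed),
        removed_unique=dict(removed_unique),
        surviving_15_30=surviving_after_cleanup(
            raw_total,
            removed["no_3adt"],
            removed["too_short"],
            removed["junk"],
            removed["too_long"],
        ),
        mappable_total=mappable_total,
        mappable_unique=mappable_unique,
    )
    report.validate()
    return report


def run_preprocess(
    records: Iterable[ReadRecord],
    adapter: str | None,
    rfam: Sequence[str] | ContaminantIndex = (),
    repbase: Sequence[str] | ContaminantIndex = (),
    min_len: int = 15,
    max_len: int = 30,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    max_n_fraction: float = 0.1,
    min_distinct_bases: int = 3,
) -> tuple[list[ReadRecord], FilterReport]:
    """Run the whole filter chain and return (all records, ledger).

    ``adapter=None`` skips trimming (input already adapter-free, e.g. a
    collapsed FASTA of inserts).  Identical raw sequences are collapsed
    first so each unique sequence is processed once.
    """
    collapsed = collapse(records)
    if adapter:
        collapsed = [
            trim_3p_adapter(r, adapter, min_overlap, max_mismatch_rate) for r in collapsed
        ]
        # trimming can make distinct raw reads share an insert; re-collapse kept ones
        kept = collapse([r for r in collapsed if r.kept])
        collapsed = kept + [r for r in collapsed if not r.kept]
    staged = filter_by_length(collapsed, min_len, max_len)
    staged = remove_junk(staged, max_n_fraction, min_distinct_bases)
    staged = remove_contaminants(staged, rfam, repbase)
    # empty inserts were charged to too_short; restore a placeholder sequence
    for rec in staged:
        if not rec.sequence:
            rec.sequence = "-"
    return staged, build_accounting(staged)
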