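"""Degradome (PARE) target calling.

Degradome reads mark the 5' ends of uncapped mRNA fragments; a
miRNA-directed cleavage leaves a peak of read 5' ends at the slice
site.  Targets are called by (i) anchoring degradome reads on the
transcriptome by exact match of their first 20 nt, sense strand only;
(ii) scanning each miRNA against every transcript with Allen-style
penalties (mismatch 1, G:U 0.5, doubled at miRNA positions 2-13,
alignments kept below a 4.5 cutoff); (iii) requiring the observed
cleavage position to fall at the canonical site within the binding
region; and (iv) attaching a t-plot abundance category:

=========  ========================================================
category   evidence at the cleavage site
=========  ========================================================
0          >1 read, equal to the transcript maximum, maximum unique
1          equal to the transcript maximum, maximum shared
2          below the maximum but above the median of nonzero sites
3          at or below the median, more than 1 read
4          exactly 1 read
=========  ========================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqs import normalize, revcomp

log = logging.getLogger(__name__)

#: Allen-style alignment scoring
MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
GAP_PENALTY = 2.0  # retained for completeness; the scanner is gapless
CORE_START, CORE_END = 2, 13  # miRNA positions (1-based, inclusive) scored double
SCORE_CUTOFF = 4.5

#: number of 5'-terminal bases used to anchor a degradome read
ANCHOR_LEN = 20
MIN_DEGRADOME_READ = 18


@dataclass
class DegradomeProfile:
    """Per-position counts of degradome read 5' ends on one transcript."""

    transcript_id: str
    length: int
    position_counts: dict = field(default_factory=dict)  # 0-based pos -> count
    multi_mapped: set = field(default_factory=set)

    def add(self, pos: int, count: int = 1) -> None:
        if not 0 <= pos < self.length:
            raise ValueError(f"position {pos} outside transcript {self.transcript_id}")
        self.position_counts[pos] = self.position_counts.get(pos, 0) + count

    def count_at(self, pos: int) -> int:
        return self.position_counts.get(pos, 0)


@dataclass
class TargetAlignment:
    """A gapless miRNA:mRNA duplex alignment on a transcript."""

    mir_name: str
    transcript_id: str
    binding_start: int  # 0-based half-open, transcript coords
    binding_end: int
    score: float
    labels: str  # per target position 5'->3': '|' match, 'o' G:U, 'x' mismatch
    predicted_cleavage_site: int  # 0-based: base paired to miRNA position 10


@dataclass
class TargetCall:
    mir_family: str
    mir_name: str
    target_gene: str
    cleavage_site: int  # 1-based in reports
    reads_at_site: int
    category: int
    alignment_score: float
    homolog: str | None = None
    conserved_flag: bool = False


def map_degradome_reads(
    reads: Iterable[tuple[str, int]],
    transcripts: Mapping[str, str],
    anchor_len: int = ANCHOR_LEN,
    min_read_len: int = MIN_DEGRADOME_READ,
) -> dict[str, DegradomeProfile]:
    """Anchor degradome read 5' ends on transcripts (exact, sense strand).

    ``reads`` yields (sequence, count).  A read contributes its count
    at the position of its 5'-most base on every transcript where its
    first ``anchor_len`` nt occur verbatim; multi-mapped anchors are
    flagged on each profile.  Reads shorter than ``min_read_len`` are
    skipped.
    """
    norm = {tid: normalize(seq) for tid, seq in transcripts.items()}
    profiles = {
        tid: DegradomeProfile(tid, len(seq)) for tid, seq in norm.items()
    }
    for seq, count in reads:
        seq = normalize(seq)
        if len(seq) < min_read_len:
            continue
        anchor = seq[: min(anchor_len, len(seq))]
        hit_tids = []
        hit_positions = []
        for tid, tseq in norm.items():
            start = tseq.find(anchor)
            while start != -1:
                hit_tids.append(tid)
                hit_positions.append((tid, start))
                start = tseq.find(anchor, start + 1)
        for tid, pos in hit_positions:
            profiles[tid].add(pos, count)
            if len(set(hit_tids)) > 1:
                profiles[tid].multi_mapped.add(pos)
    return profiles


def assign_category(profile: DegradomeProfile, site: int) -> int:
    """Abundance category (0-4) of an evidence site; site must have >= 1 read."""
    count = profile.count_at(site)
    if count < 1:
        raise ValueError(
            f"position {site} of {profile.transcript_id} has no degradome evidence"
        )
    counts = list(profile.position_counts.values())
    maximum = max(counts)
    if count == 1:
        return 4
    if count == maximum:
        return 0 if counts.count(maximum) == 1 else 1
    median = float(np.median(counts))
    return 2 if count > median else 3


def score_duplex(mir: str, target_window: str) -> tuple[float, str]:
    """Penalty score of a gapless miRNA:target duplex.

    The target window is the transcript sense strand, 5'->3'; miRNA
    position k (1-based from its 5' end) faces target position L-k.
    Returns (score, labels) with labels along the target 5'->3'.
    """
    mir = normalize(mir)
    window = normalize(target_window)
    if len(mir) != len(window):
        raise ValueError("gapless duplex requires equal lengths")
    L = len(mir)
    score = 0.0
    labels = []
    for t in range(L):  # target position, 5'->3'
        k = L - t  # 1-based miRNA position facing it
        m, w = mir[k - 1], window[t]
        pair = (m, revcomp(w))  # base the target position would need
        weight = 2.0 if CORE_START <= k <= CORE_END else 1.0
        if m == revcomp(w):
            labels.append("|")
        elif (m, w) in (("G", "T"), ("T", "G")):
            # G:U wobble on the RNA duplex (T stands for U)
            labels.append("o")
            score += GU_PENALTY * weight
        else:
            labels.append("x")
            score += MISMATCH_PENALTY * weight
    return score, "".join(labels)


def align_mir_target(
    mir_name: str,
    mir_seq: str,
    transcript_id: str,
    transcript_seq: str,
    cutoff: float = SCORE_CUTOFF,
) -> list[TargetAlignment]:
    """Scan a miRNA over a full transcript; keep windows scoring <= cutoff."""
    mir = normalize(mir_seq)
    tseq = normalize(transcript_seq)
    L = len(mir)
    out = []
    for start in range(0, len(tseq) - L + 1):
        window = tseq[start : start + L]
        score, labels = score_duplex(mir, window)
        if score <= cutoff:
            out.append(
                TargetAlignment(
                    mir_name=mir_name,
                    transcript_id=transcript_id,
                    binding_start=start,
                    binding_end=start + L,
                    score=score,
                    labels=labels,
                    predicted_cleavage_site=start + L - 10,
                )
            )
    return out


def check_cleavage_position(
    binding_start: int,
    binding_end: int,
    site: int,
    counting: str = "mirna",
    allowed: tuple[int, int] = (9, 10),
) -> bool:
    """Is an observed 5'-end site at the expected slice position?

    All coordinates 0-based; ``binding_end`` half-open.  Two counting
    conventions for "the 9th or 10th nucleotide of the binding region":

    * ``"mirna"`` (default): counted opposite miRNA positions 9/10,
      i.e. from the 3' end of the binding region -- the canonical
      slice-site geometry (cleavage across from miRNA positions 10-11);
    * ``"five_prime"``: counted literally from the 5' end of the
      binding region on the target.
    """
    if not binding_start <= site < binding_end:
        return False
    if counting == "mirna":
        ordinal = binding_end - site  # miRNA position facing the site
    elif counting == "five_prime":
        ordinal = site - binding_start + 1
    else:
        raise ValueError(f"unknown counting convention {counting!r}")
    return ordinal in allowed


@dataclass
class HomologyEntry:
    at_gene: str
    known_target_flag: bool = False


def call_targets(
    alignments: Iterable[TargetAlignment],
    profiles: Mapping[str, DegradomeProfile],
    homology_map: Mapping[str, HomologyEntry] | None = None,
    family_of: Mapping[str, str] | None = None,
    counting: str = "mirna",
) -> list[TargetCall]:
    """Combine alignments, degradome evidence and homology into target calls.

    For each retained alignment the most abundant evidence site inside
    the binding region is taken as the observed cleavage site; a call
    is emitted iff that site passes the slice-position check and has at
    least one read.  Without a homology map the homology criterion
    becomes advisory (calls are emitted unannotated, with a warning).
    """
    if homology_map is None:
        log.warning("no homology map supplied; homology filter is advisory")
    calls = []
    for aln in alignments:
        profile = profiles.get(aln.transcript_id)
        if profile is None:
            continue
        sites = [
            (c, -p, p)
            for p, c in profile.position_counts.items()
            if aln.binding_start <= p < aln.binding_end
        ]
        if not sites:
            continue
        _, _, site = max(sites)
        if not check_cleavage_position(
            aln.binding_start, aln.binding_end, site, counting
        ):
            continue
        entry = homology_map.get(aln.transcript_id) if homology_map else None
        family = (family_of or {}).get(aln.mir_name) or aln.mir_name
        calls.append(
            TargetCall(
                mir_family=family,
                mir_name=aln.mir_name,
                target_gene=aln.transcript_id,
                cleavage_site=site + 1,  # 1-based in reports
                reads_at_site=profile.count_at(site),
                category=assign_category(profile, site),
                alignment_score=aln.score,
                homolog=entry.at_gene if entry else None,
                conserved_flag=bool(entry and entry.known_target_flag),
            )
        )
    calls.sort(key=lambda c: (c.mir_family, c.category, -c.reads_at_site, c.target_gene))
    return calls


def emit_tplot(
    profile: DegradomeProfile, sites: Sequence[int] = ()
) -> pd.DataFrame:
    """Per-position table (1-based positions) suitable for any plotting tool."""
    marked = {s for s in sites}
    rows = [
        (pos + 1, count, pos in marked)
        for pos, count in sorted(profile.position_counts.items())
    ]
    return pd.DataFrame(rows, columns=["position", "reads", "is_site"])
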