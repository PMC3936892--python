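"""End-to-end miRNA discovery: reads -> filtered set -> classes ->
validated hairpins -> named miRNAs -> differential expression.

The order of operations mirrors standard small-RNA practice: each
library is cleaned and accounted, the pooled mappable sequences are
split into known / conserved / novel classes, every genome-anchored
candidate is screened through the precursor window ladder (most
abundant first, so a validated duplex consumes its star sequence
before the star is considered as a candidate in its own right), and
the surviving hairpins are named and profiled across the two
libraries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotate import (
    HairpinRecord,
    LocusHit,
    MatureMiRNA,
    assign_names,
    find_conserved_candidates,
    map_to_genome,
    match_known,
    parse_family,
)
from .expression import DEResult, fold_change, normalize_rpm
from .hairpin import FLANK_LADDER, screen_candidate
from .preprocess import FilterReport, ReadRecord, run_preprocess


@dataclass
class DiscoveryConfig:
    adapter: str | None = None
    min_len: int = 15
    max_len: int = 30
    flank_steps: tuple = FLANK_LADDER
    max_genome_hits: int = 20
    max_conserved_mismatches: int = 3
    species: str = "xxx"
    arm_style: str = "5p"
    star_tolerance: int = 2
    pseudo_rpm: float = 0.01
    de_threshold: float = 2.0


@dataclass
class RejectedCandidate:
    sequence: str
    locus: LocusHit
    mirna_class: str  # conserved | novel
    failed_criteria: tuple
    flank: int | None


@dataclass
class DiscoveryResult:
    reports: dict  # lib -> FilterReport
    lib_sizes: dict  # lib -> mappable total
    known_matches: dict  # read seq -> [known names]
    hairpins: list  # validated HairpinRecord
    matures: list  # named MatureMiRNA
    rejected: list  # RejectedCandidate
    counts: dict  # name -> (reads_A, reads_B)
    de: list  # DEResult

    def mature_frame(self) -> pd.DataFrame:
        """Precursor-table style report: one row per named mature arm,
        with the retained window's length, GC%, folding energy and MFEI."""
        by_seq = {}
        for hp in self.hairpins:
            for seq in (hp.mature_seq, hp.star_seq):
                if seq:
                    by_seq.setdefault(seq, hp.candidate)
        rows = []
        for m in self.matures:
            a, b = self.counts.get(m.name, (0, 0))
            cand = by_seq.get(m.sequence)
            if cand is not None and cand.metrics is not None:
                metrics = cand.metrics.rounded()
                lp, cg = cand.precursor_length, metrics.gc_percent
                dg, mfei = metrics.mfe, metrics.mfei
            else:
                lp = cg = dg = mfei = None
            rows.append(
                (m.name, m.sequence, m.mature_length, lp, cg, dg, mfei,
                 m.family, m.arm, m.predicted_only_flag, a, b)
            )
        return pd.DataFrame(
            rows,
            columns=["miR_name", "miR_seq", "LM", "LP", "CG%", "dG", "MFEI",
                     "family", "arm", "predicted", "FbA", "FbB"],
        )

    def de_frame(self) -> pd.DataFrame:
        from .expression import de_table

        return de_table(self.de)


def _build_locus_index(hits_by_seq: Mapping[str, list]) -> dict:
    index: dict[tuple, list] = {}
    for seq, hits in hits_by_seq.items():
        for h in hits:
            index.setdefault((h.chrom, h.strand), []).append((h.start, h.end, seq))
    for key in index:
        index[key].sort()
    return index


def run_discovery(
    genome,
    libraries: Mapping[str, Sequence[ReadRecord]],
    known_species: Mapping[str, str],
    plant_mirs: Mapping[str, str],
    rfam: Sequence[str] = (),
    repbase: Sequence[str] = (),
    config: DiscoveryConfig | None = None,
) -> DiscoveryResult:
    """Run the whole discovery pipeline on raw libraries 'A' and 'B'."""
    config = config or DiscoveryConfig()

    # 1. preprocess each library
    reports: dict[str, FilterReport] = {}
    counts_by_lib: dict[str, dict[str, int]] = {}
    for lib, records in libraries.items():
        staged, report = run_preprocess(
            records, config.adapter, rfam, repbase,
            min_len=config.min_len, max_len=config.max_len,
        )
        reports[lib] = report
        counts_by_lib[lib] = {
            r.sequence: r.count for r in staged if r.kept
        }
    lib_sizes = {lib: reports[lib].mappable_total for lib in reports}

    all_seqs = sorted(set().union(*counts_by_lib.values()))
    total_count = {
        s: sum(counts_by_lib[lib].get(s, 0) for lib in counts_by_lib) for s in all_seqs
    }

    # 2. classify
    known = match_known(all_seqs, known_species)
    hits_by_seq = map_to_genome(all_seqs, genome, config.max_genome_hits)
    candidates = [s for s in hits_by_seq if s not in known]
    conserved, novel = find_conserved_candidates(
        candidates, plant_mirs, config.max_conserved_mismatches
    )

    locus_index = _build_locus_index(hits_by_seq)

    def star_finder(chrom, strand, lo, hi):
        entries = locus_index.get((chrom, strand), [])
        i = bisect.bisect_left(entries, (lo, -1, ""))
        out = []
        while i < len(entries) and entries[i][0] < hi:
            s, e, _seq = entries[i]
            if e <= hi:
                out.append((s, e))
            i += 1
        return out

    # 3. screen known loci first (partner-arm discovery), then candidates
    hairpin_records: list[HairpinRecord] = []
    rejected: list[RejectedCandidate] = []
    consumed_as_star: set[tuple] = set()
    consumed_seqs: set[str] = set()

    def screen(seq: str, locus: LocusHit, mirna_class: str, known_name=None) -> None:
        cand = screen_candidate(
            genome, locus, star_finder,
            flank_steps=config.flank_steps,
            star_tolerance=config.star_tolerance,
        )
        if cand is None:
            return
        star_seq = None
        if cand.star_span is not None:
            star_seq = cand.sequence[cand.star_span[0] : cand.star_span[1]]
        if cand.verdict.passed or (
            known_name is not None and cand.verdict.failed == ("star_detected",)
        ):
            record = HairpinRecord(
                chrom=cand.chrom,
                start=cand.window_start,
                end=cand.window_end,
                strand=cand.strand,
                mature_seq=seq,
                mature_arm=cand.mir_arm,
                star_seq=star_seq,
                star_observed=cand.star_observed,
                family=conserved[seq].family if seq in conserved else None,
                known_name=known_name,
                candidate=cand,
            )
            hairpin_records.append(record)
            consumed_seqs.add(seq)
            if cand.star_observed and star_seq:
                consumed_as_star.add(star_seq)
                # remember the star's genome span so it is not re-screened
                if cand.strand == "+":
                    g = (cand.window_start + cand.star_span[0],
                         cand.window_start + cand.star_span[1])
                else:
                    g = (cand.window_end - cand.star_span[1],
                         cand.window_end - cand.star_span[0])
                consumed_loci.add((cand.chrom, cand.strand) + g)
        else:
            rejected.append(
                RejectedCandidate(seq, locus, mirna_class, cand.verdict.failed, cand.flank)
            )

    consumed_loci: set[tuple] = set()

    for seq in sorted(known, key=lambda s: (-total_count[s], s)):
        for locus in hits_by_seq.get(seq, ()):
            screen(seq, locus, "known", known_name=known[seq][0])

    order = sorted(candidates, key=lambda s: (-total_count[s], s))
    for seq in order:
        if seq in consumed_as_star:
            continue
        mirna_class = "conserved" if seq in conserved else "novel"
        for locus in hits_by_seq[seq]:
            if (locus.chrom, locus.strand, locus.start, locus.end) in consumed_loci:
                continue
            screen(seq, locus, mirna_class)

    # 4. naming
    matures = assign_names(
        hairpin_records, species=config.species, arm_style=config.arm_style
    )
    # known sequences without a validated hairpin still count as known miRNAs
    named_seqs = {m.sequence for m in matures}
    for seq, names in sorted(known.items()):
        if seq in named_seqs:
            continue
        name = names[0]
        arm = "3p" if name.endswith(("3p", "p3")) else "5p"
        matures.append(
            MatureMiRNA(
                name=name, sequence=seq, arm=arm, family=parse_family(name), loci=()
            )
        )

    # 5. expression
    counts: dict[str, tuple] = {}
    for m in matures:
        a = counts_by_lib.get("A", {}).get(m.sequence, 0)
        b = counts_by_lib.get("B", {}).get(m.sequence, 0)
        counts[m.name] = (a, b)
    de: list[DEResult] = []
    if "A" in lib_sizes and "B" in lib_sizes and min(lib_sizes.values()) > 0:
        for rec in normalize_rpm(counts, lib_sizes["A"], lib_sizes["B"]):
            de.append(fold_change(rec, config.pseudo_rpm, config.de_threshold))

    return DiscoveryResult(
        reports=reports,
        lib_sizes=lib_sizes,
        known_matches=known,
        hairpins=hairpin_records,
        matures=matures,
        rejected=rejected,
        counts=counts,
        de=de,
    )
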