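"""Classification and naming of genome-anchored small RNAs.

Mappable reads fall into three disjoint classes:

* **known** -- exact full-length identity with a mature miRNA already
  annotated for the target species;
* **conserved** -- exact genome hit plus a match to a known plant
  mature miRNA of equal length within 3 mismatches (Hamming, no
  indels);
* **novel** -- exact genome hit matching no known plant miRNA.

Names follow the miRBase dialect: ``<species>-miR<family><letter>`` for
conserved candidates (letters distinguish distinct mature sequences
within a family), ``<species>-miRn<k>`` for novel families, ``-1``/``-2``
sub-member indices for identical mature sequences produced from
distinct loci, ``-5p``/``-3p`` arm suffixes, and a ``P-`` prefix for an
arm that was never sequenced and exists only as a structural
prediction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqs import hamming, normalize, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusHit:
    """An exact full-length alignment of a read to the genome."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    read_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.read_sequence):
            raise ValueError("locus length != read length")


@dataclass
class MatureMiRNA:
    """A named mature miRNA with arm and family identity."""

    name: str
    sequence: str
    arm: str  # '5p' or '3p'
    family: str
    submember_index: int | None = None
    predicted_only_flag: bool = False
    loci: tuple = ()

    @property
    def mature_length(self) -> int:
        return len(self.sequence)


def match_known(
    read_seqs: Iterable[str], known: Mapping[str, str]
) -> dict[str, list[str]]:
    """Exact full-length matches of reads against the species' known set.

    ``known`` maps name -> mature sequence (already U->T normalized).
    Returns read sequence -> all matching names (duplicate sequences
    under different names are all reported).
    """
    by_seq: dict[str, list[str]] = {}
    for name, seq in known.items():
        by_seq.setdefault(normalize(seq), []).append(name)
    out = {}
    for rs in read_seqs:
        names = by_seq.get(normalize(rs))
        if names:
            out[rs] = sorted(names)
    return out


def map_to_genome(
    read_seqs: Iterable[str], genome, max_hits: int = 20
) -> dict[str, list[LocusHit]]:
    """All exact full-length genome hits of each read, both strands.

    Reads with no hit are omitted from the result (unmapped); reads
    with more than ``max_hits`` loci are treated as repetitive and
    likewise dropped, with a log message.
    """
    contigs = {chrom: str(genome[chrom][:]) for chrom in _chrom_names(genome)}
    out: dict[str, list[LocusHit]] = {}
    for rs in read_seqs:
        seq = normalize(rs)
        hits = []
        rc = revcomp(seq)
        for chrom, contig in contigs.items():
            for strand, probe in (("+", seq), ("-", rc)):
                start = contig.find(probe)
                while start != -1:
                    hits.append(LocusHit(chrom, start, start + len(seq), strand, rs))
                    start = contig.find(probe, start + 1)
        if not hits:
            continue
        if len(hits) > max_hits:
            log.info("read %s... dropped as repetitive (%d loci)", rs[:12], len(hits))
            continue
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        out[rs] = hits
    return out


def _chrom_names(genome) -> list[str]:
    keys = genome.keys() if hasattr(genome, "keys") else [r.name for r in genome]
    return list(keys)


_FAMILY_RE = re.compile(r"^(?:[a-zA-Z]{3,4}-)?(?:P-)?(miRn?\d+|miR[A-Za-z]*\d*)", re.I)


def parse_family(name: str) -> str:
    """Family token of a miRBase-style name: ath-miR156a-5p -> miR156."""
    m = _FAMILY_RE.match(name)
    if not m:
        return name
    fam = m.group(1)
    # strip a trailing variant letter (miR156a -> miR156)
    return re.sub(r"(?<=\d)[a-z]+$", "", fam)


@dataclass
class ConservedMatch:
    read_sequence: str
    best_name: str
    family: str
    mismatches: int
    tied_families: tuple = ()


def find_conserved_candidates(
    read_seqs: Iterable[str],
    plant_mirs: Mapping[str, str],
    max_mm: int = 3,
) -> tuple[dict[str, ConservedMatch], list[str]]:
    """Split genome-anchored reads into conserved matches and novel leftovers.

    A read is a conserved candidate iff some known plant mature of
    *equal length* is within ``max_mm`` Hamming mismatches; the
    best-scoring known name is recorded and its family inherited.
    Equal-score ties are broken by the lexicographically smallest
    family name and logged.
    """
    by_len: dict[int, list[tuple[str, str, str]]] = {}
    for name, seq in plant_mirs.items():
        seq = normalize(seq)
        by_len.setdefault(len(seq), []).append((seq, name, parse_family(name)))
    conserved: dict[str, ConservedMatch] = {}
    novel: list[str] = []
    for rs in read_seqs:
        seq = normalize(rs)
        best: list[tuple[int, str, str]] = []  # (mm, family, name)
        for kseq, kname, kfam in by_len.get(len(seq), ()):
            mm = hamming(seq, kseq)
            if mm <= max_mm:
                best.append((mm, kfam, kname))
        if not best:
            novel.append(rs)
            continue
        best.sort()
        top_mm = best[0][0]
        top = [b for b in best if b[0] == top_mm]
        families = sorted({fam for _, fam, _ in top})
        if len(families) > 1:
            log.info(
                "read %s...: tie between families %s at %d mismatches; "
                "keeping %s", rs[:12], families, top_mm, families[0]
            )
        _, fam, name = min(top, key=lambda b: (b[1], b[2]))
        conserved[rs] = ConservedMatch(rs, name, fam, top_mm, tuple(families))
    return conserved, novel


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


@dataclass
class HairpinRecord:
    """A validated precursor with its two duplex arms, ready for naming.

    ``family`` is None for novel hairpins (assigned serially) or the
    inherited family token for conserved ones; ``known_name`` overrides
    both when the hairpin extends an already-annotated miRNA.
    """

    chrom: str
    start: int  # precursor window, genome coords
    end: int
    strand: str
    mature_seq: str  # the candidate read that seeded the screen
    mature_arm: str  # '5p' or '3p'
    star_seq: str | None = None
    star_observed: bool = False
    family: str | None = None
    known_name: str | None = None
    candidate: object = None  # retained PrecursorCandidate, if any


def _arm_suffix(arm: str, style: str) -> str:
    return {"5p": {"5p": "5p", "p5": "p5"}, "3p": {"5p": "3p", "p5": "p3"}}[arm][style]


def assign_names(
    hairpins: Sequence[HairpinRecord],
    species: str = "xxx",
    arm_style: str = "5p",
    novel_prefix: str = "miRn",
) -> list[MatureMiRNA]:
    """Deterministically name both arms of each validated hairpin.

    Novel families are numbered in genome-coordinate order of their
    first locus; identical mature sequences from distinct loci get
    ``-1``, ``-2`` sub-member indices (also in coordinate order);
    conserved families reuse the inherited family token with ``a``,
    ``b``... letters for distinct mature sequences; an arm whose read
    was never observed is emitted with the ``P-`` prefix and
    ``predicted_only_flag`` set.
    """
    if arm_style not in ("5p", "p5"):
        raise ValueError("arm_style must be '5p' or 'p5'")
    ordered = sorted(hairpins, key=lambda h: (h.chrom, h.start, h.end, h.strand))
    for h in ordered:
        if h.star_seq is None and h.candidate is None:
            raise ValueError("hairpin with no star sequence and no structure")

    # group loci that produce the same mature sequence -> sub-members
    groups: dict[tuple, list[HairpinRecord]] = {}
    order: list[tuple] = []
    for h in ordered:
        key = ("known", h.known_name) if h.known_name else (
            ("cons", h.family, h.mature_seq) if h.family else ("novel", h.mature_seq)
        )
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(h)

    # conserved: letter per distinct mature within a family
    letters: dict[tuple, str] = {}
    fam_counts: dict[str, int] = {}
    for key in order:
        if key[0] == "cons":
            fam = key[1]
            idx = fam_counts.get(fam, 0)
            fam_counts[fam] = idx + 1
            letters[key] = chr(ord("a") + idx)
    multi_fam = {f for f, c in fam_counts.items() if c > 1}

    novel_no = 0
    out: list[MatureMiRNA] = []
    for key in order:
        members = groups[key]
        if key[0] == "novel":
            novel_no += 1
            base = f"{species}-{novel_prefix}{novel_no}"
            family = f"{novel_prefix}{novel_no}"
        elif key[0] == "cons":
            fam = key[1]
            letter = letters[key] if fam in multi_fam else ""
            base = f"{species}-{fam}{letter}"
            family = fam
        else:
            base = key[1]
            family = parse_family(key[1])
        for sub, h in enumerate(members, start=1):
            stem = f"{base}-{sub}" if len(members) > 1 else base
            sub_index = sub if len(members) > 1 else None
            star_arm = "3p" if h.mature_arm == "5p" else "5p"
            arms = [(h.mature_arm, h.mature_seq, True)]
            if h.star_seq is not None:
                arms.append((star_arm, h.star_seq, h.star_observed))
            for arm, seq, observed in arms:
                name = f"{stem}-{_arm_suffix(arm, arm_style)}"
                if not observed:
                    name = "P-" + name
                out.append(
                    MatureMiRNA(
                        name=name,
                        sequence=seq,
                        arm=arm,
                        family=family,
                        submember_index=sub_index,
                        predicted_only_flag=not observed,
                        loci=((h.chrom, h.start, h.end, h.strand),),
                    )
                )
    return out
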