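"""Synthetic study generator: genome, libraries, contaminants, degradome.

Produces the full input universe for the pipeline -- a toy genome with
planted miRNA hairpins, two adapter-ligated small-RNA libraries with
known per-miRNA abundances, contaminant and junk reads, and a
degradome experiment with planted cleavage sites -- together with
machine-readable ground truth sufficient to score every pipeline
stage.

Hairpin design
--------------
Planted precursors are *alphabet-insulated* so that the weighted
maximum-pairing folder recovers exactly the intended stem: duplex
arms use only G/C (paired region) with A elsewhere (A cannot pair in
the absence of T), or, for the low-MFEI decoy, an A/T-only duplex
padded with C (C cannot pair in the absence of G).  Each mature spans
19 paired bases plus a 2-nt 3' overhang; the star arm is the reverse
complement of the paired region, offset to leave 2-nt 3' overhangs on
both strands.  Decoys perturb exactly one screening criterion:

================  ====================================================
kind              designed violation
================  ====================================================
no_star           star reads withheld (criterion 1)
mismatch_total    4 scattered unpairable star positions (criterion 2)
mismatch_run      4 consecutive unpairable star positions (criterion 2)
bulge_count       two 1-nt star-strand insertions (criterion 3)
bulge_size        one 3-nt star-strand insertion (criterion 3)
blunt_overhang    fully base-paired duplex, no 3' overhangs (criterion 4)
low_mfei          A/U-only stem: pairing too weak for MFEI > 0.8
================  ====================================================

Every planted hairpin (and every decoy, from both arms) is verified at
generation time by running the real screening code against the
assembled genome; the generator resamples and ultimately errors out
rather than emit a truth table the data do not support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import LocusHit
from .degradome import HomologyEntry, align_mir_target, map_degradome_reads, assign_category
from .hairpin import classify_candidate, compute_metrics, evaluate_duplex, screen_candidate
from .fold import fold
from .preprocess import (
    ContaminantIndex,
    FilterReport,
    ReadRecord,
    is_junk,
    surviving_after_cleanup,
    trim_3p_adapter,
)
from .seqs import revcomp

DECOY_KINDS = (
    "no_star",
    "mismatch_total",
    "mismatch_run",
    "bulge_count",
    "bulge_size",
    "blunt_overhang",
    "low_mfei",
)

#: decoy kind -> criterion its rejection must be charged to
DECOY_CRITERION = {
    "no_star": "star_detected",
    "mismatch_total": "duplex_mismatches",
    "mismatch_run": "duplex_mismatches",
    "bulge_count": "asymmetric_bulges",
    "bulge_size": "asymmetric_bulges",
    "blunt_overhang": "arms_and_overhang",
    "low_mfei": "mfei",
}

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe two flower-bud libraries of 2x10^5 reads with 10
    planted novel hairpins, 2 species-known and 2 plant-conserved
    miRNAs, one decoy per violable screening criterion, and a
    degradome of 5 genuine targets plus shuffled decoy transcripts.
    """

    seed: int = 1
    n_true_hairpins: int = 10
    n_known: int = 2
    n_conserved: int = 2
    decoy_kinds: tuple = DECOY_KINDS
    genome_length: int = 30_000
    library_depth: int = 200_000
    abundance_range: tuple = (6_000.0, 16_000.0)
    decoy_abundance_range: tuple = (800.0, 2_000.0)
    star_fraction: float = 0.1
    adapter: str = DEFAULT_ADAPTER
    contaminant_fraction: float = 0.05
    junk_fraction: float = 0.02
    no_adapter_fraction: float = 0.02
    short_fraction: float = 0.02
    long_fraction: float = 0.01
    n_targets: int = 5
    n_decoy_transcripts: int = 3
    transcript_length: int = 1_200
    degradome_depth: int = 2_000
    peak_fraction: float = 0.8
    species: str = "xxx"
    loop_len: int = 8
    flank: int = 50
    spacing: int = 200
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0.5 < self.peak_fraction <= 1.0:
            raise ValueError("peak_fraction must lie in (0.5, 1] so planted sites are maxima")
        for name in ("n_true_hairpins", "library_depth", "genome_length",
                     "degradome_depth", "n_targets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("decoy_kinds", "abundance_range", "decoy_abundance_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PlantedHairpin:
    """Ground truth for one planted locus."""

    hid: str
    cls: str  # novel | known | conserved | decoy
    kind: str  # 'true' or a decoy kind
    violated: str | None
    chrom: str
    prec_start: int
    prec_end: int
    strand: str
    mature: str
    star: str
    star_emitted: bool
    mature_locus: tuple  # genome coords, 0-based half-open
    star_locus: tuple
    ratio: float  # planted B:A abundance ratio (RPM scale)
    known_name: str | None = None
    foreign_name: str | None = None  # conserved: the foreign plant miRNA entry
    expected_counts: dict = field(default_factory=dict)  # arm -> {lib: count}

    @property
    def de_class(self) -> str:
        if self.ratio > 2.0:
            return "up_in_B"
        if self.ratio < 0.5:
            return "up_in_A"
        return "unchanged"

    @property
    def planted_fold(self) -> float:
        return max(self.ratio, 1.0 / self.ratio)


@dataclass
class PlantedTarget:
    transcript_id: str
    mir_hid: str
    mature: str
    binding_start: int  # 0-based
    cleavage_site: int  # 0-based; reports add 1
    expected_category: int
    is_decoy: bool = False


@dataclass
class SimTruth:
    hairpins: list = field(default_factory=list)
    expected_reports: dict = field(default_factory=dict)  # lib -> FilterReport
    targets: list = field(default_factory=list)

    def hairpin_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hairpins:
            rows.append({
                "hid": h.hid, "class": h.cls, "kind": h.kind,
                "violated": h.violated or "", "chrom": h.chrom,
                "prec_start": h.prec_start, "prec_end": h.prec_end,
                "strand": h.strand, "mature": h.mature, "star": h.star,
                "star_emitted": h.star_emitted,
                "mature_start": h.mature_locus[0], "mature_end": h.mature_locus[1],
                "star_start": h.star_locus[0], "star_end": h.star_locus[1],
                "ratio": h.ratio, "de_class": h.de_class,
                "count_A_mature": h.expected_counts.get("mature", {}).get("A", 0),
                "count_B_mature": h.expected_counts.get("mature", {}).get("B", 0),
                "count_A_star": h.expected_counts.get("star", {}).get("A", 0),
                "count_B_star": h.expected_counts.get("star", {}).get("B", 0),
            })
        return pd.DataFrame(rows)

    def target_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.targets])


@dataclass
class SimBundle:
    """All simulated inputs plus ground truth, in memory."""

    config: SimConfig
    genome: dict
    libraries: dict  # lib -> list[ReadRecord] (collapsed raw reads)
    known_species: dict  # name -> mature sequence (species' own annotation)
    plant_mirs: dict  # name -> mature sequence (all-plant reference)
    rfam: list
    repbase: list
    truth: SimTruth
    transcripts: dict = field(default_factory=dict)
    degradome_reads: list = field(default_factory=list)  # (sequence, count)
    homology: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "genome.fa", self.genome.items())
        for lib, records in self.libraries.items():
            _write_fastq(out / f"lib{lib}.fastq", records)
        _write_fasta(out / "known_mature.fa", self.known_species.items())
        _write_fasta(out / "plant_mirnas.fa", self.plant_mirs.items())
        _write_fasta(out / "rfam.fa", ((f"rfam_{i}", s) for i, s in enumerate(self.rfam)))
        _write_fasta(out / "repbase.fa", ((f"repbase_{i}", s) for i, s in enumerate(self.repbase)))
        if self.transcripts:
            _write_fasta(out / "transcripts.fa", self.transcripts.items())
            _write_fastq(
                out / "degradome.fastq",
                [ReadRecord(f"d{i}", seq, count)
                 for i, (seq, count) in enumerate(self.degradome_reads)],
            )
            pd.DataFrame(
                [(tid, e.at_gene, e.known_target_flag) for tid, e in self.homology.items()],
                columns=["transcript_id", "at_gene_id", "known_target_flag"],
            ).to_csv(out / "homology.tsv", sep="\t", index=False)
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        self.truth.hairpin_frame().to_csv(tdir / "hairpins.tsv", sep="\t", index=False)
        if self.truth.targets:
            self.truth.target_frame().to_csv(tdir / "targets.tsv", sep="\t", index=False)
        for lib, report in self.truth.expected_reports.items():
            report.to_frame().to_csv(tdir / f"filter_report_{lib}.tsv", sep="\t", index=False)


def _write_fasta(path, items, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            seq = str(seq)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for i in range(rec.count):
                fh.write(f"@{rec.read_id}_{i}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------


def _draw_core(rng, k: int, alphabet: str) -> str:
    """Random duplex core containing both alphabet letters."""
    while True:
        core = "".join(rng.choice(list(alphabet), size=k))
        if len(set(core)) == 2:
            return core


def make_hairpin(rng, kind: str = "true", loop_len: int = 8, flank: int = 50) -> dict:
    """Construct one precursor with designed duplex spans.

    Returns a dict with the precursor sequence, mature/star sequences,
    their 0-based spans on the precursor, and the criteria the design
    is expected to fail (empty for a sound hairpin).  The construction
    is verified by folding before being accepted; an unverifiable draw
    raises after bounded retries.
    """
    expected_failed = ()
    if kind in DECOY_CRITERION:
        expected_failed = (DECOY_CRITERION[kind],)
    elif kind != "true":
        raise ValueError(f"unknown hairpin kind {kind!r}")

    for _ in range(50):
        pad, overhang = "A", "AA"
        if kind == "low_mfei":
            core = _draw_core(rng, 19, "AT")
            pad, overhang = "C", "CC"
            mature = core + overhang
            star = revcomp(core) + overhang
        elif kind == "blunt_overhang":
            core = list(_draw_core(rng, 21, "GC"))
            core[10] = "A"  # keeps the read above the low-complexity screen
            mature = "".join(core)
            star = revcomp(mature)
        else:
            core = _draw_core(rng, 19, "GC")
            mature = core + overhang
            star_core = list(revcomp(core))
            if kind == "mismatch_total":
                for j in (2, 6, 10, 14):
                    star_core[j] = "A"
            elif kind == "mismatch_run":
                for j in (8, 9, 10, 11):
                    star_core[j] = "A"
            elif kind == "bulge_count":
                star_core = star_core[:5] + ["A"] + star_core[5:13] + ["A"] + star_core[13:]
            elif kind == "bulge_size":
                star_core = star_core[:9] + ["A", "A", "A"] + star_core[9:]
            star = "".join(star_core) + overhang

        right_pad = flank - loop_len - len(star)
        if right_pad < 0:
            raise ValueError("flank too small for loop and star arm")
        precursor = pad * flank + mature + pad * loop_len + star + pad * right_pad
        mir_span = (flank, flank + len(mature))
        star_span = (mir_span[1] + loop_len, mir_span[1] + loop_len + len(star))

        structure, mfe = fold(precursor)
        duplex = evaluate_duplex(structure, mir_span, star_span)
        metrics = compute_metrics(mfe, sequence=precursor)
        verdict = classify_candidate(duplex, metrics, star_observed=(kind != "no_star"))
        if verdict.failed == expected_failed:
            return {
                "kind": kind,
                "precursor": precursor,
                "mature": mature,
                "star": star,
                "mir_span": mir_span,
                "star_span": star_span,
                "expected_failed": expected_failed,
            }
    raise RuntimeError(f"could not construct a verifiable {kind} hairpin")


# ---------------------------------------------------------------------------
# genome and libraries
# ---------------------------------------------------------------------------


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _ratio_plan(n: int) -> list[float]:
    cycle = [4.0, 1.0, 0.25, 1.0, 3.0, 1.0, 1.0 / 3.0, 1.0, 5.0, 0.2]
    return [cycle[i % len(cycle)] for i in range(n)]


def _plan_abundances(config: SimConfig, rng, hairpins, budget_fraction=0.82,
                     attempts: int = 20) -> None:
    """Fix per-library expected read counts for every planted arm.

    Expectations in the two libraries follow each hairpin's designed
    ratio and are rescaled so both libraries spend the same expected
    mappable budget; the truth ratio is updated to the exact RPM ratio
    this plants (within a few percent of the designed value, enforced
    so the designed DE class is preserved).
    """
    target = budget_fraction * config.library_depth
    for _ in range(attempts):
        raw = {}
        for h in hairpins:
            lo, hi = (config.decoy_abundance_range if h.cls == "decoy"
                      else config.abundance_range)
            base = _loguniform(rng, lo, hi)
            scale = math.sqrt(h.ratio)
            raw[h.hid] = (base / scale, base * scale)
        # when up- and down-regulated groups both exist, rescale the
        # up-group (ratio preserved) so both library sums match exactly
        up = [h.hid for h in hairpins if h.ratio > 1]
        down = [h.hid for h in hairpins if h.ratio < 1]
        if up and down:
            u_a = sum(raw[hid][0] for hid in up)
            u_b = sum(raw[hid][1] for hid in up)
            d_a = sum(raw[hid][0] for hid in down)
            d_b = sum(raw[hid][1] for hid in down)
            alpha = (d_b - d_a) / (u_a - u_b)
            if 0.1 <= alpha <= 10.0:
                for hid in up:
                    a, b = raw[hid]
                    raw[hid] = (a * alpha, b * alpha)
        per_arm = 1.0 + config.star_fraction
        sums = {
            "A": sum(a * per_arm for a, _ in raw.values()),
            "B": sum(b * per_arm for _, b in raw.values()),
        }
        factor = {lib: target / sums[lib] for lib in sums}
        shift = factor["B"] / factor["A"]

        def declass(r: float) -> str:
            return "up_in_B" if r > 2 else ("up_in_A" if r < 0.5 else "unchanged")

        # planted folds must keep a margin around the two-fold boundary so
        # sampling noise cannot flip the designed DE class
        planted = {h.hid: h.ratio * shift for h in hairpins}
        ok = all(
            declass(planted[h.hid]) == declass(h.ratio)
            and (max(planted[h.hid], 1 / planted[h.hid]) > 2.3
                 or max(planted[h.hid], 1 / planted[h.hid]) < 1.7)
            for h in hairpins
        )
        if ok:
            for h in hairpins:
                h.expected_counts["expect"] = {
                    "A": raw[h.hid][0] * factor["A"],
                    "B": raw[h.hid][1] * factor["B"],
                }
                h.ratio = planted[h.hid]
            return
    raise RuntimeError("could not balance library abundances")


def _loguniform(rng, lo: float, hi: float) -> float:
    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def build_genome_and_libraries(config: SimConfig, rng=None) -> SimBundle:
    """Plant hairpins in a toy genome and emit two read libraries.

    Deterministic given ``config.seed``; the assembled genome is
    re-screened with the production code and rebuilt (bounded retries)
    if any planted truth is not recovered as designed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    # --- draw hairpins -----------------------------------------------------
    plans: list[tuple[str, str]] = []  # (cls, kind)
    plans += [("known", "true")] * config.n_known
    plans += [("conserved", "true")] * config.n_conserved
    plans += [("novel", "true")] * config.n_true_hairpins
    decoys = list(config.decoy_kinds)
    # keep the C-padded low-MFEI decoy at the chromosome end, preceded by the
    # structure-independent no_star decoy, so its C-rich spacers only ever
    # appear in windows whose verdict cannot depend on them
    for special in ("no_star", "low_mfei"):
        if special in decoys:
            decoys.remove(special)
            decoys.append(special)
    plans += [("decoy", kind) for kind in decoys]

    designs = []
    seen_matures: set[str] = set()
    for cls, kind in plans:
        while True:
            d = make_hairpin(rng, kind, config.loop_len, config.flank)
            if d["mature"] not in seen_matures and d["star"] not in seen_matures:
                break
        seen_matures.add(d["mature"])
        seen_matures.add(d["star"])
        d["cls"] = cls
        designs.append(d)

    # --- assemble genome with verification --------------------------------
    slot = 2 * config.flank + 21  # nominal precursor footprint
    needed = len(designs) * (slot + config.spacing) + config.spacing
    if config.genome_length < needed:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{len(designs)} hairpins (needs >= {needed})"
        )
    for attempt in range(20):
        hairpins, contig = _assemble(config, rng, designs)
        genome = {config.chrom: contig}
        if _verify_in_context(config, genome, hairpins):
            break
    else:
        raise RuntimeError("could not assemble a genome matching the planted truth")

    # --- reference sets ----------------------------------------------------
    known_species: dict[str, str] = {}
    plant_mirs: dict[str, str] = {}
    k = c = 0
    for h in hairpins:
        if h.cls == "known":
            k += 1
            h.known_name = f"{config.species}-miR90{k}"
            known_species[h.known_name] = h.mature
        elif h.cls == "conserved":
            c += 1
            variant = list(h.mature)
            for j in (3, 12):  # 2 mismatches, staying on the G/C stem alphabet
                variant[j] = "C" if variant[j] == "G" else "G"
            h.foreign_name = f"aly-miR80{c}"
            plant_mirs[h.foreign_name] = "".join(variant)
    # plant reference also carries the species' own annotation plus padding
    plant_mirs.update(known_species)
    plant_mirs["osa-miR7777"] = _random_dna(rng, 21)

    # the P- (predicted partner) case: the last known hairpin has no star reads
    for h in reversed(hairpins):
        if h.cls == "known":
            h.star_emitted = False
            break

    # --- contaminant references -------------------------------------------
    rfam = [_random_dna(rng, 500) for _ in range(3)]
    repbase = [_random_dna(rng, 400) for _ in range(2)]

    # --- abundances ---------------------------------------------------------
    # designed cross-library ratios pair r with 1/r so the two libraries
    # stay near the same mappable depth; each library is then rescaled to a
    # common expected budget and the truth records the exact RPM ratio that
    # rescaling plants
    ratios = iter(_ratio_plan(sum(1 for h in hairpins if h.cls == "novel")))
    known_ratios = iter([1.0, 1.0])
    cons_ratios = iter([4.0, 0.25])
    for h in hairpins:
        if h.cls == "novel":
            h.ratio = next(ratios)
        elif h.cls == "known":
            h.ratio = next(known_ratios, 1.0)
        elif h.cls == "conserved":
            h.ratio = next(cons_ratios, 1.0)
        else:
            h.ratio = 1.0
    _plan_abundances(config, rng, hairpins)

    libraries: dict[str, list[ReadRecord]] = {}
    truth = SimTruth(hairpins=hairpins)
    contaminant_sets = (ContaminantIndex(rfam), ContaminantIndex(repbase))
    for lib in ("A", "B"):
        records, report = _emit_library(config, rng, lib, hairpins, rfam, repbase,
                                        contaminant_sets)
        libraries[lib] = records
        truth.expected_reports[lib] = report

    return SimBundle(
        config=config,
        genome=genome,
        libraries=libraries,
        known_species=known_species,
        plant_mirs=plant_mirs,
        rfam=rfam,
        repbase=repbase,
        truth=truth,
    )


def _assemble(config: SimConfig, rng, designs) -> tuple[list[PlantedHairpin], str]:
    for _ in range(50):
        result = _assemble_once(config, rng, designs)
        if result is not None:
            return result
    raise RuntimeError("could not assemble a genome with uniquely mapping reads")


def _assemble_once(config: SimConfig, rng, designs):
    parts: list[str] = []
    pos = 0
    hairpins: list[PlantedHairpin] = []
    for i, d in enumerate(designs):
        spacer_char = None
        if d["kind"] == "low_mfei":
            spacer_char = "C"
        spacer = spacer_char * config.spacing if spacer_char else _random_dna(rng, config.spacing)
        parts.append(spacer)
        pos += config.spacing
        prec = d["precursor"]
        mature_locus = (pos + d["mir_span"][0], pos + d["mir_span"][1])
        star_locus = (pos + d["star_span"][0], pos + d["star_span"][1])
        hairpins.append(
            PlantedHairpin(
                hid=f"hp{i:02d}",
                cls=d["cls"],
                kind=d["kind"],
                violated=d["expected_failed"][0] if d["expected_failed"] else None,
                chrom=config.chrom,
                prec_start=pos,
                prec_end=pos + len(prec),
                strand="+",
                mature=d["mature"],
                star=d["star"],
                star_emitted=d["kind"] != "no_star",
                mature_locus=mature_locus,
                star_locus=star_locus,
                ratio=1.0,
            )
        )
        parts.append(prec)
        pos += len(prec)
        if d["kind"] == "low_mfei":
            parts.append("C" * config.spacing)
            pos += config.spacing
    tail = config.genome_length - pos
    if tail > 0:
        parts.append(_random_dna(rng, tail))
    contig = "".join(parts)
    # every planted read sequence must occur exactly once on the forward
    # strand; reverse-strand occurrences are only expected for the blunt
    # decoy, whose star is the exact reverse complement of its mature
    for h in hairpins:
        mirror_ok = 1 if h.kind == "blunt_overhang" else 0
        for seq in (h.mature, h.star):
            if contig.count(seq) != 1 or contig.count(revcomp(seq)) != mirror_ok:
                return None  # resample fillers
    return hairpins, contig


def _planted_read_loci(hairpins) -> dict:
    loci: dict[tuple, list] = {}
    for h in hairpins:
        loci.setdefault((h.chrom, h.strand), []).append(h.mature_locus)
        if h.star_emitted:
            loci.setdefault((h.chrom, h.strand), []).append(h.star_locus)
        if h.kind == "blunt_overhang":
            # palindromic duplex: both reads also map on the minus strand
            other = "-" if h.strand == "+" else "+"
            loci.setdefault((h.chrom, other), []).append(h.mature_locus)
            if h.star_emitted:
                loci.setdefault((h.chrom, other), []).append(h.star_locus)
    return loci


def _verify_in_context(config: SimConfig, genome, hairpins) -> bool:
    """Re-screen every planted locus with the production code."""
    loci = _planted_read_loci(hairpins)

    def star_finder(chrom, strand, lo, hi):
        return loci.get((chrom, strand), [])

    for h in hairpins:
        locus = LocusHit(h.chrom, *h.mature_locus, strand=h.strand, read_sequence=h.mature)
        res = screen_candidate(genome, locus, star_finder)
        if h.kind == "true":
            if res is None or not res.verdict.passed or not res.star_observed:
                return False
        else:
            expected = (DECOY_CRITERION[h.kind],)
            if res is None or res.verdict.passed or res.verdict.failed != expected:
                return False
            if h.star_emitted:  # the decoy's star arm must not validate either
                star = LocusHit(h.chrom, *h.star_locus, strand=h.strand,
                                read_sequence=h.star)
                sres = screen_candidate(genome, star, star_finder)
                if sres is not None and sres.verdict.passed:
                    return False
            if h.kind == "blunt_overhang":
                # the palindromic duplex also maps on the minus strand
                for locus in (
                    LocusHit(h.chrom, *h.star_locus, strand="-", read_sequence=h.mature),
                    LocusHit(h.chrom, *h.mature_locus, strand="-", read_sequence=h.star),
                ):
                    mres = screen_candidate(genome, locus, star_finder)
                    if mres is not None and mres.verdict.passed:
                        return False
    return True


# ---------------------------------------------------------------------------
# library emission
# ---------------------------------------------------------------------------


def _poisson_at_least_one(rng, lam: float) -> int:
    return max(1, int(rng.poisson(lam)))


def _emit_library(config, rng, lib, hairpins, rfam, repbase, contaminant_sets):
    """Emit one library's collapsed raw reads plus its expected ledger."""
    adapter = config.adapter
    rfam_idx, repbase_idx = contaminant_sets
    emitted: list[tuple[str, str, int, str]] = []  # (raw, insert, count, category)
    raw_seen: set[str] = set()

    def classify(raw: str) -> tuple[str, str]:
        """Expected fate of a raw read under the filter chain (oracle-free)."""
        rec = trim_3p_adapter(ReadRecord("probe", raw), adapter)
        if not rec.kept:
            return raw, "no_3adt"
        insert = rec.sequence
        if len(insert) < 15:
            return insert, "too_short"
        if len(insert) > 30:
            return insert, "too_long"
        if is_junk(insert):
            return insert, "junk"
        if insert in rfam_idx:
            return insert, "rfam"
        if insert in repbase_idx:
            return insert, "repbase"
        return insert, "mappable"

    def emit(raw: str, count: int, want: str, retries=None) -> bool:
        if raw in raw_seen:
            return False
        insert, got = classify(raw)
        if got != want:
            if retries is None:
                raise RuntimeError(f"planted read classifies as {got}, expected {want}")
            return False
        raw_seen.add(raw)
        emitted.append((raw, insert, count, want))
        return True

    def emit_resampling(draw, count: int, want: str, attempts: int = 50) -> None:
        for _ in range(attempts):
            if emit(draw(), count, want, retries=True):
                return
        raise RuntimeError(f"could not draw a clean {want} read")

    # planted miRNA reads
    for h in hairpins:
        expectation = h.expected_counts["expect"][lib]
        n_mature = _poisson_at_least_one(rng, expectation)
        emit(h.mature + adapter, n_mature, "mappable")
        h.expected_counts.setdefault("mature", {})[lib] = n_mature
        if h.star_emitted:
            n_star = _poisson_at_least_one(rng, config.star_fraction * expectation)
            emit(h.star + adapter, n_star, "mappable")
            h.expected_counts.setdefault("star", {})[lib] = n_star

    depth = config.library_depth

    def spread(total: int, n_unique: int):
        lam = total / n_unique
        return [_poisson_at_least_one(rng, lam) for _ in range(n_unique)]

    # contaminants: windows of the reference contaminant sequences
    rfam_total = int(config.contaminant_fraction * depth * 0.7)
    repbase_total = int(config.contaminant_fraction * depth * 0.3)
    for total, n_unique, sources, want in (
        (rfam_total, 30, rfam, "rfam"),
        (repbase_total, 15, repbase, "repbase"),
    ):
        for count in spread(total, n_unique):
            def draw_window():
                src = sources[rng.integers(len(sources))]
                w = int(rng.integers(20, 25))
                start = int(rng.integers(0, len(src) - w))
                return src[start : start + w] + adapter
            emit_resampling(draw_window, count, want)

    # junk: homopolymer/dimer artifacts and N-rich reads
    junk_total = int(config.junk_fraction * depth)
    junk_draws = []
    for count in spread(junk_total, 12):
        def draw_junk():
            style = rng.integers(3)
            n = int(rng.integers(18, 25))
            if style == 0:
                insert = str(rng.choice(list("ACGT"))) * n
            elif style == 1:
                a, b = rng.choice(list("ACGT"), size=2, replace=False)
                insert = (str(a) + str(b)) * (n // 2)
            else:
                insert = list(_random_dna(rng, 20))
                for j in rng.choice(20, size=3, replace=False):
                    insert[int(j)] = "N"
                insert = "".join(insert)
            return insert + adapter
        emit_resampling(draw_junk, count, "junk")

    # adapter-less reads
    for count in spread(int(config.no_adapter_fraction * depth), 20):
        emit_resampling(lambda: _random_dna(rng, int(rng.integers(18, 26))),
                        count, "no_3adt")

    # length outliers
    for count in spread(int(config.short_fraction * depth), 15):
        emit_resampling(lambda: _random_dna(rng, int(rng.integers(8, 14))) + adapter,
                        count, "too_short")
    for count in spread(int(config.long_fraction * depth), 10):
        emit_resampling(lambda: _random_dna(rng, int(rng.integers(31, 35))) + adapter,
                        count, "too_long")

    # expected ledger, computed from the planted categories alone
    report = FilterReport()
    insert_seen: dict[str, set] = {}
    for raw, insert, count, category in emitted:
        report.raw_total += count
        report.raw_unique += 1
        key = insert if insert else "-"
        bucket = insert_seen.setdefault(category, set())
        fresh = key not in bucket
        bucket.add(key)
        if category == "mappable":
            report.mappable_total += count
            report.mappable_unique += fresh
        else:
            report.removed[category] += count
            report.removed_unique[category] += fresh
    report.surviving_15_30 = surviving_after_cleanup(
        report.raw_total,
        report.removed["no_3adt"],
        report.removed["too_short"],
        report.removed["junk"],
        report.removed["too_long"],
    )
    report.validate()

    records = [
        ReadRecord(f"{lib.lower()}{i:05d}", raw, count)
        for i, (raw, _insert, count, _cat) in enumerate(emitted)
    ]
    order = rng.permutation(len(records))
    return [records[i] for i in order], report


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------


def build_degradome(bundle: SimBundle, rng=None) -> SimBundle:
    """Plant miRNA targets in a toy transcriptome and emit degradome reads.

    Each genuine target embeds the exact reverse complement of a
    planted novel mature; ``peak_fraction`` of its reads start at the
    position opposite miRNA nucleotide 10 (the canonical slice site)
    and the remainder are uniform background.  Decoy transcripts carry
    a shuffled binding site that no planted miRNA aligns to below the
    score cutoff.
    """
    config = bundle.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 10_007)
    novel = [h for h in bundle.truth.hairpins if h.cls == "novel"][: config.n_targets]
    if len(novel) < config.n_targets:
        raise ValueError("not enough planted novel hairpins for the requested targets")
    all_matures = [h.mature for h in bundle.truth.hairpins]

    transcripts: dict[str, str] = {}
    degradome: list[tuple[str, int]] = []
    targets: list[PlantedTarget] = []
    homology: dict[str, HomologyEntry] = {}
    per_target = max(config.degradome_depth // max(config.n_targets, 1), 10)

    for i, h in enumerate(novel):
        tid = f"T{i + 1:04d}"
        L = len(h.mature)
        site_seq = revcomp(h.mature)
        for _ in range(50):
            body = _random_dna(rng, config.transcript_length)
            b = int(rng.integers(200, config.transcript_length - 200))
            tseq = body[:b] + site_seq + body[b + L:]
            if tseq.count(site_seq) == 1:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a unique binding site")
        cleavage = b + L - 10  # 0-based: base paired to miRNA position 10
        n_peak = int(round(config.peak_fraction * per_target))
        n_bg = per_target - n_peak
        counts: dict[int, int] = {cleavage: n_peak}
        for _ in range(n_bg):
            p = int(rng.integers(0, len(tseq) - 20))
            counts[p] = counts.get(p, 0) + 1
        for pos, count in sorted(counts.items()):
            degradome.append((tseq[pos : pos + 20], count))
        transcripts[tid] = tseq
        targets.append(
            PlantedTarget(tid, h.hid, h.mature, b, cleavage, expected_category=0)
        )
        homology[tid] = HomologyEntry(at_gene=f"AT{i + 1}G{10000 + i * 7:05d}",
                                      known_target_flag=True)

    for j in range(config.n_decoy_transcripts):
        tid = f"D{j + 1:04d}"
        h = novel[j % len(novel)]
        for _ in range(100):
            site = list(revcomp(h.mature))
            rng.shuffle(site)
            body = _random_dna(rng, config.transcript_length)
            b = int(rng.integers(200, config.transcript_length - 200))
            tseq = body[:b] + "".join(site) + body[b + len(site):]
            if all(
                not align_mir_target("m", m, tid, tseq) for m in all_matures
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not shuffle a non-aligning decoy site")
        n_bg = max(per_target // 4, 5)
        counts = {}
        for _ in range(n_bg):
            p = int(rng.integers(0, len(tseq) - 20))
            counts[p] = counts.get(p, 0) + 1
        for pos, count in sorted(counts.items()):
            degradome.append((tseq[pos : pos + 20], count))
        transcripts[tid] = tseq
        targets.append(PlantedTarget(tid, h.hid, h.mature, b, -1, -1, is_decoy=True))
        homology[tid] = HomologyEntry(at_gene=f"AT{j + 1}G{90000 + j:05d}",
                                      known_target_flag=False)

    # verify planted sites score as designed before publishing the truth
    profiles = map_degradome_reads(degradome, transcripts)
    for t in targets:
        if t.is_decoy:
            continue
        if assign_category(profiles[t.transcript_id], t.cleavage_site) != t.expected_category:
            raise RuntimeError(f"planted site on {t.transcript_id} lost its category")

    bundle.transcripts = transcripts
    bundle.degradome_reads = degradome
    bundle.homology = homology
    bundle.truth.targets = targets
    return bundle


def simulate(config: SimConfig | None = None, **overrides) -> SimBundle:
    """Generate the complete synthetic study (genome, libraries, degradome)."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    bundle = build_genome_and_libraries(config)
    return build_degradome(bundle)
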