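"""Precursor hairpin screening: duplex geometry and folding metrics.

A candidate mature read anchored on the genome is screened by
extracting a ladder of precursor windows around it, folding each
window, locating the miRNA/miRNA* duplex on the folded stem, and
applying five criteria:

1. the star (partner-arm) sequence is itself observed in the reads;
2. the duplex has fewer than 4 mismatched bases and no run of 4
   consecutive mismatches;
3. at most one asymmetric bulge, no larger than 2 nt;
4. the two sequences sit on opposite stem arms and form a duplex with
   2-nt 3' overhangs;
5. the precursor's minimal folding energy index (MFEI) exceeds 0.8.

MFEI = AMFE / GC%, with AMFE = |MFE| / length * 100; the index
penalizes sequences whose folding energy is explained by base
composition alone, which separates miRNA precursors from other small
RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .fold import fold, pair_table
from .seqs import gc_percent, revcomp

#: default flank ladder (nt each side) for precursor window extraction
FLANK_LADDER = (20, 50, 100, 150)

#: expected 3' overhang of each duplex strand, nt
OVERHANG = 2

CRITERIA = (
    "star_detected",
    "duplex_mismatches",
    "asymmetric_bulges",
    "arms_and_overhang",
    "mfei",
)


@dataclass
class ThermoMetrics:
    """Composition/energy metrics of a precursor window.

    gc_percent is a percentage of the window; amfe is kcal/mol per
    100 nt; mfei is dimensionless.  Full precision is kept internally;
    reports round to 1 decimal.
    """

    gc_percent: float
    mfe: float
    amfe: float
    mfei: float

    def rounded(self) -> "ThermoMetrics":
        return ThermoMetrics(
            round(self.gc_percent, 1), round(self.mfe, 1),
            round(self.amfe, 1), round(self.mfei, 1),
        )


def compute_metrics(
    mfe: float,
    sequence: str | None = None,
    length: int | None = None,
    gc: float | None = None,
) -> ThermoMetrics:
    """MFE/AMFE/MFEI from a sequence, or directly from length and GC%.

    ``mfe`` is in kcal/mol (<= 0).  Passing ``length`` and ``gc``
    explicitly reproduces tabulated values without refolding.
    """
    if sequence is not None:
        if not sequence:
            raise ValueError("empty sequence")
        length = len(sequence)
        gc = gc_percent(sequence)
    if not length:
        raise ValueError("precursor length must be positive")
    if gc is None or gc <= 0:
        raise ValueError("GC percent must be positive")
    amfe = abs(mfe) / length * 100.0
    return ThermoMetrics(gc_percent=gc, mfe=mfe, amfe=amfe, mfei=amfe / gc)


@dataclass
class DuplexReport:
    """Parsed miRNA/miRNA* duplex features on a folded precursor."""

    mismatch_count: int
    max_consecutive_mismatches: int
    asymmetric_bulge_count: int
    max_asymmetric_bulge_size: int
    overhang_3p_ok: bool
    opposite_arms_ok: bool
    mir_3p_overhang: int | None = None
    star_3p_overhang: int | None = None


def _span_check(span: tuple[int, int], n: int, what: str) -> None:
    s, e = span
    if not (0 <= s < e <= n):
        raise ValueError(f"{what} {span} outside structure of length {n}")


def evaluate_duplex(
    structure: str,
    mir_span: tuple[int, int],
    star_span: tuple[int, int],
    overhang: int = OVERHANG,
) -> DuplexReport:
    """Score the miRNA/miRNA* duplex geometry on a dot-bracket structure.

    Spans are 0-based half-open on the precursor.  A mismatch is a
    miRNA position (excluding its expected ``overhang`` 3'-terminal
    bases) that is unpaired or paired outside the star span.  An
    asymmetric bulge is a run of unpaired bases on one duplex strand
    with no opposing unpaired run.  Overhangs are measured as the
    number of 3'-terminal bases of each strand beyond its outermost
    base paired to the partner.
    """
    pt = pair_table(structure)
    n = len(structure)
    _span_check(mir_span, n, "mir_span")
    _span_check(star_span, n, "star_span")
    ms, me = mir_span
    ss, se = star_span
    if max(ms, ss) < min(me, se):
        raise ValueError("mir_span and star_span overlap")

    in_star = lambda p: p is not None and ss <= p < se
    core = range(ms, me - overhang)

    # --- mismatches over the miRNA core ---
    mismatch = 0
    max_run = run = 0
    for i in core:
        if in_star(pt[i]):
            run = 0
        else:
            mismatch += 1
            run += 1
            max_run = max(max_run, run)

    # --- duplex column walk for asymmetric bulges ---
    paired = [(i, pt[i]) for i in core if in_star(pt[i])]
    bulges: list[int] = []
    for (i1, p1), (i2, p2) in zip(paired, paired[1:]):
        a = i2 - i1 - 1  # unpaired on the miRNA strand
        b = abs(p2 - p1) - 1  # unpaired on the star strand
        if a > 0 and b == 0:
            bulges.append(a)
        elif b > 0 and a == 0:
            bulges.append(b)
        # a == b or both > 0: opposing unpaired runs, counted as mismatches

    # --- 3' overhangs ---
    mir_paired = [i for i in range(ms, me) if in_star(pt[i])]
    star_paired = [j for j in range(ss, se) if pt[j] is not None and ms <= pt[j] < me]
    if mir_paired and star_paired:
        mir_oh = (me - 1) - max(mir_paired)
        star_oh = (se - 1) - max(star_paired)
        overhang_ok = mir_oh == overhang and star_oh == overhang
    else:
        mir_oh = star_oh = None
        overhang_ok = False

    # --- opposite arms: both spans (minus their 3' overhangs) must sit
    # strictly outside the terminal loop enclosed by the innermost pair ---
    opposite = False
    if mir_paired and star_paired:
        if ms < ss:
            left, right, left_paired = mir_span, star_span, mir_paired
        else:
            left, right, left_paired = star_span, mir_span, star_paired
        inner_left = max(left_paired)
        inner_right = pt[inner_left]
        if inner_right is not None and inner_right > inner_left:
            eff_left_end = left[1] - 1 - overhang
            eff_right_start = right[0]
            opposite = eff_left_end <= inner_left and eff_right_start >= inner_right

    return DuplexReport(
        mismatch_count=mismatch,
        max_consecutive_mismatches=max_run,
        asymmetric_bulge_count=len(bulges),
        max_asymmetric_bulge_size=max(bulges, default=0),
        overhang_3p_ok=overhang_ok,
        opposite_arms_ok=opposite,
        mir_3p_overhang=mir_oh,
        star_3p_overhang=star_oh,
    )


def infer_star_span(
    structure: str, mir_span: tuple[int, int], overhang: int = OVERHANG
) -> tuple[int, int] | None:
    """Predict the star-arm span from the fold: the positions paired to
    the miRNA core, extended by the 2-nt 3' overhang on the high side."""
    pt = pair_table(structure)
    ms, me = mir_span
    partners = [pt[i] for i in range(ms, me - overhang) if pt[i] is not None]
    if not partners:
        return None
    lo, hi = min(partners), max(partners)
    return lo, min(hi + 1 + overhang, len(structure))


@dataclass
class Verdict:
    """Outcome of the five-criterion screen for one precursor window."""

    passed: bool
    flags: dict
    failed: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        state = "PASS" if self.passed else "FAIL(" + ",".join(self.failed) + ")"
        return state


def classify_candidate(
    duplex: DuplexReport,
    metrics: ThermoMetrics,
    star_observed: bool,
    max_mismatches: int = 4,
    max_mismatch_run: int = 4,
    max_bulges: int = 1,
    max_bulge_size: int = 2,
    min_mfei: float = 0.8,
) -> Verdict:
    """Apply the five screening criteria; MFEI must strictly exceed 0.8."""
    flags = {
        "star_detected": star_observed,
        "duplex_mismatches": duplex.mismatch_count < max_mismatches
        and duplex.max_consecutive_mismatches < max_mismatch_run,
        "asymmetric_bulges": duplex.asymmetric_bulge_count <= max_bulges
        and duplex.max_asymmetric_bulge_size <= max_bulge_size,
        "arms_and_overhang": duplex.overhang_3p_ok and duplex.opposite_arms_ok,
        "mfei": metrics.mfei > min_mfei,
    }
    failed = tuple(c for c in CRITERIA if not flags[c])
    return Verdict(passed=not failed, flags=flags, failed=failed)


# ---------------------------------------------------------------------------
# window extraction and screening
# ---------------------------------------------------------------------------


@dataclass
class PrecursorCandidate:
    """A precursor window around a genome-anchored candidate read."""

    chrom: str
    window_start: int  # genome coords, 0-based half-open
    window_end: int
    strand: str
    sequence: str  # window sequence, 5'->3' on the read's strand
    flank: int
    mir_span: tuple  # 0-based half-open on `sequence`
    structure: str | None = None
    mfe: float | None = None
    star_span: tuple | None = None
    star_observed: bool = False
    duplex: DuplexReport | None = None
    metrics: ThermoMetrics | None = None
    verdict: Verdict | None = None

    @property
    def precursor_length(self) -> int:
        return len(self.sequence)

    @property
    def mir_arm(self) -> str:
        """'5p' if the candidate sits on the 5' side of its star, else '3p'."""
        if self.star_span is None or self.mir_span[0] < self.star_span[0]:
            return "5p"
        return "3p"


def extract_precursor_windows(
    genome, locus, flank_steps: Sequence[int] = FLANK_LADDER
) -> list[PrecursorCandidate]:
    """One window candidate per flank size, truncated at contig ends.

    ``genome`` maps chrom -> sequence (any str-indexable mapping works,
    including ``pyfaidx.Fasta``).  On the minus strand the window is
    reverse-complemented so the candidate always reads 5'->3'.
    """
    contig = str(genome[locus.chrom][:])
    out = []
    for flank in flank_steps:
        ws = max(0, locus.start - flank)
        we = min(len(contig), locus.end + flank)
        if ws >= locus.start and we <= locus.end:
            continue  # zero extractable flank on both sides
        seq = contig[ws:we]
        if locus.strand == "-":
            seq = revcomp(seq)
            mir_span = (we - locus.end, we - locus.start)
        else:
            mir_span = (locus.start - ws, locus.end - ws)
        out.append(
            PrecursorCandidate(
                chrom=locus.chrom,
                window_start=ws,
                window_end=we,
                strand=locus.strand,
                sequence=seq,
                flank=flank,
                mir_span=mir_span,
            )
        )
    return out


def _overlaps(a: tuple, b: tuple) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _window_position(cand: PrecursorCandidate, gstart: int, gend: int) -> tuple | None:
    """Map a genome interval into window coordinates (read-strand orientation)."""
    if gstart < cand.window_start or gend > cand.window_end:
        return None
    if cand.strand == "-":
        return (cand.window_end - gend, cand.window_end - gstart)
    return (gstart - cand.window_start, gend - cand.window_start)


def screen_candidate(
    genome,
    locus,
    star_finder: Callable | None = None,
    flank_steps: Sequence[int] = FLANK_LADDER,
    fold_fn: Callable = fold,
    overhang: int = OVERHANG,
    star_tolerance: int = 2,
    **thresholds,
) -> PrecursorCandidate | None:
    """Screen one genome-anchored candidate through the window ladder.

    ``star_finder(chrom, strand, span_lo, span_hi)`` returns observed
    read loci (genome-coordinate (start, end) tuples) available as
    potential star sequences within the window.  The smallest window
    whose structure passes all criteria is retained; when none passes,
    the window with the fewest failed criteria (smallest first) is
    returned, carrying its verdict, so rejections can report which
    criterion failed.  Returns None when no window is extractable.
    """
    best: PrecursorCandidate | None = None
    for cand in extract_precursor_windows(genome, locus, flank_steps):
        structure, mfe = fold_fn(cand.sequence)
        cand.structure, cand.mfe = structure, mfe
        inferred = infer_star_span(structure, cand.mir_span, overhang)
        if inferred is not None and _overlaps(inferred, cand.mir_span):
            inferred = None  # self-pairing candidate: no interpretable star arm
        star_span, star_observed = inferred, False
        if inferred is not None and star_finder is not None:
            for g_lo, g_hi in star_finder(cand.chrom, cand.strand,
                                          cand.window_start, cand.window_end):
                pos = _window_position(cand, g_lo, g_hi)
                if pos is None or _overlaps(pos, cand.mir_span):
                    continue
                if (abs(pos[0] - inferred[0]) <= star_tolerance
                        and abs(pos[1] - inferred[1]) <= star_tolerance):
                    star_span, star_observed = pos, True
                    break
        cand.star_span = star_span
        cand.star_observed = star_observed
        cand.metrics = compute_metrics(mfe, sequence=cand.sequence)
        if star_span is not None:
            cand.duplex = evaluate_duplex(structure, cand.mir_span, star_span, overhang)
        else:
            cand.duplex = DuplexReport(
                mismatch_count=cand.mir_span[1] - cand.mir_span[0] - overhang,
                max_consecutive_mismatches=cand.mir_span[1] - cand.mir_span[0] - overhang,
                asymmetric_bulge_count=0,
                max_asymmetric_bulge_size=0,
                overhang_3p_ok=False,
                opposite_arms_ok=False,
            )
        cand.verdict = classify_candidate(
            cand.duplex, cand.metrics, star_observed, **thresholds
        )
        if cand.verdict.passed:
            return cand
        if best is None or len(cand.verdict.failed) < len(best.verdict.failed):
            best = cand
    return best
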