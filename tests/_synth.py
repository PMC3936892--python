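"""Random miRNA/miRNA* duplex structures with constructed ground truth.

Used by the duplex-evaluator oracle tests: structures are written
directly as dot-bracket strings from a random list of duplex events
(paired column, 1x1 mismatch, one-sided bulge), so the expected
mismatch/bulge/overhang statistics are known by construction and do
not depend on any folding or pairing code under test.
"""

from dataclasses import dataclass


@dataclass
class DuplexCase:
    structure: str
    mir_span: tuple
    star_span: tuple
    mismatch_count: int
    max_run: int
    bulge_count: int
    max_bulge: int
    overhang_ok: bool
    opposite_ok: bool


def random_duplex_case(rng, mir_is_left=True) -> DuplexCase:
    n_cols = int(rng.integers(14, 22))
    blunt = rng.random() < 0.12
    events = []
    last_special = True  # force the first column to be a pair
    for i in range(n_cols):
        # anchor the duplex ends with pairs (three on blunt duplexes, whose
        # evaluation core truncates into the final columns)
        if i >= n_cols - (3 if blunt else 1) or (blunt and i < 3):
            events.append(("pair",))
            continue
        if last_special:
            events.append(("pair",))
            last_special = False
            continue
        roll = rng.random()
        if roll < 0.60:
            events.append(("pair",))
        elif roll < 0.80:
            events.append(("mm",))
            last_special = True
        elif roll < 0.90:
            events.append(("bulge_left", int(rng.integers(1, 4))))
            last_special = True
        else:
            events.append(("bulge_right", int(rng.integers(1, 4))))
            last_special = True

    o_left = int(rng.integers(2, 4))  # left arm's 3' overhang pokes the loop
    o_right = int(rng.integers(2, 4))
    if blunt:
        o_left = o_right = 0

    left, right_rev = [], []
    for ev in events:
        kind = ev[0]
        if kind == "pair":
            left.append("(")
            right_rev.append(")")
        elif kind == "mm":
            left.append(".")
            right_rev.append(".")
        elif kind == "bulge_left":
            left.append("." * ev[1])
        else:
            right_rev.append("." * ev[1])
    left_arm = "".join(left) + "." * o_left
    right_arm = "".join(reversed(right_rev)) + "." * o_right

    fl = int(rng.integers(0, 8))
    loop = int(rng.integers(4, 10))
    fr = int(rng.integers(0, 8))
    structure = "." * fl + left_arm + "." * loop + right_arm + "." * fr
    left_span = (fl, fl + len(left_arm))
    right_span = (fl + len(left_arm) + loop, fl + len(left_arm) + loop + len(right_arm))

    # constructed truth, from the event list and the structure text alone
    mir_span, star_span = (left_span, right_span) if mir_is_left else (right_span, left_span)
    core = structure[mir_span[0] : mir_span[1] - 2]
    mismatches = core.count(".")
    max_run = _longest_dot_run(core)
    bulges = [ev[1] for ev in events if ev[0].startswith("bulge")]
    return DuplexCase(
        structure=structure,
        mir_span=mir_span,
        star_span=star_span,
        mismatch_count=mismatches,
        max_run=max_run,
        bulge_count=len(bulges),
        max_bulge=max(bulges, default=0),
        overhang_ok=(o_left == 2 and o_right == 2),
        opposite_ok=(o_left <= 2),
    )


def _longest_dot_run(text: str) -> int:
    best = run = 0
    for c in text:
        if c == ".":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best
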