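"""Secondary-structure backend for precursor screening.

The screening pipeline only needs a pseudoknot-free structure and a
folding energy for each candidate precursor window.  Two backends are
provided:

* :func:`fold` -- a weighted maximum base-pairing dynamic program
  (Watson-Crick plus G:U, minimum hairpin loop of 3 unpaired bases)
  with a simple energy proxy: -2.0 kcal/mol per G:C pair and
  -1.0 kcal/mol per A:U or G:U pair.  This is an explicit proxy model,
  not a nearest-neighbor thermodynamic calculation; it exists so the
  whole pipeline runs self-contained and deterministically.
* :func:`read_vienna` / :func:`write_vienna` -- pass-through of
  externally produced dot-bracket files (e.g. from a thermodynamic
  folder), including the ``(dG = ...)`` energy comment convention.

Tracebacks are deterministic: at each subproblem the closing pair is
preferred, then leaving the 5' base unpaired, then the 3' base, then
the leftmost bifurcation.  Preferring the closing pair first recovers
contiguous stems whenever they are co-optimal.
"""

from __future__ import annotations

import re

import numpy as np

from .seqs import normalize

#: proxy energy magnitude per pair type (kcal/mol)
PAIR_ENERGY = {
    ("G", "C"): 2,
    ("C", "G"): 2,
    ("A", "T"): 1,
    ("T", "A"): 1,
    ("G", "T"): 1,
    ("T", "G"): 1,
}

MIN_HAIRPIN_LOOP = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# 5x5 integer weight lookup, 0 = cannot pair
_W5 = np.zeros((5, 5), dtype=np.int32)
for (a, b), w in PAIR_ENERGY.items():
    _W5[_BASE_INDEX[a], _BASE_INDEX[b]] = w


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"cannot fold sequence with non-ACGU(T)N base {exc}") from None


def fold(sequence: str, min_loop: int = MIN_HAIRPIN_LOOP) -> tuple[str, float]:
    """Fold a sequence, returning ``(dot_bracket, mfe_kcal_per_mol)``.

    The structure maximizes the total pair weight (G:C twice the weight
    of A:U/G:U) over all pseudoknot-free pairings with at least
    ``min_loop`` unpaired bases in every hairpin loop; the reported
    energy is minus that weight.  N is treated as unpairable.
    """
    seq = normalize(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    enc = _encode(seq)
    W = _W5[enc[:, None], enc[None, :]]

    N = np.zeros((n + 1, n + 1), dtype=np.int32)  # padded so N[i+1, j-1] is safe
    M = N[:n, :n]  # view on the real table
    for span in range(min_loop + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.maximum(M[i + 1, j], M[i, j - 1])
        w = W[i, j]
        paired = M[i + 1, j - 1] + w
        best = np.maximum(best, np.where(w > 0, paired, -1))
        # bifurcation into two non-trivial substructures
        for t in range(len(i)):
            ii, jj = int(i[t]), int(j[t])
            lo = ii + min_loop + 1
            hi = jj - min_loop - 1
            if lo <= hi:
                b = int(np.max(M[ii, lo:hi + 1] + M[lo + 1:hi + 2, jj]))
                if b > best[t]:
                    best[t] = b
        M[i, j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i, j] == 0:
            continue
        target = M[i, j]
        if W[i, j] > 0 and j - i > min_loop and M[i + 1, j - 1] + W[i, j] == target:
            structure[i] = "("
            structure[j] = ")"
            stack.append((i + 1, j - 1))
        elif M[i + 1, j] == target:
            stack.append((i + 1, j))
        elif M[i, j - 1] == target:
            stack.append((i, j - 1))
        else:
            for k in range(i + min_loop + 1, j - min_loop):
                if M[i, k] + M[k + 1, j] == target:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
            else:  # pragma: no cover - the DP guarantees a split exists
                raise AssertionError("traceback failed")
    return "".join(structure), -float(M[0, n - 1])


def structure_energy(seq: str, structure: str) -> float:
    """Proxy energy of a given structure (sum of pair weights, negated)."""
    pt = pair_table(structure)
    seq = normalize(seq)
    total = 0
    for i, j in enumerate(pt):
        if j is not None and i < j:
            total += PAIR_ENERGY.get((seq[i], seq[j]), 0)
    return -float(total)


def pair_table(structure: str) -> list:
    """Partner index for every position of a dot-bracket string (None if unpaired)."""
    pt: list = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


_ENERGY_RE = re.compile(r"\((?:dG|\s*)\s*=?\s*(-?\d+(?:\.\d+)?)\s*(?:kcal/mol)?\s*\)\s*$")


def read_vienna(path) -> list[tuple[str, str, str, float | None]]:
    """Parse a Vienna-style file: ``>name``, sequence, structure + energy.

    Returns a list of (name, sequence, structure, energy) tuples; the
    energy is taken from a trailing ``(dG = -12.3)`` style comment and
    None when absent.
    """
    entries = []
    name, seq, struct, energy = None, "", None, None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, seq, struct, energy))
                name, seq, struct, energy = line[1:].split()[0], "", None, None
            elif set(line.split()[0]) <= set(".()"):
                m = _ENERGY_RE.search(line)
                if m:
                    energy = float(m.group(1))
                    struct = line[: m.start()].strip()
                else:
                    struct = line
            else:
                seq += line
        if name is not None:
            entries.append((name, seq, struct, energy))
    for name, seq, struct, energy in entries:
        if struct is not None and len(struct) != len(seq):
            raise ValueError(f"{name}: structure/sequence length mismatch")
    return entries


def write_vienna(path, entries) -> None:
    """Write (name, sequence, structure, energy) tuples as a Vienna file."""
    with open(path, "w") as fh:
        for name, seq, struct, energy in entries:
            fh.write(f">{name}\n{seq}\n")
            if energy is None:
                fh.write(f"{struct}\n")
            else:
                fh.write(f"{struct} (dG = {energy:.2f})\n")
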