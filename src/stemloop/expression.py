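"""Cross-library expression profiling of miRNAs.

Counts from the two flower-bud libraries (A: male-sterile line, B:
male-fertile line) are normalized to reads per million mappable reads
(RPM); a miRNA is called differentially expressed when the ratio of
the larger to the smaller normalized abundance strictly exceeds
two-fold.  qRT-PCR relative expression follows the 2^-ddCt convention
against a reference gene and calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class CountRecord:
    """Per-miRNA raw and normalized abundance in libraries A and B."""

    mir_name: str
    reads_A: int
    reads_B: int
    lib_size_A: int
    lib_size_B: int
    rpm_A: float = 0.0
    rpm_B: float = 0.0


@dataclass
class DEResult:
    mir_name: str
    fold_change: float  # larger normalized value over smaller, >= 1
    direction: str  # up_in_A | up_in_B | unchanged
    is_de: bool
    rpm_A: float = 0.0
    rpm_B: float = 0.0


@dataclass
class QPCRRecord:
    target_ct: float
    reference_ct: float
    delta_delta_ct: float
    relative_expression: float


def normalize_rpm(
    counts: Mapping[str, tuple[int, int]], lib_size_A: int, lib_size_B: int
) -> list[CountRecord]:
    """Reads-per-million normalization against each library's mappable total."""
    if lib_size_A <= 0 or lib_size_B <= 0:
        raise ValueError("library sizes must be positive")
    out = []
    for name, (a, b) in counts.items():
        out.append(
            CountRecord(
                mir_name=name,
                reads_A=a,
                reads_B=b,
                lib_size_A=lib_size_A,
                lib_size_B=lib_size_B,
                rpm_A=a / lib_size_A * 1e6,
                rpm_B=b / lib_size_B * 1e6,
            )
        )
    return out


def fold_change(
    record: CountRecord, pseudo_rpm: float = 0.01, threshold: float = 2.0
) -> DEResult:
    """Two-fold rule on normalized abundances.

    ``pseudo_rpm`` is added only when one side is zero, keeping the
    ratio finite without perturbing nonzero comparisons; a miRNA absent
    from both libraries is 'unchanged' at fold 1.
    """
    a, b = record.rpm_A, record.rpm_B
    if a == 0 and b == 0:
        return DEResult(record.mir_name, 1.0, "unchanged", False, a, b)
    if min(a, b) == 0:
        a, b = a + pseudo_rpm, b + pseudo_rpm
    fold = max(a, b) / min(a, b)
    if fold <= threshold:
        direction = "unchanged"
    elif record.rpm_B > record.rpm_A:
        direction = "up_in_B"
    else:
        direction = "up_in_A"
    return DEResult(
        record.mir_name, fold, direction, fold > threshold, record.rpm_A, record.rpm_B
    )


def de_table(results: Iterable[DEResult]) -> pd.DataFrame:
    rows = [
        (r.mir_name, round(r.rpm_A, 2), round(r.rpm_B, 2),
         round(r.fold_change, 2), r.direction, r.is_de)
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["miR_name", "rpm_A", "rpm_B", "fold_change", "direction", "is_de"]
    )


def ddct(
    target_ct_test: float,
    ref_ct_test: float,
    target_ct_calibrator: float,
    ref_ct_calibrator: float,
) -> QPCRRecord:
    """Relative qRT-PCR expression by the 2^-ddCt method.

    ddCt = (target - reference)_test - (target - reference)_calibrator;
    relative expression = 2^-ddCt (1.0 for the calibrator vs itself).
    """
    ddct_value = (target_ct_test - ref_ct_test) - (
        target_ct_calibrator - ref_ct_calibrator
    )
    return QPCRRecord(
        target_ct=target_ct_test,
        reference_ct=ref_ct_test,
        delta_delta_ct=ddct_value,
        relative_expression=2.0 ** (-ddct_value),
    )
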