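"""Bundled reference annotation: the published novel-miRNA table for the
Brassica campestris flower-bud study system.

Each precursor appears twice (its -5p and -3p arms) with the mature
length (LM), precursor length (LP), GC percentage, folding energy (dG,
kcal/mol), MFEI and raw read counts in the male-sterile (FbA) and
male-fertile (FbB) flower-bud libraries.  Useful as a realistic
fixture and for checking the MFEI arithmetic against published values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CACHE: pd.DataFrame | None = None


def novel_mirna_table() -> pd.DataFrame:
    """The bundled reference table, one row per mature arm."""
    global _CACHE
    if _CACHE is None:
        with resources.files(__package__).joinpath(
            "data/novel_mirna_reference.tsv"
        ).open() as fh:
            _CACHE = pd.read_csv(fh, sep="\t")
    return _CACHE.copy()


def precursor_table() -> pd.DataFrame:
    """One row per precursor (collapsing the two arms)."""
    df = novel_mirna_table()
    df["precursor"] = df["miR_name"].str.replace(r"-[35]p$", "", regex=True)
    return df.groupby("precursor", sort=False)[["LP", "CG", "dG", "MFEI"]].first().reset_index()
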