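"""Small bundled datasets.

``six_tg_colonies.tsv`` tallies the 6-thioguanine resistance pilot used to
confirm that the barcoded gene-trap transposon is mutagenic: a test library
was selected in 6-TG (which kills mismatch-repair-proficient cells), 80
surviving colonies were isolated and their integrations mapped, and the
mapped clones are tallied per disrupted gene.  Clones disrupting one of the
four canonical mismatch-repair genes (Msh2, Msh6, Mlh1, Pms2) are the
expected true positives.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

MISMATCH_REPAIR_GENES = ("Msh6", "Msh2", "Mlh1", "Pms2")


def six_tg_resistant_colonies() -> pd.DataFrame:
    """Colony tally of the 6-TG resistance pilot (gene, colonies, sites)."""
    with files("bartrap.data").joinpath("six_tg_colonies.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def mmr_clone_count(table: pd.DataFrame | None = None) -> int:
    """Number of 6-TG-resistant clones disrupting a canonical mismatch
    repair gene — the pilot's headline mutagenesis check."""
    table = table if table is not None else six_tg_resistant_colonies()
    mmr = table[table["gene"].isin(MISMATCH_REPAIR_GENES)]
    return int(mmr["colonies"].sum())
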