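"""Bundled machine-readable reference tables.

Two artifacts ship with the package: the published 8-species x 21-position
cCA key for the CITES-listed sharks (positions numbered from the COI
start codon, position 60 flagged low-confidence) and the published
identification results for 72 market samples (41 processed fins from
Hong Kong, 31 sequenced fin-soup ceratotrichia from the USA). Both are
data of record, stored as printed, never regenerated.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .key import CCAKey, read_key

#: Common names the published results table uses for the CITES-listed species.
CITES_COMMON_NAMES: frozenset[str] = frozenset({
    "Whale", "Basking", "White", "Oceanic whitetip", "Porbeagle",
    "Scalloped hammerhead", "Smooth hammerhead", "Great hammerhead",
})


def _data_path(name: str):
    return resources.files("finid").joinpath("data", name)


def load_table3_key() -> CCAKey:
    """The bundled CITES-shark cCA key (8 species, 21 COI positions 57-174)."""
    with resources.as_file(_data_path("table3_key.tsv")) as tsv, \
            resources.as_file(_data_path("table3_meta.json")) as meta:
        return read_key(tsv, meta)


def load_table2_fixture() -> pd.DataFrame:
    """The bundled market-sample identification results (72 rows).

    Columns: num, type (P = processed fin, S = soup), loc, bold,
    blast_top_hit, coverage, identity (printed integer percent), unq, id
    (the best identification from the two searches).
    """
    with resources.as_file(_data_path("table2_results.tsv")) as tsv:
        return pd.read_csv(tsv, sep="\t", dtype={"num": int, "coverage": int,
                                                 "identity": int})
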