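"""Reference-library quality screening.

Public barcode repositories contain mislabelled records: a sequence
deposited as one species whose closest matches are another species
entirely (e.g. a "white shark" entry nearly identical to blue shark but
only ~83% identical to every other white shark). Each record is compared
against all others; a record is *suspect* when some other species
matches it at or above ``foreign_threshold`` percent identity while its
best conspecific (if any) falls at or below ``conspecific_threshold``.
A record that is its species' only representative and draws no strong
foreign hit is *unresolvable* — nothing to check it against.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .identify import identity_search
from .seq import ReferenceLibrary, TaxonLabel


@dataclass(frozen=True)
class QCFlag:
    reference_id: str
    declared_label: TaxonLabel
    best_foreign: tuple[str, float] | None   # (species, identity)
    best_conspecific: float | None
    verdict: str                             # ok | suspect | unresolvable


def find_duplicates(library: ReferenceLibrary) -> list[tuple[str, ...]]:
    """Groups of same-species records with byte-identical bases."""
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in library.records:
        groups.setdefault((rec.label.binomial, rec.bases), []).append(rec.id)
    return [tuple(ids) for ids in groups.values() if len(ids) > 1]


def screen_references(library: ReferenceLibrary,
                      foreign_threshold: float = 98.0,
                      conspecific_threshold: float = 90.0,
                      min_overlap: int = 80) -> list[QCFlag]:
    """Flag probable misidentifications in a labelled reference library.

    Output is sorted suspects first, then by reference id.
    """
    if len(library.species()) < 2:
        raise InputError("reference screening needs >= 2 species in the library")
    flags: list[QCFlag] = []
    for rec in library.records:
        hits = identity_search(rec, library, min_overlap=min_overlap,
                               query_offset=library.coordinate_offset,
                               exclude_ids=frozenset({rec.id}))
        own = rec.label.binomial
        best_con: float | None = None
        best_for: tuple[str, float] | None = None
        for h in hits:
            if h.label.binomial == own:
                if best_con is None or h.identity > best_con:
                    best_con = h.identity
            elif best_for is None or h.identity > best_for[1]:
                best_for = (h.label.binomial, h.identity)
        strong_foreign = best_for is not None and best_for[1] >= foreign_threshold
        if strong_foreign and (best_con is None or best_con <= conspecific_threshold):
            verdict = "suspect"
        elif best_con is None and not strong_foreign:
            verdict = "unresolvable"
        else:
            verdict = "ok"
        flags.append(QCFlag(reference_id=rec.id, declared_label=rec.label,
                            best_foreign=best_for, best_conspecific=best_con,
                            verdict=verdict))
    flags.sort(key=lambda f: (f.verdict != "suspect", f.reference_id))
    return flags
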