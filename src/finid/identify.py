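"""Two-track identification of mini-barcode queries.

Track one is a local reference-library identity search standing in for
the BOLD/BLAST web searches: the query is compared column-wise against
every COI-registered reference, either at a known registration or by
sliding over every ungapped placement, and scored as percent compatible
columns. Track two checks the query against the cCA key: a species is a
candidate when the query is compatible with that species' diagnostic
states at every covered key position. The two tracks are combined by an
explicit decision cascade; disagreement between them is reported as a
discordance flag, never silently resolved.

Cascade (first rule that fires wins):

1. **species** — top identity is 100.0, unique to one species, and (for
   keyed species) the cCA candidate set is exactly that species;
2. **candidate_set** — the cCA candidates form a multi-species set whose
   members sit closer than ``min_diagnostic_separation`` key positions
   from one another (the oceanic-whitetip situation: the short fragment
   cannot responsibly separate them);
3. **genus** — all maximal-identity hits share one genus and the top
   identity clears ``min_genus_identity``;
4. **unidentified**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, NoInformationError
from .iupac import encode
from .key import CCAKey, key_row_distance
from .seq import NucSequence, ReferenceLibrary, TaxonLabel


@dataclass(frozen=True)
class SearchHit:
    """One reference's best ungapped placement against the query."""

    reference_id: str
    label: TaxonLabel
    identity: float          # percent compatible columns, one decimal
    coverage: float          # percent of the query length compared
    rank: int
    coi_start: int           # COI position of the query's first base at best placement
    compared: int            # number of columns compared


@dataclass(frozen=True)
class FinalCall:
    level: str               # species | genus | candidate_set | unidentified
    taxa: tuple[str, ...]


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    top_hits: tuple[SearchHit, ...]
    unique_top: bool
    search_call: str         # lowest unambiguous taxon from the search track
    cca_candidates: frozenset[str]
    cca_incompatibilities: dict[str, int]
    final_call: FinalCall
    discordance_flag: bool


@dataclass(frozen=True)
class IdentifyConfig:
    min_overlap: int = 80
    min_diagnostic_separation: int = 2
    min_genus_identity: float = 98.0
    use_low_confidence: bool = False


def _library_matrix(library: ReferenceLibrary) -> np.ndarray:
    return np.stack([encode(r.bases) for r in library.records])


def identity_search(query: NucSequence, library: ReferenceLibrary,
                    min_overlap: int = 80,
                    query_offset: int | None = None,
                    exclude_ids: frozenset[str] = frozenset()) -> list[SearchHit]:
    """Rank every reference by percent-compatible-columns against the query.

    With ``query_offset`` (the COI position of the query's first base)
    the comparison is a single column-wise pass on the overlapping COI
    interval; without it every ungapped placement with >= ``min_overlap``
    overlapping columns is tried and the placement maximising the number
    of compatible columns (ties: higher identity, then leftmost) wins.
    Identity is reported to one decimal; coverage is the percent of the
    query length included in the comparison. Hits are sorted by identity
    descending, coverage descending, then reference id.
    """
    if not library.records:
        raise InputError("empty reference library")
    lq = len(query)
    if lq < min_overlap:
        raise InputError(
            f"query {query.id!r} length {lq} below min_overlap {min_overlap}")
    keep = [i for i, r in enumerate(library.records) if r.id not in exclude_ids]
    if not keep:
        raise InputError("all references excluded")
    mat = _library_matrix(library)[keep]
    q = encode(query.bases)
    ll = library.alignment_length
    n = mat.shape[0]

    if query_offset is not None:
        offsets = [query_offset - library.coordinate_offset]
    else:
        offsets = range(-(lq - min_overlap), ll - min_overlap + 1)

    best_comp = np.full(n, -1, dtype=np.int64)
    best_cmp = np.full(n, 1, dtype=np.int64)   # compared columns at best placement
    best_off = np.zeros(n, dtype=np.int64)
    for off in offsets:
        a, b = max(0, off), min(ll, off + lq)
        if b - a < min_overlap:
            continue
        qa = a - off
        comp = ((mat[:, a:b] & q[qa:b - off]) != 0).sum(axis=1)
        compared = b - a
        better = (comp > best_comp) | (
            (comp == best_comp) & (comp * best_cmp > best_comp * compared))
        best_comp = np.where(better, comp, best_comp)
        best_cmp = np.where(better, compared, best_cmp)
        best_off = np.where(better, off, best_off)
    if (best_comp < 0).all():
        return []

    hits = []
    for j in range(n):
        if best_comp[j] < 0:
            continue
        rec = library.records[keep[j]]
        identity = round(100.0 * int(best_comp[j]) / int(best_cmp[j]), 1)
        coverage = round(100.0 * int(best_cmp[j]) / lq, 1)
        hits.append((rec, identity, coverage,
                     int(best_off[j]) + library.coordinate_offset,
                     int(best_cmp[j])))
    hits.sort(key=lambda h: (-h[1], -h[2], h[0].id))
    return [SearchHit(reference_id=rec.id, label=rec.label, identity=ident,
                      coverage=cov, rank=i + 1, coi_start=start, compared=cmp_)
            for i, (rec, ident, cov, start, cmp_) in enumerate(hits)]


def cca_match(query: NucSequence, key: CCAKey, coi_start: int = 1,
              use_low_confidence: bool = False
              ) -> tuple[frozenset[str], dict[str, int]]:
    """Candidate species under the cCA key, plus per-species incompatibility counts.

    ``coi_start`` registers the query (COI position of its first base).
    Positions outside the query's coverage are skipped, as are
    low-confidence positions unless enabled. A species is a candidate
    when it accrues zero incompatibilities.
    """
    lq = len(query)
    active = [(i, p) for i, p in enumerate(key.positions)
              if (use_low_confidence or p not in key.low_confidence_positions)
              and 0 <= p - coi_start < lq]
    if not active:
        raise NoInformationError(
            f"query {query.id!r} covers no usable key positions")
    counts: dict[str, int] = {}
    for sp, states in key.rows.items():
        mism = 0
        for i, p in active:
            qmask = int(encode(query.bases[p - coi_start])[0])
            smask = int(encode(states[i])[0])
            if not qmask & smask:
                mism += 1
        counts[sp] = mism
    candidates = frozenset(sp for sp, c in counts.items() if c == 0)
    return candidates, counts


def identify(query: NucSequence, library: ReferenceLibrary, key: CCAKey,
             config: IdentifyConfig = IdentifyConfig()) -> IdentificationResult:
    """Run both tracks on one query and combine them into a final call."""
    hits = identity_search(query, library, min_overlap=config.min_overlap)
    if not hits:
        return IdentificationResult(
            query_id=query.id, top_hits=(), unique_top=False, search_call="",
            cca_candidates=frozenset(), cca_incompatibilities={},
            final_call=FinalCall("unidentified", ()), discordance_flag=False)
    top_identity = hits[0].identity
    top_hits = tuple(h for h in hits if h.identity == top_identity)
    top_species = {h.label.binomial for h in top_hits}
    top_genera = {h.label.genus for h in top_hits}
    unique_top = len(top_species) == 1

    if unique_top:
        search_call = next(iter(top_species))
    elif len(top_genera) == 1:
        search_call = next(iter(top_genera))
    else:
        search_call = ""

    try:
        candidates, counts = cca_match(query, key, coi_start=top_hits[0].coi_start,
                                       use_low_confidence=config.use_low_confidence)
        cca_informative = True
    except NoInformationError:
        candidates, counts = frozenset(), {}
        cca_informative = False

    # a conflict is the search species being *excluded* by the cCA; the cCA
    # merely failing to narrow to one species is ambiguity, not discordance
    discordance = (unique_top and search_call in key.rows and cca_informative
                   and search_call not in candidates)

    # 1. species
    if (top_identity == 100.0 and unique_top
            and (search_call not in key.rows
                 or candidates == frozenset({search_call}))):
        final = FinalCall("species", (search_call,))
    # 2. candidate set of mutually-near keyed species
    elif (cca_informative and len(candidates) >= 2
          and all(key_row_distance(key, a, b) < config.min_diagnostic_separation
                  for a in candidates for b in candidates if a < b)):
        final = FinalCall("candidate_set", tuple(sorted(candidates)))
    # 3. genus fallback
    elif len(top_genera) == 1 and top_identity >= config.min_genus_identity:
        final = FinalCall("genus", (next(iter(top_genera)),))
    else:
        final = FinalCall("unidentified", ())

    return IdentificationResult(
        query_id=query.id, top_hits=top_hits, unique_top=unique_top,
        search_call=search_call, cca_candidates=candidates,
        cca_incompatibilities=counts, final_call=final,
        discordance_flag=discordance)


def results_to_table(results: list[IdentificationResult],
                     sample_types: dict[str, str] | None = None) -> pd.DataFrame:
    """Flatten identification results into the report table (one row per query)."""
    rows = []
    for r in results:
        top = r.top_hits[0] if r.top_hits else None
        rows.append({
            "query_id": r.query_id,
            "type": (sample_types or {}).get(r.query_id, ""),
            "top_hit": top.label.binomial if top else "",
            "coverage": top.coverage if top else float("nan"),
            "identity": top.identity if top else float("nan"),
            "unique": "Yes" if r.unique_top else "No",
            "cca_candidates": ";".join(sorted(r.cca_candidates)),
            "call_level": r.final_call.level,
            "call_taxa": ";".join(r.final_call.taxa),
            "discordant": "yes" if r.discordance_flag else "no",
        })
    return pd.DataFrame(rows)


def tabulate(table: pd.DataFrame, taxon_col: str = "call_taxa",
             type_col: str = "type") -> pd.DataFrame:
    """Count final-call taxa per sample type.

    Returns a deterministic table with columns ``taxon``, ``sample_type``
    and ``count``, rows sorted by taxon then sample type; empty input
    yields an empty table.
    """
    cols = ["taxon", "sample_type", "count"]
    if table.empty:
        return pd.DataFrame(columns=cols)
    table = table.fillna({taxon_col: "", type_col: ""})
    counts = (table.groupby([taxon_col, type_col]).size()
              .reset_index(name="count")
              .rename(columns={taxon_col: "taxon", type_col: "sample_type"}))
    return counts.sort_values(["taxon", "sample_type"],
                              kind="mergesort").reset_index(drop=True)[cols]
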