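"""Identity search, cCA matching, the decision cascade, and tabulation."""

import numpy as np
import pandas as pd
import pytest

from finid.errors import InputError, NoInformationError
from finid.identify import (IdentifyConfig, cca_match, identify,
                            identity_search, results_to_table, tabulate)
from finid.key import CCAKey
from finid.seq import NucSequence, ReferenceLibrary, TaxonLabel

# --- independent oracle -----------------------------------------------------

_SETS = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
         "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
         "H": "ACT", "V": "ACG", "N": "ACGT", "-": ""}


def oracle_best_placement(query, ref, min_overlap):
    """Naive per-column sliding comparison; returns (identity, coverage)."""
    best = None  # (compatible, compared, offset)
    for off in range(-(len(query) - min_overlap), len(ref) - min_overlap + 1):
        a, b = max(0, off), min(len(ref), off + len(query))
        if b - a < min_overlap:
            continue
        comp = sum(1 for i in range(a, b)
                   if set(_SETS[ref[i]]) & set(_SETS[query[i - off]]))
        cand = (comp, b - a, off)
        if best is None or comp > best[0] or (
                comp == best[0] and comp * best[1] > best[0] * (b - a)):
            best = cand
    if best is None:
        return None
    comp, compared, _ = best
    return (round(100.0 * comp / compared, 1),
            round(100.0 * compared / len(query), 1))


def _lib(seqs, offset=1):
    recs = [NucSequence(f"r{i}", s, TaxonLabel(g, sp))
            for i, (s, g, sp) in enumerate(seqs)]
    return ReferenceLibrary(recs, coordinate_offset=offset)


def test_self_match_is_100_100():
    rng = np.random.default_rng(0)
    s = "".join(rng.choice(list("ACGT"), 120))
    lib = _lib([(s, "Prionace", "glauca")])
    hit = identity_search(NucSequence("q", s), lib)[0]
    assert (hit.identity, hit.coverage) == (100.0, 100.0)


def test_single_mismatch_in_118_columns_rounds_to_99_2():
    rng = np.random.default_rng(1)
    s = "".join(rng.choice(list("ACGT"), 118))
    q = list(s)
    q[50] = {"A": "C"}.get(q[50], "A")
    lib = _lib([(s, "Prionace", "glauca")])
    hit = identity_search(NucSequence("q", "".join(q)), lib)[0]
    assert hit.identity == 99.2  # 117/118


def test_sliding_search_matches_bruteforce_oracle_exactly():
    rng = np.random.default_rng(2)
    refs = []
    genera = ["Carcharhinus", "Sphyrna", "Lamna"]
    for i in range(20):
        s = "".join(rng.choice(list("ACGTN"), size=200,
                               p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        refs.append((s, genera[i % 3], f"sp{i}"))
    lib = _lib(refs)
    for trial in range(5):
        src = refs[rng.integers(0, len(refs))][0]
        start = int(rng.integers(0, 80))
        q = list(src[start:start + 120])
        for i in rng.integers(0, 120, size=3):
            q[i] = "ACGT"[rng.integers(0, 4)]
        query = NucSequence("q", "".join(q))
        hits = identity_search(query, lib, min_overlap=80)
        assert len(hits) == len(refs)
        for h in hits:
            ref = lib.records[int(h.reference_id[1:])].bases
            assert (h.identity, h.coverage) == oracle_best_placement(
                query.bases, ref, 80)


def test_hits_sorted_by_identity_coverage_then_id(cites_library):
    q = cites_library.records[0]
    hits = identity_search(q, cites_library)
    keys = [(-h.identity, -h.coverage, h.reference_id) for h in hits]
    assert keys == sorted(keys)
    assert [h.rank for h in hits] == list(range(1, len(hits) + 1))


def test_empty_library_and_short_query_are_input_errors(cites_library):
    with pytest.raises(InputError):
        identity_search(NucSequence("q", "ACGT" * 10), cites_library,
                        min_overlap=80)


# --- cCA matching -----------------------------------------------------------

def _query_from_row(key, species, fill="A"):
    """A query spanning the key's positional range, equal to one row's states."""
    lo, hi = min(key.positions), max(key.positions)
    bases = [fill] * (hi - lo + 1)
    for p, state in zip(key.positions, key.rows[species]):
        s = _SETS[state]
        bases[p - lo] = s[0]  # concrete member of the state
    return NucSequence(f"q|{species}", "".join(bases)), lo


def test_query_equal_to_a_row_is_its_sole_candidate(table3_key):
    for species in table3_key.rows:
        q, lo = _query_from_row(table3_key, species)
        cands, counts = cca_match(q, table3_key, coi_start=lo)
        assert cands == {species}
        assert counts[species] == 0


def test_incompatibility_counting_at_position_57(table3_key):
    q, lo = _query_from_row(table3_key, "Lamna nasus")
    cands, counts = cca_match(q, table3_key, coi_start=lo)
    # L. nasus has T at 57 where the hammerheads have C: each accrues >= 1
    assert counts["Sphyrna lewini"] >= 1
    assert "Sphyrna lewini" not in cands


def test_all_n_query_is_compatible_with_every_row(table3_key):
    lo, hi = min(table3_key.positions), max(table3_key.positions)
    q = NucSequence("q", "N" * (hi - lo + 1))
    cands, counts = cca_match(q, table3_key, coi_start=lo)
    assert cands == set(table3_key.rows)
    assert set(counts.values()) == {0}


def test_query_covering_no_key_positions_is_an_error(table3_key):
    with pytest.raises(NoInformationError):
        cca_match(NucSequence("q", "ACGT"), table3_key, coi_start=300)


def test_masking_low_confidence_position_is_sound(table3_key):
    """Perturbing position 60 never changes candidates while it is masked."""
    for species in list(table3_key.rows)[:3]:
        q, lo = _query_from_row(table3_key, species)
        cands0, _ = cca_match(q, table3_key, coi_start=lo)
        for b in "ACGT":
            bases = list(q.bases)
            bases[60 - lo] = b
            pq = NucSequence(q.id, "".join(bases))
            cands, _ = cca_match(pq, table3_key, coi_start=lo)
            assert cands == cands0


# --- decision cascade -------------------------------------------------------

def test_species_call_for_clean_reference_queries(cites_library, table3_key):
    rec = cites_library.records_for("Sphyrna lewini")[0]
    res = identify(rec, cites_library, table3_key)
    assert res.final_call.level == "species"
    assert res.final_call.taxa == ("Sphyrna lewini",)
    assert res.unique_top and not res.discordance_flag


def test_leave_one_in_contains_the_truth(cites_library, table3_key):
    for rec in cites_library.records:
        res = identify(rec, cites_library, table3_key)
        truth = rec.label.binomial
        assert truth in res.final_call.taxa or res.final_call.taxa == (
            rec.label.genus,), (rec.id, res.final_call)


def _whitetip_world():
    """Four requiem species distinguishable only at low-confidence position 60."""
    rng = np.random.default_rng(12)
    backbone = "".join(rng.choice(list("ACGT"), 200))
    species = ["longimanus", "obscurus", "galapagensis", "perezi"]
    states = {"longimanus": "A", "obscurus": "C", "galapagensis": "G",
              "perezi": "T"}
    recs = []
    for sp in species:
        b = list(backbone)
        b[59] = states[sp]
        for i in range(2):
            recs.append(NucSequence(f"{sp}{i}", "".join(b),
                                    TaxonLabel("Carcharhinus", sp)))
    lib = ReferenceLibrary(recs, coordinate_offset=1)
    key = CCAKey(positions=(60, 100, 150),
                 rows={f"Carcharhinus {sp}": states[sp] + backbone[99]
                       + backbone[149] for sp in species},
                 low_confidence_positions=frozenset({60}))
    return lib, key


def test_mutually_close_cca_candidates_yield_a_candidate_set_call():
    lib, key = _whitetip_world()
    query = lib.records_for("Carcharhinus longimanus")[0]
    res = identify(query, lib, key)
    assert res.final_call.level == "candidate_set"
    assert res.final_call.taxa == tuple(sorted(key.rows))
    assert not res.discordance_flag  # ambiguity, not conflict


def test_candidate_set_members_are_never_separated_by_cca_alone():
    lib, key = _whitetip_world()
    for rec in lib.records:
        res = identify(rec, lib, key)
        assert res.final_call.level == "candidate_set"
        assert rec.label.binomial in res.final_call.taxa


def test_multi_species_tie_in_one_genus_is_a_genus_call():
    rng = np.random.default_rng(13)
    s = "".join(rng.choice(list("ACGT"), 150))
    lib = _lib([(s, "Carcharhinus", "falciformis"),
                (s, "Carcharhinus", "sorrah")])
    key = CCAKey(positions=(10,), rows={"Sphyrna lewini":
                                        "G" if s[9] != "G" else "C"})
    res = identify(NucSequence("q", s), lib, key)
    assert not res.unique_top
    assert res.final_call.level == "genus"
    assert res.final_call.taxa == ("Carcharhinus",)


def test_mixed_genus_tie_below_species_is_unidentified():
    rng = np.random.default_rng(14)
    s = "".join(rng.choice(list("ACGT"), 150))
    lib = _lib([(s, "Carcharhinus", "falciformis"),
                (s, "Prionace", "glauca")])
    key = CCAKey(positions=(10,), rows={"Sphyrna lewini":
                                        "G" if s[9] != "G" else "C"})
    res = identify(NucSequence("q", s), lib, key)
    assert res.final_call.level == "unidentified"


def test_discordance_is_flagged_when_cca_excludes_the_search_species(
        cites_library, table3_key):
    rec = cites_library.records_for("Sphyrna lewini")[0]
    # corrupt the query at enough key positions to exclude S. lewini
    bases = list(rec.bases)
    for p in (85, 126, 132):   # positions where the S. lewini states are concrete
        col = p - cites_library.coordinate_offset
        bases[col] = "G" if bases[col] != "G" else "A"
    q = NucSequence("q", "".join(bases))
    res = identify(q, cites_library, table3_key)
    assert "Sphyrna lewini" not in res.cca_candidates
    if res.unique_top and res.search_call == "Sphyrna lewini":
        assert res.discordance_flag
        assert res.final_call.level != "species"


def test_identification_report_is_deterministic(cites_library, table3_key):
    queries = cites_library.records[:6]
    t1 = results_to_table([identify(q, cites_library, table3_key)
                           for q in queries]).to_csv(sep="\t", index=False)
    t2 = results_to_table([identify(q, cites_library, table3_key)
                           for q in queries]).to_csv(sep="\t", index=False)
    assert t1 == t2


# --- tabulation -------------------------------------------------------------

def test_tabulate_reproduces_published_counts(table2):
    counts = tabulate(table2, taxon_col="id", type_col="type")
    def n(taxon, typ):
        row = counts[(counts.taxon == taxon) & (counts.sample_type == typ)]
        return int(row["count"].iloc[0]) if len(row) else 0
    assert n("School", "P") == 5
    assert n("Blue", "P") == 2
    assert int(counts[counts.sample_type == "S"]["count"].sum()) == 31
    assert int(counts[counts.sample_type == "P"]["count"].sum()) == 41
    cites = counts[counts.taxon.isin({"Scalloped hammerhead",
                                      "Smooth hammerhead"})]
    assert int(cites[cites.sample_type == "S"]["count"].sum()) == 3


def test_tabulate_empty_input_is_an_empty_table():
    out = tabulate(pd.DataFrame(columns=["call_taxa", "type"]))
    assert list(out.columns) == ["taxon", "sample_type", "count"]
    assert out.empty
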