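"""Per-species IUPAC consensus and compound character attribute (cCA) keys.

A cCA key is a character-based species diagnosis: a shared set of COI
positions at which each species' joint nucleotide states distinguish it
from its designated close relatives. States are IUPAC codes so that
within-species polymorphism (a ``K`` or ``Y`` cell) is represented
rather than erased; diagnosis and row distance are defined by IUPAC
*incompatibility* (empty intersection of base sets), never by mere
character inequality — ``R`` against ``G`` is not a diagnostic
difference.

The consensus rule is union-IUPAC: every base observed above a frequency
threshold (default: any observation) at a column contributes to the
emitted code. Position selection is greedy set cover over candidate
positions, deterministic with a leftmost tie-break; minimality of the
result is not claimed.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (InputError, InseparableTaxaError, KeyDegeneracyError,
                     KeyLookupError)
from .iupac import compatible, iupac_code, iupac_set
from .seq import NucSequence, TaxonLabel


@dataclass(frozen=True)
class SpeciesConsensus:
    """One species' union-IUPAC consensus over its aligned records."""

    label: TaxonLabel
    bases: NucSequence
    n_sequences: int
    coordinate_offset: int = 1

    def state_at(self, coi_position: int) -> str:
        i = coi_position - self.coordinate_offset
        if not 0 <= i < len(self.bases.bases):
            raise InputError(
                f"COI position {coi_position} outside consensus range")
        return self.bases.bases[i]


@dataclass
class CCAKey:
    """Diagnostic states for a set of species at a shared list of COI positions.

    ``rows`` maps binomial -> state string (one IUPAC character per
    position); ``relatives`` records, per target species, the relatives
    the key was constructed against; ``low_confidence_positions`` flags
    positions in the poorly resolved early part of the read that the
    matcher excludes by default.
    """

    positions: tuple[int, ...]
    rows: dict[str, str]
    relatives: dict[str, list[str]] = field(default_factory=dict)
    low_confidence_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        self.positions = tuple(self.positions)
        self.low_confidence_positions = frozenset(self.low_confidence_positions)
        for sp, states in self.rows.items():
            if len(states) != len(self.positions):
                raise InputError(
                    f"row {sp!r} has {len(states)} states for "
                    f"{len(self.positions)} positions")
        if not self.low_confidence_positions <= set(self.positions):
            raise InputError("low-confidence positions must be key positions")

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def states(self, binomial: str) -> str:
        try:
            return self.rows[binomial]
        except KeyError:
            raise KeyLookupError(f"species {binomial!r} not in key") from None

    def validate_unique(self) -> None:
        """Every pair of rows must be incompatible at >= 1 position."""
        names = list(self.rows)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if key_row_distance(self, a, b) == 0:
                    raise KeyDegeneracyError(
                        f"rows {a!r} and {b!r} are compatible at every position")


def key_row_distance(key: CCAKey, species_a: str, species_b: str) -> int:
    """Number of key positions where the two rows are IUPAC-incompatible."""
    ra, rb = key.states(species_a), key.states(species_b)
    return sum(1 for x, y in zip(ra, rb) if not compatible(x, y))


def build_consensus(records: Sequence[NucSequence], min_frequency: float = 0.0,
                    label: TaxonLabel | None = None,
                    coordinate_offset: int = 1) -> SpeciesConsensus:
    """Union-IUPAC consensus of equal-length records from one species.

    Per column, each record's (possibly ambiguous) code is expanded to
    its base set; bases observed in more than ``min_frequency`` of the
    non-gap records are unioned and the minimal IUPAC code covering the
    union is emitted. An all-gap column emits ``-``. A single record is
    its own consensus.
    """
    if not records:
        raise InputError("cannot build a consensus from zero records")
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise InputError(f"records have unequal lengths {sorted(lengths)}")
    if label is None:
        label = records[0].label
    cols = []
    for i in range(lengths.pop()):
        counts: Counter[str] = Counter()
        n_informative = 0
        for rec in records:
            expansion = iupac_set(rec.bases[i])
            if expansion:
                n_informative += 1
                counts.update(expansion)
        if n_informative == 0:
            cols.append("-")
            continue
        kept = {b for b, c in counts.items() if c / n_informative > min_frequency}
        if not kept:  # threshold excluded everything; fall back to the mode
            top = max(counts.values())
            kept = {b for b, c in counts.items() if c == top}
        cols.append(iupac_code(frozenset(kept)))
    seq = NucSequence(f"consensus|{label.binomial if label else 'unlabelled'}",
                      "".join(cols), label)
    return SpeciesConsensus(label=label, bases=seq, n_sequences=len(records),
                            coordinate_offset=coordinate_offset)


def diagnostic_positions(target: SpeciesConsensus,
                         relatives: Sequence[SpeciesConsensus],
                         candidate_region: tuple[int, int]) -> list[int]:
    """Greedy minimal set of COI positions separating target from every relative.

    A position separates a relative when the target and relative states
    there are IUPAC-incompatible. Greedy set cover: each step picks the
    position resolving the most not-yet-separated relatives, ties broken
    by smaller COI position. Raises :class:`InseparableTaxaError` naming
    the first relative that no candidate position can separate.
    """
    if any(r.label.binomial == target.label.binomial for r in relatives):
        raise InputError("target must not appear among its relatives")
    lo = target.coordinate_offset
    hi = lo + len(target.bases.bases) - 1
    start, end = max(candidate_region[0], lo), min(candidate_region[1], hi)
    candidates = list(range(start, end + 1))
    separates: dict[int, set[int]] = {}
    for pos in candidates:
        t = target.state_at(pos)
        covered = {i for i, rel in enumerate(relatives)
                   if not compatible(t, rel.state_at(pos))}
        if covered:
            separates[pos] = covered
    for i, rel in enumerate(relatives):
        if not any(i in cov for cov in separates.values()):
            raise InseparableTaxaError(target.label.binomial, rel.label.binomial)
    uncovered = set(range(len(relatives)))
    chosen: list[int] = []
    while uncovered:
        best = max(sorted(separates),
                   key=lambda p: (len(separates[p] & uncovered), -p))
        gain = separates[best] & uncovered
        if not gain:  # unreachable given the pre-check, defensive
            raise InseparableTaxaError(target.label.binomial, "<unknown>")
        chosen.append(best)
        uncovered -= gain
        del separates[best]
    return sorted(chosen)


def build_cca_key(consensuses: Mapping[str, SpeciesConsensus],
                  targets: Sequence[str],
                  relatives_map: Mapping[str, Sequence[str]],
                  candidate_region: tuple[int, int],
                  positions: Sequence[int] | None = None,
                  low_confidence_positions: Iterable[int] = ()) -> CCAKey:
    """Construct a shared-position cCA key for a set of target species.

    The shared position list is the union of each target's greedy
    diagnostic set (or an explicit ``positions`` list); rows record
    every listed species' consensus state at each shared position. Key
    uniqueness is verified before return.
    """
    for t in targets:
        if t not in consensuses:
            raise InputError(f"no consensus for target {t!r}")
        for r in relatives_map.get(t, ()):
            if r not in consensuses:
                raise InputError(f"no consensus for relative {r!r} of {t!r}")
    if positions is None:
        pos_union: set[int] = set()
        for t in targets:
            rels = [consensuses[r] for r in relatives_map.get(t, ())]
            if rels:
                pos_union |= set(diagnostic_positions(consensuses[t], rels,
                                                      candidate_region))
        shared = tuple(sorted(pos_union))
    else:
        shared = tuple(positions)
    if not shared:
        raise InputError("no diagnostic positions found")
    row_species = list(dict.fromkeys([*targets, *(
        r for t in targets for r in relatives_map.get(t, ()))]))
    rows = {sp: "".join(consensuses[sp].state_at(p) for p in shared)
            for sp in row_species}
    key = CCAKey(positions=shared, rows=rows,
                 relatives={t: list(relatives_map.get(t, ())) for t in targets},
                 low_confidence_positions=frozenset(low_confidence_positions) & set(shared))
    key.validate_unique()
    return key


def write_key(key: CCAKey, tsv_path: str | Path,
              meta_path: str | Path | None = None) -> None:
    """Write the key TSV (``species<TAB>p57<TAB>...``) and optional meta JSON."""
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species"] + [f"p{p}" for p in key.positions])
        for sp, states in key.rows.items():
            w.writerow([sp] + list(states))
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump({"relatives": key.relatives,
                       "low_confidence_positions":
                           sorted(key.low_confidence_positions)},
                      fh, indent=2)
            fh.write("\n")


def read_key(tsv_path: str | Path,
             meta_path: str | Path | None = None) -> CCAKey:
    """Read a key TSV plus optional sidecar JSON (relatives, low-confidence flags)."""
    with open(tsv_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or header[0] != "species":
            raise InputError(f"key file {tsv_path} must start with a 'species' column")
        try:
            positions = tuple(int(h[1:]) for h in header[1:])
        except ValueError:
            raise InputError(f"malformed position columns in {tsv_path}") from None
        rows: dict[str, str] = {}
        for row in reader:
            if not row:
                continue
            rows[row[0]] = "".join(row[1:])
    relatives: dict[str, list[str]] = {}
    low_conf: frozenset[int] = frozenset()
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        relatives = {k: list(v) for k, v in meta.get("relatives", {}).items()}
        low_conf = frozenset(meta.get("low_confidence_positions", []))
    return CCAKey(positions=positions, rows=rows, relatives=relatives,
                  low_confidence_positions=low_conf)
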