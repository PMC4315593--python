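"""Synthetic reference libraries and degraded query panels.

The generator honours a cCA key rather than a real phylogeny: every
species draws a backbone from a shared ancestor by i.i.d. per-site
substitution, records carry bases compatible with their species' key
state at every key position (all members of an ambiguous state such as
``K`` are represented once record count permits, so a union-IUPAC
consensus round-trips the key exactly), and within-species variation is
injected only at non-key positions. A primer scaffold — the forward
annealing footprint upstream of the readable region and the reverse
footprint downstream of it — is embedded so in-silico PCR succeeds on
every template.

Degraded queries model processed-fin and fin-soup reads: a random
subinterval in the mini-barcode length regime with bases blanked to
``N`` at a configurable rate. Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import FISHF2_T1, SHARK_COI_MINIR, READABLE_REGION
from .errors import ConfigError
from .iupac import iupac_set, reverse_complement
from .key import CCAKey
from .seq import NucSequence, ReferenceLibrary, TaxonLabel

_BASES = np.array(list("ACGT"))

# COI intervals where the primer annealing footprints are embedded when
# primer_scaffold is on: forward (non-tail portion of FishF2_t1) ends just
# upstream of the readable region, reverse just downstream of it.
FWD_SCAFFOLD_START = 30
REV_SCAFFOLD_START = 180


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``species_panel`` is a list of ``(binomial, n_records)``. Rates are
    per-site probabilities; ``key_position_noise`` is the probability a
    record deviates (incompatibly) from its key state at a key position.
    """

    key: CCAKey
    species_panel: list[tuple[str, int]]
    sequence_length: int = 655
    coordinate_offset: int = 1
    within_species_mutation_rate: float = 0.005
    between_species_background_divergence: float = 0.05
    key_position_noise: float = 0.0
    primer_scaffold: bool = True
    truncation_model: tuple[int, int] = (110, 130)
    ambiguity_injection_rate: float = 0.02
    seed: int = 0
    allow_unkeyed: bool = False

    def __post_init__(self):
        for p in (self.within_species_mutation_rate,
                  self.between_species_background_divergence,
                  self.key_position_noise, self.ambiguity_injection_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0,1]")
        if any(n < 1 for _, n in self.species_panel):
            raise ConfigError("per-species record counts must be >= 1")
        if self.truncation_model[0] > self.truncation_model[1]:
            raise ConfigError("truncation min_length > max_length")
        if not self.allow_unkeyed:
            missing = [sp for sp, _ in self.species_panel
                       if sp not in self.key.rows]
            if missing:
                raise ConfigError(
                    f"species {missing} absent from the key and no backbone "
                    f"rule (set allow_unkeyed to generate them freely)")


def _coi_to_col(pos: int, offset: int) -> int:
    return pos - offset


def simulate_library(config: SimConfig) -> ReferenceLibrary:
    """Generate a labelled, COI-registered library honouring the key."""
    rng = np.random.default_rng(config.seed)
    L, off = config.sequence_length, config.coordinate_offset
    lo, hi = off, off + L - 1
    key_cols = {p: i for i, p in enumerate(config.key.positions)
                if lo <= p <= hi}
    ancestor = rng.integers(0, 4, size=L)
    records: list[NucSequence] = []
    for binomial, n in config.species_panel:
        genus, species = binomial.split(" ", 1)
        label = TaxonLabel(genus, species)
        # species backbone: ancestor + background divergence
        backbone = ancestor.copy()
        mut = rng.random(L) < config.between_species_background_divergence
        backbone[mut] = (backbone[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
        states = config.key.rows.get(binomial)
        # per key position, plan record assignments so every member of an
        # ambiguous state appears at least once when n allows it
        plans: dict[int, list[str]] = {}
        if states is not None:
            for pos, ki in key_cols.items():
                members = sorted(iupac_set(states[ki]))
                plan = [members[i % len(members)] for i in range(n)]
                rng.shuffle(plan)
                plans[pos] = plan
        for r in range(n):
            seq = backbone.copy()
            mut = rng.random(L) < config.within_species_mutation_rate
            for pos in key_cols:
                mut[_coi_to_col(pos, off)] = False
            seq[mut] = (seq[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            chars = list(_BASES[seq])
            for pos, plan in plans.items():
                col = _coi_to_col(pos, off)
                if config.key_position_noise and rng.random() < config.key_position_noise:
                    allowed = iupac_set(config.key.rows[binomial][key_cols[pos]])
                    others = sorted(set("ACGT") - allowed)
                    chars[col] = others[rng.integers(0, len(others))] if others else plan[r]
                else:
                    chars[col] = plan[r]
            if config.primer_scaffold:
                _embed_scaffold(chars, off, L)
            rid = f"sim|{binomial.replace(' ', '_')}|{r + 1:02d}"
            records.append(NucSequence(rid, "".join(chars), label))
    return ReferenceLibrary(records, coordinate_offset=off)


def _embed_scaffold(chars: list[str], offset: int, length: int) -> None:
    fwd = FISHF2_T1[1][FISHF2_T1[2]:]               # non-tail annealing bases
    rev = reverse_complement(SHARK_COI_MINIR[1])    # plus-strand footprint
    for start, probe in ((FWD_SCAFFOLD_START, fwd), (REV_SCAFFOLD_START, rev)):
        a = start - offset
        if a < 0 or a + len(probe) > length:
            raise ConfigError(
                "primer scaffold does not fit the configured sequence window")
        chars[a:a + len(probe)] = list(probe)


def simulate_degraded_queries(library: ReferenceLibrary, config: SimConfig
                              ) -> tuple[list[NucSequence], pd.DataFrame]:
    """One degraded read per library record, plus the truth table.

    Each query is a random subinterval within the truncation bounds; when
    the primer scaffold is on the subinterval is constrained to overlap
    the readable region. Bases are blanked to ``N`` independently at
    ``ambiguity_injection_rate``. The truth table maps query_id to the
    source species and records the query's true COI start.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo_len, hi_len = config.truncation_model
    L = library.alignment_length
    off = library.coordinate_offset
    if lo_len < 30 or hi_len > L:
        raise ConfigError(f"truncation bounds ({lo_len},{hi_len}) outside [30,{L}]")
    queries: list[NucSequence] = []
    truth_rows = []
    for rec in library.records:
        qlen = int(rng.integers(lo_len, hi_len + 1))
        smin, smax = 0, L - qlen
        if config.primer_scaffold:
            # force overlap with the readable mini-barcode region
            rstart, rend = READABLE_REGION
            smin = max(smin, _coi_to_col(rstart, off) - qlen + 1)
            smax = min(smax, _coi_to_col(rend, off))
            if smin > smax:
                raise ConfigError("readable region cannot be overlapped at "
                                  f"query length {qlen}")
        s = int(rng.integers(smin, smax + 1))
        bases = list(rec.bases[s:s + qlen])
        blank = rng.random(qlen) < config.ambiguity_injection_rate
        for i in np.flatnonzero(blank):
            bases[i] = "N"
        qid = f"q|{rec.id}"
        queries.append(NucSequence(qid, "".join(bases), None))
        truth_rows.append({"query_id": qid, "source_id": rec.id,
                           "species": rec.label.binomial,
                           "coi_start": s + off, "length": qlen})
    return queries, pd.DataFrame(truth_rows)


def planted_pair_key(name_a: str, name_b: str, n_diff: int,
                     n_positions: int = 12,
                     region: tuple[int, int] = READABLE_REGION) -> CCAKey:
    """A two-species key whose rows differ at exactly ``n_diff`` positions.

    Used to plant known separation structure (the at-least-2-positions
    rule, and the single-position oceanic-whitetip situation) in
    synthetic panels.
    """
    if not 1 <= n_diff <= n_positions:
        raise ConfigError("n_diff must be within [1, n_positions]")
    lo, hi = region
    if n_positions > hi - lo + 1:
        raise ConfigError("region too small for the requested position count")
    step = (hi - lo) // (n_positions - 1)
    positions = tuple(lo + i * step for i in range(n_positions))
    row_a = "A" * n_positions
    row_b = "C" * n_diff + "A" * (n_positions - n_diff)
    return CCAKey(positions=positions, rows={name_a: row_a, name_b: row_b},
                  relatives={name_a: [name_b], name_b: [name_a]})
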