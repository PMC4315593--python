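"""In-silico PCR with the mini-barcode primer cocktail.

The assay multiplexes two M13-tailed universal fish barcoding forward
primers (FishF2_t1, VF2_t1) with a shark-specific reverse primer
(Shark COI-MINIR) that anneals ~150 bp into the COI barcode region, so
that degraded templates still yield a short sequencable amplicon. Here
the primers are matched against a template with IUPAC-aware degenerate
comparison: a position matches when the primer and template base sets
intersect, a site qualifies when at most ``max_mismatches`` positions
disagree and none of the primer's 3'-terminal ``three_prime_clamp``
positions do. The M13 tail never binds template on the first cycles and
is excluded from the comparison.

All intervals are 1-based inclusive. ``coordinate_offset`` registers the
template to COI coordinates (offset 1 = template starts at the COI start
codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, TrimError
from .iupac import compatible, reverse_complement
from .seq import NucSequence

M13_TAIL = "TGTAAAACGACGGCCAGT"

FISHF2_T1 = ("FishF2_t1", M13_TAIL + "CGACTAATCATAAAGATATCGGCAC", len(M13_TAIL))
VF2_T1 = ("VF2_t1", M13_TAIL + "CAACCAACCACAAAGACATTGGCAC", len(M13_TAIL))
SHARK_COI_MINIR = ("Shark_COI-MINIR", "AAGATTACAAAAGCGTGGGC")

#: Default readable region of the mini-barcode in COI coordinates.
READABLE_REGION = (57, 174)


@dataclass(frozen=True)
class PrimerSet:
    """The assay's primers plus matching tolerances.

    ``forward_primers`` entries are ``(name, bases, tail_length)``; the
    leading ``tail_length`` bases (the M13 tail) are metadata excluded
    from annealing comparison. Printed primer sequences are stored with
    typesetting whitespace stripped.
    """

    forward_primers: tuple[tuple[str, str, int], ...] = (FISHF2_T1, VF2_T1)
    reverse_primer: tuple[str, str] = SHARK_COI_MINIR
    max_mismatches: int = 2
    three_prime_clamp: int = 3
    insert_bounds: tuple[int, int] = (30, 1000)

    def __post_init__(self):
        for name, bases, tail in self.forward_primers:
            if tail >= len(bases):
                raise InputError(f"primer {name!r}: tail length {tail} >= primer length")


@dataclass(frozen=True)
class AmpliconHit:
    """One (forward site, reverse site) pairing on a template.

    ``fwd_site``/``rev_site`` are the annealing footprints (non-tail
    portion only) and ``insert`` the sequencable portion between them,
    all in the template's registered coordinates.
    """

    template_id: str
    forward_primer_name: str
    fwd_site: tuple[int, int]
    rev_site: tuple[int, int]
    amplicon: NucSequence
    insert: NucSequence
    insert_interval: tuple[int, int]
    mismatches: int

    @property
    def amplicon_length(self) -> int:
        return self.rev_site[1] - self.fwd_site[0] + 1


def find_annealing_sites(template: NucSequence, primer: str, orientation: str,
                         max_mismatches: int = 2, three_prime_clamp: int = 3,
                         coordinate_offset: int = 1) -> list[tuple[tuple[int, int], int]]:
    """Scan one strand for degenerate primer annealing sites.

    Reverse orientation scans the reverse complement; footprints are
    always reported as intervals in template coordinates. Sites come
    back sorted by (mismatch count, position).
    """
    if not template.bases:
        raise InputError("empty template")
    m, n = len(primer), len(template.bases)
    if m > n:
        raise InputError(f"primer (length {m}) longer than template (length {n})")
    probe = primer if orientation == "forward" else reverse_complement(primer)
    if orientation not in ("forward", "reverse"):
        raise InputError(f"orientation must be forward|reverse, got {orientation!r}")
    # indices of the probe corresponding to the primer's 3'-terminal clamp:
    # forward primers end at the right edge of the footprint, reverse primers
    # (after reverse complementing) at the left edge.
    if orientation == "forward":
        clamp_idx = range(m - three_prime_clamp, m)
    else:
        clamp_idx = range(0, three_prime_clamp)
    clamp = set(i for i in clamp_idx if 0 <= i < m)
    sites: list[tuple[tuple[int, int], int]] = []
    for off in range(n - m + 1):
        window = template.bases[off:off + m]
        mism = 0
        ok = True
        for i in range(m):
            if not compatible(probe[i], window[i]):
                if i in clamp:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            start = off + coordinate_offset
            sites.append(((start, start + m - 1), mism))
    sites.sort(key=lambda s: (s[1], s[0][0]))
    return sites


def insilico_pcr(template: NucSequence, primers: PrimerSet | None = None,
                 coordinate_offset: int = 1) -> list[AmpliconHit]:
    """All qualifying forward/reverse primer pairings on a template.

    Tailed forward primers anneal with their non-tail portion only. Hits
    are sorted by total mismatches, ties broken by leftmost forward site;
    an empty list means no pair was found.
    """
    primers = primers or PrimerSet()
    rev_name, rev_bases = primers.reverse_primer
    rev_sites = find_annealing_sites(
        template, rev_bases, "reverse",
        primers.max_mismatches, primers.three_prime_clamp, coordinate_offset)
    hits: list[AmpliconHit] = []
    lo, hi = primers.insert_bounds
    for name, bases, tail in primers.forward_primers:
        anneal = bases[tail:]
        fwd_sites = find_annealing_sites(
            template, anneal, "forward",
            primers.max_mismatches, primers.three_prime_clamp, coordinate_offset)
        for (fstart, fend), fmism in fwd_sites:
            for (rstart, rend), rmism in rev_sites:
                if fend >= rstart:
                    continue
                insert_len = rstart - fend - 1
                if not lo <= insert_len <= hi:
                    continue
                a = fstart - coordinate_offset
                b = rend - coordinate_offset
                amp = NucSequence(template.id, template.bases[a:b + 1], template.label)
                ins = NucSequence(template.id,
                                  template.bases[fend - coordinate_offset + 1:
                                                 rstart - coordinate_offset],
                                  template.label)
                hits.append(AmpliconHit(
                    template_id=template.id, forward_primer_name=name,
                    fwd_site=(fstart, fend), rev_site=(rstart, rend),
                    amplicon=amp, insert=ins,
                    insert_interval=(fend + 1, rstart - 1),
                    mismatches=fmism + rmism))
    hits.sort(key=lambda h: (h.mismatches, h.fwd_site[0], h.forward_primer_name))
    return hits


def trim_to_readable(hit: AmpliconHit,
                     readable_region: tuple[int, int] = READABLE_REGION) -> NucSequence:
    """Restrict an amplicon insert to the readable mini-barcode region."""
    istart, iend = hit.insert_interval
    rstart, rend = readable_region
    start, end = max(istart, rstart), min(iend, rend)
    if start > end:
        raise TrimError(
            f"insert [{istart},{iend}] does not overlap readable region "
            f"[{rstart},{rend}]")
    a, b = start - istart, end - istart
    return NucSequence(hit.insert.id, hit.insert.bases[a:b + 1], hit.insert.label)
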