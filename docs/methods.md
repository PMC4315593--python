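# Methods

## The identification problem

Standard COI barcoding compares a ~650 bp query against a reference
library and relies on the "barcode gap": within-species identity is
high, between-species identity low. A ~110–130 bp mini-barcode read
from degraded material weakens that gap — several requiem sharks
(*Carcharhinus*) are identical or nearly identical over the fragment —
so identity search is complemented by a *character-based* diagnosis:
the compound character attribute (cCA), a fixed set of COI positions
whose joint states distinguish each target species from its designated
close relatives.

## IUPAC algebra and why incompatibility, not inequality

Every base is a set: `K = {G,T}`, `N = {A,C,G,T}`, the alignment gap
`-` the empty set. Two characters *match* when their sets intersect.
This is load-bearing in three places:

- **primer scanning** — degenerate primer or template positions count
  as matches when the sets intersect;
- **consensus** — a polymorphic column emits the minimal IUPAC code
  covering every observed base, so polymorphism is represented, not
  erased by a majority vote (the bundled key's `K`, `Y` and `R` cells
  exist precisely because of within-species polymorphism);
- **diagnosis and distance** — a key state `R` against a query `G`
  is *not* a diagnostic difference; treating it as one would
  misdiagnose polymorphic individuals. Row distance counts only
  positions with empty intersection. It is deliberately not a metric
  (triangle violations are possible and unasserted).

`-` and `N` are distinct: `N` (unknown base) is compatible with
everything, `-` (alignment gap) with nothing.

## Coordinates

All public interfaces use 1-based, inclusive COI positions numbered
from the start codon; a library stores a single `coordinate_offset`
(the COI position of alignment column 0). Alignment to COI coordinates
is accepted as input — the toolkit performs no multiple alignment.

## In-silico PCR

A site qualifies when at most `max_mismatches` (default 2) positions
are incompatible and none within the primer's 3′-terminal
`three_prime_clamp` bases (default 3) — polymerase extension is
intolerant of 3′ mismatches. The published assay reports only that all
tested species amplified, so these tolerances are configurable
defaults from common primer-scan practice, not published values. The
18-base M13 tail (`TGTAAAACGACGGCCAGT`) of the tailed forward primers
is metadata: it does not bind template on early cycles and is excluded
from comparison. Insert-length bounds (30–1000) discard spurious
pairings of multiplexed primers. Hits are sorted by total mismatches,
ties by leftmost forward site.

The readable region defaults to COI [57, 174] — the span of the
bundled key's positions; the assay's exact amplicon ends are not
published (only "~150 bp" amplicon, "~110–130 bp" readable), so the
region is a configuration value, not a constant.

## Consensus and diagnostic position selection

Union-IUPAC consensus with `min_frequency = 0` (include every observed
base); a single sequence is its own consensus. Diagnostic positions
are chosen by greedy set cover: each step takes the position separating
the most not-yet-separated relatives, ties broken by the smaller COI
position — deterministic, valid by construction (re-verified on
return), but not guaranteed minimal; tests compare it against an
exhaustive solver on small instances. The procedure that produced the
published 21-position key is not described anywhere, and the key may
not be re-derivable without the original sequence panels; the shipped
key is therefore a bundled artifact of record, and `build_cca_key`
accepts an explicit position list to evaluate rows at a given key.
The relatives map is explicit input (the original choice of relatives
came from prior phylogenetic work); no tree is inferred. Position 60
is flagged low-confidence as data in the bundled key's sidecar — it
lies in the poorly resolved early part of the read and is excluded
from matching unless explicitly enabled.

## Identity search

The offline stand-in for BOLD/BLAST: percent compatible columns over
the best ungapped placement of the query against each COI-registered
reference (every placement with ≥ `min_overlap` = 80 overlapping
columns is scored; the placement maximising compatible columns wins,
ties going to higher identity then leftmost). Ungapped sliding is exact
for the degradation model used here (truncation + substitution + N); a
gapped aligner would be needed for indel-rich data. Identity is
rounded to one decimal, matching the published tables' percent
formatting; "100% species-level match" means identity 100.0 on the
compared interval with a unique top species. Each hit carries the COI
position of the query under its best placement; `identify()` uses the
top hit's placement to register the query for cCA matching.

## Decision cascade

1. **species** — top identity 100.0, unique top species, and (for
   keyed species) cCA candidates exactly that species;
2. **candidate_set** — the cCA candidates form a ≥2-species set whose
   members are pairwise closer than `min_diagnostic_separation`
   (default 2, from the observed at-least-2-positions separation of
   all targets except the oceanic whitetip) — the fragment cannot
   responsibly separate them, so all are reported;
3. **genus** — all top hits share one genus and top identity ≥
   `min_genus_identity` (default 98; an identity floor the published
   account implies but does not state — its lowest printed identity
   for a genus call is 99%);
4. **unidentified** — including mixed-genus ties, a conservative
   choice the published results never exercise.

The candidate-set rule is checked before the genus fallback: a
whitetip-like query (unique 100% top hit, cCA unable to separate four
congeners) must surface the full candidate set rather than collapse to
a bare genus call. Discordance — the search species being *excluded*
by the cCA — is flagged and reported, never auto-resolved; cCA
ambiguity (candidates ⊇ the search species) is not discordance, it is
what the candidate-set level expresses.

## Reference screening

A record is *suspect* when some foreign species matches it at ≥
`foreign_threshold` (default 98%) while its best conspecific is at ≤
`conspecific_threshold` (default 90%); thresholds bracket the known
mislabelled-entry narratives (99% foreign vs 83% and 86% conspecific)
with margin — the original screening was by manual inspection, not a
stated rule. A species' only record with no strong foreign hit is
*unresolvable*. Identical conspecific duplicates are reported
separately (`find_duplicates`), never as suspects. Self-comparison is
excluded.

## Synthetic data: what it emulates and what it does not

The generator honours a cCA key, not a phylogeny: per species, a
backbone is drawn from a shared ancestor by i.i.d. per-site
substitution (`between_species_background_divergence`, default 0.05),
records get within-species substitutions (default rate 0.005) at
non-key positions only, and at each key position every member of the
species' state set appears at least once when the record count allows,
so a union-IUPAC consensus round-trips the key exactly. The primer
scaffold embeds the forward annealing footprint at COI 30–54 and the
reverse footprint at 180–199, giving a 170 bp amplicon with a 125 bp
insert covering the readable region — within the published "~150 bp /
~110–130 bp" envelope. Degraded queries are random subintervals
(default 110–130 bp, the observed read-length regime) with bases
blanked to N at `ambiguity_injection_rate` (default 0.02).

Not modelled: transition/transversion bias, rate heterogeneity,
indels, chimeras, sequencing quality scores, real phylogenetic
covariance between relatives. Passing tests therefore demonstrate the
toolkit's self-consistency — key recovery, calibration of the cascade,
screening behaviour — under a substitution-only error model, not
performance on real trade samples.

Screening tests use a deeper-divergence panel
(`between_species_background_divergence = 0.10`): the default 0.05
yields ~90% between-species identity, exactly at the conspecific
threshold, whereas the documented mislabelling cases sit at 83–86% —
the 10% setting reproduces that regime, and the screening guarantee is
stated only for libraries whose between-species divergence exceeds
100 − `conspecific_threshold`.

## Bundled data

`data/table3_key.tsv` + `data/table3_meta.json`: the published
8 × 21 cCA key (positions 57–174), relatives map restricted to the
eight keyed species (the true closest-relative panels include
non-CITES species whose consensuses are not part of the key), and the
position-60 low-confidence flag. `data/table2_results.tsv`: the
published identification results for 72 market samples, stored as
printed (integer percent cells); the known discrepancy between the
41 processed-fin rows and the in-text count of 40 is preserved, and
tabulation checks are restricted to counts where text and table agree.

## Problem sizes

Tests and the acceptance script run panels of 8 species × 10 records
(655 bp), a 40 × 200 oracle library, and 6-record planted-separation
pairs — sizes at which the exhaustive oracles (subset search, naive
sliding comparison) remain exact and the whole suite completes in
seconds.

## Known limitations

- No gapped alignment: queries with indels relative to the library
  will lose identity linearly rather than be realigned.
- Genus calls trust the library's labels; a mislabelled library
  (see `refqc`) can produce confident wrong genus calls.
- The greedy key builder can return non-minimal position sets.
- The bundled key covers only the eight CITES species; queries from
  unrelated taxa report low identities and an empty or vacuous
  candidate set rather than a positive "not shark" call.
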