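# Methods

## Data model

A *larval record* is one chromosomally scored larva: site, date, sex,
Y-bearing status, and a genotype (`st/st`, `st/i`, `i/i`) for each inversion
scored.  Males are Y-bearing by definition; rare X0X0Y triploids are stored
as Y-bearing with an explicit ploidy note and count as carriers when one
constituent is inverted (they carry a male-determining Y, so excluding them
would bias the linkage denominator).  Sex assignment at multi-taxon sites is
chromosomal: a female's taxon is often unknowable (e.g. all-standard
females where several taxa co-occur), so `taxon_assignment` is optional
rather than imputed.

Inversion names are normalised to a canonical `ARM-n[·m]` spelling.  The
published tables mix middle dots, periods, second hyphens and Unicode
hyphens for compound inversions (`IIL-73·74` vs `IIL-73.74` vs `IIS-49-52`);
all are accepted on input and the middle dot is emitted.  Dates are stored
ISO-8601; US month/day/year spellings are normalised on load.

## Sex linkage

The *extent of Y linkage* of an inversion is the carrier fraction among
Y-bearing larvae scored for it.  This definition reproduces the worked
census exactly (113 of 113 Y-bearers carrying IIL-6 → 1.000, with the
triploid in both numerator and denominator).  The complementary view — the
male share among carriers — is reported as a secondary field, since the two
coincide only when females never carry.  Y linkage is a within-taxon
statistic: in pipeline runs each taxon's diagnostic inversion is assessed
over that taxon's own larvae, because at multi-taxon sites other taxa's
males are standard for it by construction and would dilute the estimate
toward the taxon's local frequency.

Classification thresholds are configuration, not biology: an inversion is
called sex-linked when its Y-carrier rate is ≥ 0.95 and its female carrier
rate ≤ 0.05, autosomal when the two rates differ by ≤ 0.10, otherwise
ambiguous.  The defaults bracket the survey's weakest reported linkage
(0.967) while honouring its verbal "exclusively, or very nearly so"
criterion; both knobs are exposed.

An autosomal inversion is *shared* by a taxon iff its heterozygote
proportion is strictly positive — a printed zero means absence, and this
rule reproduces the published incidences (13/15 for IS-1, 11/15 for IL-1)
and the five-taxon set positive for all three common polymorphisms.

## Range geometry

Coordinates are projected with a spherical Albers equal-area conic on the
authalic sphere (R = 6 371 007.181 m), standard parallels 20° N and 60° N,
central meridian 96° W, origin 40° N — a conventional equal-area choice for
North America.  Equal-area matters because areas in km² are read directly
off the projected plane; closed-form forward/inverse formulas round-trip to
well under 1e-6°.  The original survey's GIS projection is unpublished, so
multi-point hull areas are **not** comparable figure for figure; the only
area reproduced exactly is the analytic single-site 5-km disc, π·5² ≈ 78.54
km² (printed as 79).

Ranges: ≥ 3 non-collinear sites → convex hull; 1 site → 5-km disc; 2 sites
or any collinear set → 5-km buffer of the extremal segment (a degenerate
zero-area hull would make contact counting vacuous).  Buffers are polygonal
discs with 256 segments per quadrant (relative area error ~6e-6).  *Contact*
is any intersection, boundary touching included.  County-centroid sites
(~100 km accuracy) participate by default — their error is small against
continental ranges — with a flag to exclude them.  An optional land-mask
polygon can clip ranges; none ships with the package because no canonical
mask provenance exists, and tests run unclipped.

## Sampling saturation

Rarefaction draws seeded subsamples *without replacement* from one
collection (the procedure resamples a real collection, not a
superpopulation) on a default grid of 100, 200, 300, … larvae, 500
replicates.  Diversity is the count of distinct Y types — the set of
diagnostic inversions a Y-bearing larva carries, with the non-inverted
standard sequence counting as one further type — because females are
uninformative for taxon identity at mixed sites.  The replicate mean is
compared against the analytic accumulation expectation
E[S(n)] = Σᵢ (1 − (1 − pᵢ)ⁿ) evaluated at the *realised* type frequencies;
the binomial form slightly underestimates the exact hypergeometric
expectation, so tests allow three replicate standard errors (floored at
0.05 types).  At n equal to the collection size the detected fraction is
exactly 1 and the replicate SD exactly 0.

## Breakpoint sharing

Each inversion carries a proximal and a distal breakpoint on its arm's band
map (the long arm of chromosome II spans sections 55–71).  Sharing is exact
section-label equality by default; an integer tolerance flag absorbs scoring
ambiguity in weakly banded "puffing" regions, where the original scoring
treated look-alike breakpoints as positive without a stated rule.  Share
flags are computed only over distinct inversion pairs — a self-pair would
share trivially — but the survey's denominator convention (n × n × 2, self
included; 1,800 for 30 inversions) is kept for comparability, alongside the
cleaner 4·n(n−1)/2 unordered-pair count.  The percentage 100·46/1800 =
2.5556 is exposed both rounded (2.6) and truncated (2.55), matching the two
printed spellings.  The full 30-inversion breakpoint coordinates are
unpublished, so the 46/1800 count itself cannot be recomputed from in-scope
data; the published 11-inversion distal-distal ± matrix is reproduced from
planted section labels instead.

## Synthetic surveys

The generator encodes the sympatric-origin prediction generatively:
sibling site clouds are Gaussian in the projected plane (default 9 siblings,
25 sites each, 450-km spread, giving hulls of order 10⁶ km² like the
published sibling ranges), and each nested cytotype's 1–8 sites are
rejection-sampled inside a random sibling's hull.  An orphan count (default
1, mirroring the survey's 21-of-22 outcome) places cytotypes far outside all
sibling ranges, so both confirming and violating configurations are
testable.  Larvae are drawn per site from a taxon-frequency vector (half of
sibling sites host nested cytotypes as Dirichlet-weighted minorities), sex
at ratio 0.5, Y linkage λ = 0.99 by default (the survey runs 0.967–1.000),
and autosomal genotypes with heterozygote probability q at the scale of the
published table (IS-1 at 0.457, the largest well-sampled value); homozygote
mass is split by Hardy–Weinberg from the allele frequency implied by q
(split evenly when q > 0.5, where no HW solution exists — only q is ever
asserted).  The accuracy-class mixture follows the survey's 96 GPS / 119
legacy / 92 county-centroid split.

The synthetic breakpoint catalog plants an exact number of share events by
assigning proximal labels from an even pool and distal labels from an odd
pool (no accidental sharing), then giving groups of inversions a common
distal label; group sizes are a greedy triangular-number partition of the
target count.  Its section domain is sized to the catalog (1 … 4n+1), not to
the real 17-section band map, on which 30 inversions could not avoid
collisions.

What the generator does **not** emulate: spatial dispersal or river-corridor
structure, multi-year temporal variation, multivoltine generations, B
chromosomes, or ecological covariates.  Passing recovery tests therefore
show the estimators are correct under the stated sampling model, not that
real collections satisfy it.

## Pipeline and scorecard

`run_pipeline` executes linkage → ranges → saturation → breakpoints and
writes deterministic TSV/GeoJSON/JSON artifacts (reruns are byte-identical
under a fixed seed; stage failures carry the stage name).  Scorecard
verdicts use configurable thresholds — minimum Y linkage 0.95, sharing
majority 0.5, sympatry fraction 0.9 — because the model's criteria are
stated qualitatively; the published tables pass all four at the defaults
(21/22 = 0.955 ≥ 0.9).  The model's fifth criterion, ecological
differentiation among taxa, requires data outside this package's scope and
is always reported as not evaluated.

## Problem sizes

Default test and acceptance runs use desk-scale inputs: the 206- and
708-larva worked collections, synthetic surveys of 3–9 siblings and ≤ 22
cytotypes at 40–1,000 larvae per site, 200–500 rarefaction replicates.
These sizes keep the full suite under a few minutes while leaving every
statistic's sampling error far below its test tolerance.

## Known limitations

* Multi-point range areas depend on the (unpublished) original projection
  and coordinates; only topology (contacts) and the analytic disc area are
  reproduced.
* How linkage values were computed for the two taxa without strict Y
  sex-determination (*S. saxosum*, *S. apricarium*) is unstated in the
  source tables; their printed values are carried as data, not re-derived.
* The distance between the two IIL-6 sites computed from their printed
  coordinates (~123 km haversine) disagrees with the printed 97.37 km; the
  printed value is not used anywhere.
* No assignment rule is invented for females at multi-taxon sites; analyses
  needing taxon identity use assigned records only.
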