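# Methods

## Scope and data model

The package operates downstream of identification: it consumes validated
PSMs (iProphet-dialect pepXML with per-channel reporter intensities, or an
equivalent TSV) and makes quantitation-quality decisions about them. A PSM
is identified by the triple (run basename, scan number, assumed charge) —
charge included because TPP treats charge states of one scan as distinct
spectrum queries — and carries the peptide, protein accessions,
modifications, masses, PeptideProphet F-value, iProphet probability,
optional SpectraST scores, and one reporter-intensity slot per channel.
A reporter intensity that is absent *or exactly zero* is an explicit
missing value: every feature derived from it becomes missing, and filter
conditions on missing features are bypassed rather than triggered. This
bypass rule is load-bearing — treating missing as zero would silently
remove every PSM with an incomplete reporter set.

## Normalization

Reporter channels are scaled so that each channel's median intensity over
all identified spectra is equal. The common reference is the median of the
per-channel medians; any other positive reference yields identical ratios,
this one keeps intensities near their original scale (which matters only
because one filter condition, average reporter intensity < 10 000, is an
absolute cutoff — users who normalize differently should adjust that
threshold together with their scheme).

## Features and ratio distances

Ratios divide each numerator channel by the designated denominator
channel. The intra-protein distance of PSM *j*,

IProtDist_j = sqrt( Σ_i ((R_i^j − AvgRest_i)/Avg_i)² ),

measures how far its ratio vector sits from its protein peers' (AvgRest_i
excludes *j*, Avg_i includes it); the intra-peptide distance repeats the
computation within the same peptide sequence. Conventions adopted where
the definition is silent:

- A PSM alone in its peer set has distance 0.
- Single-hit peptides (one PSM in the protein) are pooled into one
  "pseudo-peptide" peer set per protein so the intra-peptide distance
  remains defined for them; modified/charge variants of a sequence count
  as the same peptide.
- Peer groups are formed within the *primary* (first-listed) protein
  accession, so shared peptides contribute to exactly one group —
  deterministic where any multi-assignment rule would be arbitrary.
- Peers must have complete ratio vectors; PSMs with missing reporters
  neither receive nor influence distances. If some Avg_i is 0 the feature
  is set to missing with a warning rather than raising.
- The PTM count excludes isobaric-label tags (they sit on essentially
  every peptide and would make the feature constant); label deltas are
  recognized by mass (TMT 6/10/16-plex, iTRAQ 4/8-plex, ±0.01 Da) when the
  input format carries no explicit flag.

Distances are invariant to the order of peers and to global intensity
scaling; both invariances are property-tested, and the implementation is
checked against an independent brute-force evaluation of the formula on
1000 random small instances (≤ 8 PSMs, ≤ 9 ratios) to 1e-9 relative.

## The filter

Nine default conditions (charge ≥ 5, precursor mass ≥ 4000 Da, peptide
length ≥ 25, average reporter intensity < 10 000, IPepDist ≥ 0.8,
IProtDist ≥ 0.6, |Δmass| ≥ 2 Da, dot product < 0.4, F-value < 0.4) are
OR-combined: any hit removes the PSM. Comparators follow the printed
inequalities literally, so boundary values are removed by "≥" conditions
and retained by "<" conditions. Features without a published cutoff (PTM
count/ratio and five of the six SpectraST scores) are computed and
exportable but carry no default condition; users can add conditions on any
feature via the TOML config, where a bare number uses the feature's
standard direction and a `{op, threshold}` table sets both. In the DB + SL
workflow the filter sees only DB + SL-exclusive PSMs; common PSMs are the
baseline and pass through regardless of their features.

## Quantitation and accuracy metrics

Protein quantitation uses summed reporter intensity: per protein, channel
intensities are summed over contributing PSMs before ratios are formed.
Only PSMs that are not shared peptides and have complete reporters are
eligible for evaluation or protein sums. PSM and protein accuracy is the
average relative error (ARE) against the theoretical ratio vector. The
coverage-vs-ARE AUC integrates the empirical CDF of ARE over [0, max_are]
(default cap 1.0, configurable); the integral of the step CDF is evaluated
in closed form, (1/N) Σ max(0, max_are − a_i) / max_are, which is exact
and grid-free. Because the cap is a free choice, AUC values are comparable
only within a fixed cap. "Large-error" labelling takes the top quartile of
ARE, exactly ⌈0.25 N⌉ keys, ties at the cutoff broken by (ARE descending,
key ascending) for determinism. Quartile summaries use linear
interpolation (numpy's default, type-7).

## Precursor signal-to-interference

S2I = (intensity of the precursor and its isotopic cluster inside the
isolation window) / (total window intensity), computed on the nearest
preceding MS1 scan, with no interpolation between bracketing scans.
Isotope peaks are matched at precursor m/z + k·1.00335/z for k = 0..4
within 10 ppm; envelope depth, spacing and tolerance are parameters. When
the mzML lacks isolation-window metadata a symmetric ±0.85 Th window is
assumed. The purity filter removes PSMs with S2I strictly below 0.7 and
applies on the library-construction path, not to the filter's own input;
PSMs without an MS1 context are retained with a warning. An empty window
yields S2I = 0.

## Synthetic data

The generator emulates a multi-channel benchmark mixture: protein PSM
counts follow a dispersed (gamma-weighted) allocation — exact when a total
N is requested, negative-binomial otherwise; reporter intensities are
(lognormal base abundance, median 5·10⁴, log-sd 0.8) × (channel factor
from the theoretical ratios) × (multiplicative lognormal noise, CV 10%).
A fraction of PSMs (default 25%) are "bad": their noise CV is multiplied
by 4, and — when coupling is on — they are preferentially given low base
abundance (median 4·10³), long peptides (≥ 25 residues) and high charge
(≥ 5), each with probability 0.4–0.5. Shared peptides (second accession),
missing reporter channels and SpectraST score blocks are added at
configurable rates (5%, 2%, 70% by default). All draws come from one
seeded generator in a fixed order, so identical configurations produce
byte-identical datasets.

What the generator does *not* model: chromatography, co-isolation physics
(S2I fixtures are hand-built peak lists), isotope impurity of labels,
inter-run batch effects, or realistic search-score correlations (SL dot
products and F-values are drawn independently of bad status). Passing the
end-to-end tests therefore demonstrates that the filter removes PSMs whose
*ratio noise and coupled features* match its conditions — the mechanism —
not that the default cutoffs are optimal for any particular instrument or
labeling chemistry.

On this synthetic design the filter behaves as on real benchmark data
directionally: the removed population's median ARE is ~3× the retained
population's, the retained set's coverage AUC rises, and removal is
strongly enriched for truly-bad PSMs (verified by a one-sided binomial
test at α = 0.01); with coupling off and the noise multiplier at 1 the
removal is statistically independent of the bad label, showing the
enrichment is earned, not an artifact.

## Problem sizes and numerical choices

The test suite and the acceptance script use N = 4000 PSMs over 500
proteins for the end-to-end study, 10⁵ samples for the uniform-ARE AUC
check, and 1000 random instances for the distance-formula oracle — sizes
at which every quantity of interest is stable to well inside the asserted
tolerances while the whole suite runs in seconds. Floating-point values
round-trip text formats via `repr`, so TSV round-trips are exact; pepXML
round-trips are exact except modification deltas, which are reconstructed
from total residue masses (agreement to 1e-9 relative is asserted).

## Known limitations

- pepXML writing preserves analysis-summary elements verbatim after
  deleting spectrum queries, so any upstream PSM counts recorded there
  become stale; downstream TPP tools recount and do not care.
- Only the rank-1 search hit per spectrum query is read.
- Protein-level quantitation implements summed intensity only; median- or
  weighted-ratio protein rollups are out of scope, as is any FDR
  estimation (probabilities are consumed, not modelled).
- The mzML reader handles the common encodings (32/64-bit float, zlib or
  none) and reads one precursor per MS2 scan.
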