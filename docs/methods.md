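# Methods

## Scope and data model

The pipeline consumes three inputs: protein sequences with domain
annotations (FASTA + TSV), probe-modified-peptide evidence tables from a
peptide search engine (TSV; one row per peptide observation per SILAC
replicate, carrying light/heavy intensities, a search score, the observed
precursor mass and charge, and a decoy flag), and single-chain predicted
structure models (PDB or mmCIF) with per-residue confidence (pLDDT)
stored in the temperature-factor field, as AlphaFold writes it. It does
not perform spectral searching, structure prediction, or docking — those
sit on the far side of its input boundary.

All residue coordinates are 1-based and inclusive. Sites live in the
coordinate frame of a `ProteinRecord`; chimeras carry an explicit
bijective map between parent and chimera coordinates.

## Quantification and filtering

Evidence rows are localized by exact, unique substring match of the
peptide in the protein; ambiguous placements are dropped and logged
rather than guessed, because a site-level claim requires unique
localization. Sites are rolled up per (protein, residue): within a
replicate the SILAC ratio is the ratio of summed light to summed heavy
intensities across supporting rows (a sum-based roll-up is robust when a
site has one or two low-intensity observations; a median-of-ratios
variant would behave similarly at this evidence depth). When the heavy
channel is absent the ratio is assigned a cap (default 20; any value
above the enrichment threshold works, and the cap also bounds ordinary
ratios). The best score and worst |ppm| across supporting rows represent
the site.

Four filters gate acceptance, each with its literal inequality sense:

| filter | rule | default |
|---|---|---|
| enrichment | any replicate SR strictly > `sr_min` | 5 |
| identification | best score ≥ `score_min` | 500 |
| mass accuracy | max |ppm| ≤ `ppm_max` | 5 ppm |
| protein FDR | protein q-value ≤ `protein_fdr_max` | 0.01 |

The boundary behavior matters: SR = 5.0 fails, score = 500 passes,
|ppm| = 5.0 passes. Mass accuracy is evaluated at the precursor level
(observed vs theoretical monoisotopic mass, including the configurable
probe-adduct mass; the adduct mass is a required parameter because it is
probe-specific).

Protein-level FDR is target–decoy: at a score threshold t, FDR(t) =
(#decoy proteins ≥ t) / max(1, #target proteins ≥ t), with no
pseudo-count. Each protein's q-value is the minimum FDR over the
acceptance sets containing it (prefix minimum over ascending candidate
thresholds), which makes the passing set monotone in the threshold. The
estimator is calibrated under the standard assumption that decoy best
scores are exchangeable with false-target best scores and arise in equal
numbers; the estimate is evaluated in its operating regime (estimated
FDR ≤ 5%), where the simulator shows agreement with realized error
within ±0.02 at 10⁴ proteins.

Two quality checks accompany filtering: the 1:1 probe/probe control
(sites whose control SR leaves [0.5, 2] are flagged; the experiment-level
median should sit near 1) and pairwise Pearson correlation of log₂SR
between replicates over shared sites (undefined, not zero, below 3
shared sites).

## Structure mapping

Models are parsed with gemmi. A file is rejected as not AlphaFold-style
when any temperature factor leaves [0, 100]; multi-chain files are
rejected naming the chains. Model residue numbers are taken as
authoritative sequence positions (the AlphaFold full-length convention),
with an offset parameter for trimmed models, and the model sequence must
match the protein record position-by-position — any mismatch is a hard
error, since a silent off-by-one would corrupt every downstream site.

Each site is represented by one atom: Lys NZ or Tyr OH (the nucleophilic
side-chain atoms the probe actually modifies), falling back to Cβ then
Cα when truncated. Confidence bands follow the standard pLDDT
convention: very high > 90, confident > 70, low ≥ 50, very low < 50.
Only sites with pLDDT strictly above 70 enter clustering; a site at
exactly 70 is excluded (the inclusion criterion is strict, and the
boundary is documented here because the low band is sometimes quoted
inclusively). Excluded and unresolved sites remain in the mapped output
with `included = False`.

## Pocket clustering

"Pocket" here means exactly a spatial cluster of covalently labeled
residues — no cavity detection, solvent accessibility, or druggability
scoring. Included sites are partitioned by single-linkage clustering
(scipy hierarchical clustering cut at the distance threshold), which
equals connected components of the graph with edges at representative-
atom distance ≤ `cluster_distance`. Defaults: 12 Å threshold,
minimum cluster size 2 (a two-site cluster is the smallest reported
pocket in the motivating data). The partition is order-invariant;
regions are canonically ordered and identified by their smallest member
residue number. A protein with at least one region is `pocket_forming`,
otherwise `diffuse`. The 12 Å threshold is a declared convention
calibrated so that the motivating study's printed site groupings form
the reported clusters; it is configuration-exposed, and increasing it
can only merge clusters (count is monotone non-increasing).

## Chimera liftover

A chimera replaces one explicit backbone interval with one explicit
donor interval; junctions are always inputs, never inferred from domain
annotations (a helper recovers junctions from a published chimera
sequence by exact unique substring match). The coordinate map covers
every chimera position exactly once; backbone positions inside the
replaced interval and donor positions outside the inserted interval are
`unmapped`. Length conservation, residue-identity preservation, and
round-trip identity are enforced and property-tested. Domain
annotations are lifted when wholly retained; a backbone domain
straddling a junction is dropped with a warning, not an error. For a
contiguous tandem-domain engraftment every donor site maps with one
constant offset — a useful consistency check against independently
reported site pairs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the physics beneath it:

* **Sequences** — random multidomain proteins (default 10 per bundle,
  360–520 residues) with Tyr/Lys frequencies near natural abundance
  (2%/6%) and a C1A/C1B/DAGKc/DAGKa layout at fixed fractional
  positions.
* **Evidence** — per replicate (default 3, mirroring triplicate
  biological designs): true sites draw SR from lognormal(ln 12, 0.4),
  background sites from lognormal(0, 0.3), the 1:1 control from
  lognormal(0, 0.2); scores are normal (true ≈ 800 ± 100, decoy ≈ 250 ±
  80); ppm noise is normal with σ = 1.5. True sites are placed inside
  domains, on unique tryptic peptides ≤ 40 residues, one site per
  peptide. Decoy rows come from reversed sequences. Setting scales to 0
  turns noise off, which separates true from background perfectly.
* **Structures** — toy geometric models, loudly not physical folds: a
  compact confined Cα random walk (3.8 Å steps), with site
  representative atoms planted directly — pocket members within a 5 Å
  radius of a pocket center, pocket centers and diffuse-protein sites
  mutually ≥ 25 Å apart, pLDDT ≈ 85–95 in domains and 45–65 in linkers.
  The geometry margins (radius ≤ threshold/2, floor ≥ 2 × threshold)
  guarantee exact pocket recovery when all members survive filtering.

Everything is deterministic per (config, seed): identical seeds yield
byte-identical bundles. A ground-truth manifest records every planted
site, pocket membership, and diffuse flag, and classifies every evidence
row as true/background/decoy.

What passing tests on this generator do **not** show about real data:
the probe's residue-level chemoselectivity (synthetic Y/K site ratios
reflect abundance, ≈ 0.4, whereas sulfonyl-triazole chemistry in cells
is relatively Tyr-biased); correlated intensity noise, missing values,
and chromatographic artifacts; real fold geometry (planted side-chain
atoms are detached from the walk); and search-engine score behavior.
A separate protein-level score simulator (`gen_protein_scores`, default
10⁴ proteins, 20% with true signal) isolates FDR-estimator calibration
from the evidence pipeline.

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen to make
their statistical claims stable: filter-chain recovery at ~300 planted
true + ~2000 background sites per seed, 3 seeds (sensitivity ≥ 0.9
expected; observed ≈ 0.998 because each filter's failure probability per
true site is < 1%); pocket/diffuse recovery on 10-protein structured
bundles, 3 seeds; FDR calibration at 10⁴ proteins, 3 seeds; oracle
equivalence on 200 random instances each. A known behavior at these
noise levels: the ppm-noise tail (P(|ppm| > 5) ≈ 0.1% per row) very
occasionally removes one pocket member, so the acceptance script's exact
pocket-membership recovery rate can fall slightly below 1.0 for some
seeds while diffuse labeling stays exact.

Tie-breaks and degenerate inputs: empty evidence yields empty outputs
with success status; 0 or 1 included sites yield that many singleton
clusters; zero Lys sites make the Y/K ratio NaN (flagged, not infinite);
replicate correlation with insufficient overlap is NaN, never silently
0. Composition averages across proteins are unweighted by length.
Ligand efficiency is |ΔG| / N_heavy (kcal/mol per non-hydrogen atom).

## Known limitations

Single-model, single-chain structures only; no PAE matrices or
multi-fragment models. Semi-tryptic peptides, N-terminal processing and
acetylation are not modeled (evidence tables are assumed post-search).
The evidence-to-site roll-up is a declared convention — published site
tables rarely specify theirs. FDR is protein-level, matching the
filtering design it implements; site-level FDR is out of scope.
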