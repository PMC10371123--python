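# Methods

## Scope and data model

The package analyzes rare germline coding variation in *NBN* along four
stages: prioritization of annotated variants, quantification of two
multiplexed functional assays, a combined pathogenicity call, and an exact
stratified carrier-burden test. Scores (gnomAD allele fraction, CADD, REVEL)
are inputs, never computed; genomic coordinates (GRCh37, 1-based) are opaque
`chrom-pos-ref-alt` identifiers and are never lifted over or parsed beyond
equality. ClinVar designations are carried as annotations only. A missing
REVEL score (truncating variants) is stored as absent, never as 0, so it can
neither pass nor fail a numeric threshold silently.

The nibrin domain map defaults to FHA 24–100, BRCT-I 111–197, BRCT-II
221–330, C-terminal region 331–754, with the N-terminal boundary at residue
330. The exact residue bounds of the FHA/BRCT-repeat module vary between
annotations; any boundary between residues 314 and 447 yields the same
N-terminal membership for every catalog variant, so the choice is not
load-bearing for the packaged data, and all bounds are configurable.

## Prioritization

A variant is *putative damaging* iff `af < 1e-3` **and** (truncating, or
missense with `cadd > 20`). Both comparisons are strict; `af = 0` (absent
from the reference population) passes. The REVEL re-prioritization keeps
missense variants with `revel > 0.45`, again strict. Carrier counting sums
per-variant case counts, which assumes disjoint carrier sets — valid for the
packaged catalog (25 variants in exactly 50 patients) but an assumption for
arbitrary inputs; the rarity of qualifying variants makes double-carriers
negligible at these frequencies. The rarity rule is nominally defined on the
combined case+control allele frequency; per-variant case-side allele counts
are not part of the input table, so the filter operates on the provided `af`
column. Supplying combined frequencies there recovers the stricter rule.

## Reporter-stability screen

Per-cell EGFP:mCherry ratios are computed after gating to recombined cells
(`mcherry > mcherry_min` and `bfp < bfp_max`; defaults 50 and 100 in the
synthetic units of the simulator — real instruments need instrument-specific
gates, which the assay's publications do not standardize). The central ratio
is the **geometric mean** of per-cell ratios: flow intensities are
approximately log-normal, making the geometric mean the natural location
estimate and giving exact scale-equivariance — a shared detector gain cancels
in the fold change against wild type. Normalization is per-cell first, then
summarized; summarizing each channel and then ratioing is the other
defensible order and differs only at second order for log-normal data.

Fold changes are computed per replicate against that replicate's wild-type
ratio (pooled wild-type geometric mean as fallback) and averaged
arithmetically across the three replicates. At least 500 gated events are
required per acquisition (configurable); fewer is an error, not a silent
small-n estimate. A gated set with any zero mCherry is an error; zero EGFP
yields ratio 0 (fully unstable protein).

Class bins on the fold change `fc`: complete loss `fc <= 0.1`, partial loss
`0.1 < fc <= 0.5`, mild loss `0.5 < fc <= 0.8`, WT-like `fc > 0.8`. This is
the left-closed-on-reduction convention (a 10-fold signal reduction is a
complete loss: reduction of exactly 90% qualifies); the bins are implemented
as thresholds on `fc` directly because computing `1 - fc` first misplaces
exact boundary values through binary round-off (e.g. `1 - 0.8 < 0.2`).

## Mitomycin-C depletion screen

Barcode counts are normalized per sample to frequencies,
`(count + 0.5) / sum(count + 0.5)`; the 0.5 pseudocount keeps fold changes
defined for fully depleted barcodes and perturbs frequencies by < 1% at the
default depth of 10⁶ reads. The total runs over mapped library barcodes only.
Per barcode and replicate, the fold change is frequency at day 10 or day 14
over the same replicate's day 0; a variant's score is the **arithmetic mean**
of its nine barcode-by-replicate values (3 barcodes × 3 replicates). The
class is assigned from day 14 only (day 10 is reported for trend): high
`fc < 0.75`, moderate `0.75 <= fc <= 1` (both boundaries closed, since the
neighboring bins are open on those sides), WT-like `fc > 1`. Frequencies are
compositional — columns sum to 1, so depletion of sensitive variants pushes
neutral variants above 1, which is why fold changes above unity are the
WT-like signature rather than noise. No re-centering on the wild-type library
member is applied: normalization is to day 0, not to WT. A QC table reports
each variant's min/max per-barcode fold change to flag discordant barcodes.

## Pathogenicity decision table

`pathogenic` iff (complete loss, high); `likely_benign` iff (stability in
{WT-like, mild loss} and MMC WT-like); `likely_pathogenic` otherwise. The
table is total over all 4 × 3 class pairs and monotone (worsening either
axis never improves the call). Pairs not observed in the packaged data (e.g.
complete loss with WT-like tolerance) fall to `likely_pathogenic` through the
otherwise-branch — the conservative middle call for discordant evidence.
The Pearson correlation between the two screens' continuous fold changes is
provided (t transform, n − 2 df) and validated by synthetic recovery of a
shared latent severity, not against any fixed published value, since the
continuous per-variant values are not distributable data.

## Exact stratified burden test

Within each ancestry stratum, carriers/non-carriers in cases vs controls form
a 2×2 table. Conditional on all margins, the case-carrier count is
hypergeometric under the null of no association, and the summed count
`S = sum a_k` has the convolution of the K hypergeometric pmfs as its null
law. Kernels come from `scipy.stats.hypergeom` (log-gamma based) and are
convolved in linear space (`numpy.convolve`), clipped at 0 and renormalized;
supports at these cohort sizes are a few hundred points, so the O(K·range²)
cost is trivial. The two-sided p-value is the minimum-likelihood convention —
total probability of all `s` with `P(S=s) <= P(S_obs) · (1 + 1e-7)`, the
relative guard absorbing floating-point ties — clamped to (0, 1]. For K = 1
this reproduces `scipy.stats.fisher_exact` to machine precision; degenerate
strata whose margins force `a_k` contribute point masses and a fully
degenerate configuration yields p = 1.

The effect estimate is the Mantel–Haenszel common odds ratio (not the
conditional MLE; MH is the standard companion to CMH and is unbiased enough
at these counts), with optional Haldane–Anscombe 0.5 corrections applied to
all four cells of any stratum containing a zero cell. Control summary counts
are treated as carrier counts of distinct individuals. Region-restricted
tests recompute the case-side carrier total over variants whose residue
satisfies a region predicate; with more than one stratum the caller must
supply the per-stratum split of those carriers, since variant records carry
no ancestry. No multiple-testing correction is applied by default (one gene
and its domains); callers running many regions should correct externally.

## Synthetic data

The generators are pure functions of (config, seed) via
`numpy.random.default_rng`, bitwise-reproducible.

**Flow events** — mCherry is log-normal (log-mean ln 1000, log-sd 0.5, in
arbitrary intensity units); EGFP is `stability_factor × mcherry ×` log-normal
noise (log-sd 0.25), so the per-cell ratio is log-normal around the factor.
10% of events are non-recombined contaminants with high BFP (log-mean
ln 1000) and background EGFP, exercising the gate. Default 4,000 events per
acquisition, the scale of one screened variant histogram.

**Barcode screen** — exponential growth/death kinetics: barcode abundance
evolves as `skew × exp((g − s_v·κ)t)` with `g = ln2/doubling_time` (24 h) and
kill rate κ defaulting to `ln2/24` per hour so sensitivity `s_v = 1` exactly
cancels growth. Initial skew is symmetric-Dirichlet (concentration 50) over
the 3 barcodes/variant, drawn per replicate; reads are one multinomial draw
of 10⁶ per sample, so column totals equal the depth exactly and frequencies
are compositional by construction. `expected_fold_change` gives the noise-free
closed form (the shared `g` cancels in the composition) and
`sensitivities_for_targets` inverts it, which is how tests place variants at
class-midpoint expected fold changes. Logistic growth, PCR noise, and barcode
collisions are not modeled; what passing tests show is that the
quantification chain recovers known relative fitness from multinomial
counting noise, not that it is robust to library-prep artifacts.

**Cohort** — control carriers are Binomial(n0_k, p0_k); case carriers are
Binomial(n1_k, p1_k) with `p1 = θ·p0 / (1 − p0 + θ·p0)`, so θ is exactly the
per-stratum carrier odds ratio the MH estimator targets. Defaults emulate the
study scale: 4,183 cases and 118,479 controls over three ancestry strata
(55/25/20% — a realistic split; the true stratum composition is not public),
control carrier frequency 0.2% per stratum, θ = 1.77. Null calibration at
these sizes gives a type-I fraction slightly below 0.05 (exact conditional
tests are conservative), which the suite checks over 1,000 replicates, and
the MH estimator recovers θ = 3 within ±20% in median over 200 replicates.

## Problem sizes in the test suite

Class-recovery checks run 20 seeds at 2,000 flow events and 10⁶ reads;
calibration uses 1,000 null cohorts and recovery 200; Fisher agreement is
exhaustive for 2×2 tables with totals ≤ 8 plus 300 random tables with totals
≤ 30, and the enumeration oracle covers 2–3 strata with cell totals ≤ 15.
These sizes make the whole suite run in well under a minute of statistical
testing while leaving each check's power intact.

## Command-line interface

Each subcommand is a thin wrapper over one library stage; the `pipeline`
command chains prioritization, classification, and the summary report, with
an optional burden stage when a strata TSV is given. Parameters are CLI flags
with documented defaults rather than a config file: every artifact embeds a
`run_info` block (package version, seed, SHA-256 hash of the effective
parameters), so a run is reproducible from its outputs alone. Percentages in
reports are rounded half-up to one decimal.

## Known limitations

- Gating thresholds are config values, not inferred; no spillover
  compensation or automated gating.
- Counts are the input to the depletion screen; no read-level demultiplexing
  or barcode error correction.
- The burden module accepts arbitrary strata and cannot validate that the
  caller's control counts were restricted to the same variant set or region
  as the case side.
- Carrier counting rejects nothing when carrier sets overlap; it simply sums.
  Per-individual genotypes, when available, should be collapsed to carrier
  status upstream.
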