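# Methods

## Generative model of dual-reporter cytometry data

A singlet cell's fluorescence in channel *ch* is

    I_ch = mu_ch · E · X_ch,   E ~ LogNormal(0, σ_ext),  X_ch ~ LogNormal(0, σ_int,ch)

with `E` shared by both channels within a cell and `X_ch` independent
per channel. This multiplicative extrinsic x intrinsic factorization
was chosen because fluorescence is analyzed on a log scale and because
it gives the dual-reporter decomposition a known ground truth: for this
model, exactly,

    η²_ext = exp(σ_ext²) − 1,
    η²_int = exp(σ_ext²) · (exp(σ_int²) − 1)   (equal intrinsic sigmas),

both reducing to σ² to first order for small σ
(`noise_stats.lognormal_eta2`). Default parameters (`ReporterModel`):
mean intensities 1200 (GFP) and 900 (mCherry) a.u., σ_ext = 0.25,
σ_int = 0.15 per channel — chosen to put the population two decades
above the trigger threshold with noise levels typical of
moderately-expressed reporters; they are free parameters, not
calibrated to any particular strain.

Scatter: FSC-A is lognormal (median 6x10⁴ a.u., log-SD 0.22) and SSC-A
is generated with log-scale correlation 0.65 to FSC-A, giving the
smooth unimodal FSC-A/SSC-A cloud the contour gate assumes. Debris is
placed uniformly below the trigger threshold with near-zero
fluorescence; doublets are sums of two singlet draws with FSC-W
inflated by a uniform factor in [1.6, 2.2], which guarantees
separability for a quantile-based doublet gate without tuning.

What the generator does *not* emulate: autofluorescence, spectral
bleed-through, detector saturation, non-lognormal burst kinetics, and
cell-cycle substructure. Tests passing on this model therefore show
that the estimators recover the truth of a separable lognormal world,
not that instrument artifacts are handled.

## Gating

Fixed pipeline order: trigger → doublet → contour → log-transform.

* **Trigger**: FSC-A < 2570 a.u. excluded (strict; events exactly at
  the threshold are retained).
* **Doublet gate**: removes events above the within-sample FSC-W
  quantile (default 0.90). The boundary is data-driven because no
  absolute width cutoff is instrument-portable. Skipped with a warning
  below 10 events. Because it re-quantiles, re-applying it removes
  another 10%; it is not idempotent and is not meant to be re-applied.
* **Contour gate**: 64x64 2-D histogram on FSC-A/SSC-A; bins admitted
  in decreasing-count order (ties by (row, column) index) until the
  admitted bins first hold ≥ 80% of events. Retention can overshoot
  the target only by the mass of the last admitted bin (≈0.05% at
  10⁵ events); re-applying the gate to its own output again removes
  ~20%, since admission is defined relative to the current sample, so
  the contour gate is likewise single-shot by design.
* **Log-transform**: base 10 by default (a config knob — the Fano
  factor is not invariant to the base); non-positive intensities are
  dropped and counted, with a warning above 5%.

Event order is preserved through all gates so provenance labels stay
aligned, and each stage appends a `GateReport` (n_in/n_out +
parameters) to the table's history.

## Noise statistics

`fano` uses the sample variance (ddof = 1); at the 10⁴–10⁵ events
typical here the choice is numerically immaterial but it must be fixed
for exact tests. The Fano factor is computed on log-transformed
intensities (the pipeline's scale); a linear-scale computation is
available by passing linear data with `force`.

`decompose` takes **linear**-scale paired intensities and rescales each
channel to unit mean first, which makes the estimate invariant to
fluorophore brightness and detector gain and lets the two reporters be
treated as exchangeable. Negative extrinsic estimates are reported
as-is; clipping would break the additivity identity
η²_tot = η²_int + η²_ext, which holds to < 10⁻¹⁰ relative error by
construction.

## Selection-protocol simulator

Lineages are parameter vectors (reporter model, relative glycerol
growth rate, defect flags) with integer abundances. One EMS round
converts a Binomial(N, mutant_fraction) number of founding cells into
mutant classes (noise-up, general up/down regulator, single-reporter
defect, mitochondrial defect, neutral); cells of one class are grouped
into at most 10 founder lineages with independently drawn effect
magnitudes — per-cell lineages would add nothing to frequency dynamics
at the population sizes simulated. Default class probabilities put
rare large-effect classes at 0.2–1% of mutagenized cells.

"Outermost 10%" is realized as the exact floor(0.10·n) largest
Mahalanobis distances from the centroid of the (log GFP, log mCherry)
cloud under the sample covariance — this respects the elliptical shape
of lognormal populations; a singular covariance falls back to
Euclidean distance with a warning, and ties break by event index so
the mask is deterministic. Quadrant boundaries sit at the per-channel
medians (robust, parameter-free); boundary events go to the "at/below"
side. The sort keeps cells in (outermost ∩ quadrant).

Recovery is deterministic exponential growth plus multinomial
resampling to the target size (exactly), with weights
abundance·2^(growth·generations); mitochondrially defective lineages
grow at 0.05x wild-type and are effectively eliminated by ten
generations in glycerol. Agent-based division is deliberately avoided:
frequency dynamics are all the protocol analysis needs.

Desk scale: acquisitions of 2x10⁴ events per sort, up to 10⁴ sorted
cells, recovery to 10⁵ (the bench protocol sorts 10⁵ from much larger
populations). The 10x scale-down preserves enrichment behavior while
keeping a full two-round protocol under a second; all sizes are
`ProtocolConfig` knobs. At the default scale a lineage class seeded at
frequency 10⁻³ is carried by ~20 cells per acquisition, so occasional
stochastic loss of such a lineage is expected behavior (drift at the
sort bottleneck), which is why enrichment is asserted across seeds
rather than per seed.

## Bulk-segregant mapping

Segregant genotypes follow a 1:1 segregation at the leftmost locus of
each chromosome with Haldane recombination r = (1 − e^(−2d/100))/2
between adjacent loci (no interference — the simplest standard map
function); different chromosomes assort independently. Phenotypes are
base Fano + effect·(causal allele) + N(0, sd) per replicate (3
replicates by default).

Classification calls a replicate evolved-like iff its Fano exceeds the
midpoint of the two parental references; the segregant label requires
all replicates to agree, else it is excluded as inconsistent. The
midpoint rule is this package's own choice of classifier (a simple,
replaceable strategy); pools of 20 are drawn seeded and uniformly from
the consistent segregants of each class.

Pooled reads are Binomial(depth, p(1−e) + (1−p)e) per site with
symmetric base error e — a single-parameter error model sufficient for
testing SNP-index robustness. The SNP index is alt/(ref+alt) with the
alternate allele oriented to the evolved parent; zero-depth sites are
dropped (not imputed) and counted. Both filters (index > 0.3 in ≥ 1
bulk; ΔSNP > 0.8) and both clone-variant filters (coverage > 30,
AF > 0.5) are strict inequalities. No sliding-window smoothing or
interval estimation is applied to ΔSNP.

## Assays

* 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_control)_test − (Ct_target −
  Ct_control)_ref; no efficiency correction.
* Maximal growth rate: the largest OLS slope over every contiguous
  20-point window (ties → earliest window). The window must be short
  relative to the growth timescale or the estimate smooths below the
  instantaneous maximum r·K/4 of a logistic — at 12-minute sampling a
  20-point window spans 4 h, adequate for yeast in glycerol.
* P/M ratio: trapezoidal integration of (A254 − baseline) over
  caller-supplied peak boundaries, baseline = minimum absorbance over
  the full boundary span (simplest defensible choice, recorded in the
  result); only the 80S peak forms the monosome denominator (40S/60S
  excluded). Peak boundaries are inputs, not auto-detected.
* Competition fitness: experimental ratio / control ratio per time
  point, cancelling the selectable-marker cost; missing control points
  propagate as missing output; a zero control is an error.

## Numerical and design notes

* All generators and stochastic stages take explicit integer seeds; a
  run-level seed derives per-stage seeds by fixed offsets
  (`config.STAGE_OFFSETS`), and full runs are bit-reproducible.
* Event tables interchange as CSV, pooled counts as TSV or VCF with
  per-sample AD fields (read via pysam); FCS ingest is not provided —
  export to CSV upstream.
* Multi-allelic VCF sites are skipped by default (counted) or split
  per alternate allele behind a flag.
* Problem sizes in the test suite (10⁵-event noise recoveries, 100
  seeded crosses, 10-seed protocol replicates) were chosen as the
  smallest scales at which the Monte-Carlo assertions are stable.

## Known limitations

* The lognormal reporter model has no mean–noise coupling; real
  promoter-level noise shows abundance scaling the Fano factor only
  partially removes.
* The simulator treats sorting as exact mask evaluation on a sampled
  acquisition; sorter impurity/yield and abort rates are not modeled.
* Segregant phenotyping noise is Gaussian and i.i.d. across replicates;
  day effects or batch structure would inflate the inconsistent class
  relative to this model.
* The ΔSNP analysis assumes oriented biallelic sites with both parents
  sequenced; unorientable sites must be dropped upstream.
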