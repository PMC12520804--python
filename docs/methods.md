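# Methods

## Reference model

The 22 human mt-tRNA genes are modelled as a catalog of `(name, start, end,
strand, sequence)` records plus one explicit cloverleaf position table per
gene. All coordinates are 1-based inclusive rCRS; no 0-based interface
exists. H-strand genes store the rCRS slice as their tRNA-sense sequence;
the eight L-strand genes (Gln, Ala, Asn, Cys, Tyr, Ser(UCN), Glu, Pro)
store its reverse complement, and their within-gene offsets count from the
gene's 3'-most rCRS coordinate, so offset 1 is always the tRNA 5' end.
Variant alleles are always stated in rCRS terms and complemented internally
before structural interpretation; reports echo the rCRS alleles.

Cloverleaf numbering is **data, not algorithm**: mammalian mt-tRNAs have
truncated D- and T-arms, a missing D-arm in tRNA-Ser(AGY), and irregular
variable regions, so mitotRNAdb-style numbering cannot be derived reliably
from sequence. Each gene therefore carries an ordered list of
`(position_number, sequence_index, element, partner)` entries, validated on
load: every sequence index appears exactly once, paired numbers are unique
within a gene, and the partner relation is symmetric. Loop insertions reuse
the preceding position number and are never paired. The element vocabulary
is {Acceptor arm, D-arm, Anticodon stem, Anticodon loop, Variable region,
TψC loop}; stem halves of the D- and T-arms carry the arm label, which is
also how screening tables in this field label positions such as 13 or 61.
The canonical pairing template is acceptor 1–7 ↔ 72–66, D-stem 10–13 ↔
25–22, anticodon stem 27–31 ↔ 43–39 (so 30 pairs with 40) and T-stem
49–53 ↔ 65–61, with per-gene curated exceptions where the numbering tables
demand them (e.g. an extended-stem 26 ↔ 44 pair in the two leucine/serine
isoacceptors that annotate it, and a tRNA-Ala T-arm label inversion carried
as printed).

### The bundled catalog is sequence-synthetic

Real NC_012920.1 sequence is not redistributed here. The bundled file
(`data/mt_trna_catalog.synthetic.tsv`, written by `scripts/build_catalog.py`)
uses standard rCRS gene coordinates and strands — minimally adjusted for
pairwise disjointness where the real annotations overlap by 1–3 bp
(tRNA-Gln starts at 4332, tRNA-Tyr at 5827), so coordinate lookup is
single-valued — but its sequences are constructed: every position named in
the bundled study variant table carries its documented reference allele
(strand-corrected), every annotated pair those rows constrain carries the
documented partner bases, every other annotated pair is Watson–Crick
complementary, and remaining positions are seeded-random. Analyses that
depend only on catalog structure and on the constrained positions (all
tests and reports in this package) behave identically to a real-sequence
catalog; anything else must not treat the sequences as real.

## Structural effect of a substitution

A substitution at a paired position *disrupts* when the reference pair is
Watson–Crick (A·T or G·C after mapping both bases to tRNA sense) and the
mutant pair is not, and *creates* in the reverse case; G·U wobble is
deliberately not Watson–Crick, which is the convention that makes a
C-G → U·G change a disruption and a U·G → C-G change a creation. The
rendered pair string uses rCRS-allele space with the 5'-side base first,
showing the reference pair for disruptions and the newly formed pair for
creations. This single convention reproduces 7 of the 8 published pair
strings exactly; the eighth (the Ser(UCN) anticodon-stem creation) is
printed with the opposite letter order in the source table, and the golden
comparison reports that row rather than special-casing it. Arrows
(created/disrupted) match 8 of 8.

Variant calling from sequence is a positional mismatch scan of equal-length
gap-free segments (base calling and alignment are upstream concerns);
non-ACGT positions are skipped with a logged count. Only substitutions are
modelled, as homoplasmic presence/absence per subject — heteroplasmy
fractions and indels are out of scope.

## Conservation index

CI(column) = 100 · n_match / n_compared over non-human rows, where rows
gapped at the column are excluded from the denominator. The per-position
effective depth therefore varies, which is the only reading consistent with
published CI values that are not all multiples of 1/15 at a fixed
15-species panel. The species set is caller-supplied data; no bundled
alignment claims to reproduce published CI values, which are consumed as
fixture data where needed. The functional-importance threshold is
**inclusive**, CI ≥ 75% — required for a published count of six
high-conservation variants that includes a row at exactly 75.0.

## Association and clinical statistics

The association test is the uncorrected Pearson chi-square on the 2×2
carrier table, df = 1, two-sided p from the χ² tail. On the sparse tables
of rare variants this choice is forced by the published values: the
headline table (2/302 vs 0/589) gives p = 0.048 uncorrected, ~0.22 with
Yates correction, ~0.12 by Fisher. Fisher remains available behind a flag
as an explicit deviation. Degenerate tables (a zero margin, e.g. no
carriers at all) raise instead of returning a value. No multiple-testing
adjustment is applied by default across the screen's 43 tests, matching
the screening convention; a Bonferroni column can be requested and is
emitted with a warning.

Recomputing p for every bundled study row from its own printed counts
agrees with the printed p at 2-decimal precision (within 0.011) for 42 of
43 rows; the one exception (the tRNA-Gly variable-region variant with
counts 3/302 vs 2/589, printed 0.98, recomputed 0.216) is internally
inconsistent in the source and is asserted *as a flagged discrepancy*, not
forced.

Student's t uses pooled variance (Welch optional), HOMA-IR is
insulin × glucose / 22.5 with an inclusive insulin-resistance flag at 2.69,
BMI is weight/height², and 2^−ΔΔCt is the standard relative-expression
fold change. Group-level clinical p-values are not reproduced from summary
statistics: means of per-subject products (HOMA-IR) differ from products of
means, and several published covariate p-values are not recoverable from
mean ± SD alone, so they are treated as display data.

## Screening rules

A variant is `candidate_pathogenic` iff control carrier frequency < 1%
(strict), CI ≥ 75% (a missing CI fails closed), and the substitution
creates or disrupts a Watson–Crick pair. Functional evidence from cell
models is an input flag (supported/refuted/untested) recorded separately
and never computed; untested does not block candidacy, since functional
work follows the screen. Variants carried only by controls are
`benign_polymorphism`; everything else is `uncertain`. Candidate and benign
are mutually exclusive by construction, and classification is
order-invariant.

## Synthetic data

The cohort generator emulates the study design: 302 cases / 589 controls,
per-variant carrier status drawn per subject (Bernoulli mode) or planted as
round(freq · n) exact counts (for golden tests), and clinical covariates as
independent Gaussians truncated at zero at the published group mean ± SD.
HOMA-IR is computed from simulated insulin and glucose rather than sampled.
Not emulated: mutational spectra, haplogroup structure, covariate
correlations, linkage between variants — so passing simulation tests
demonstrates the pipeline's arithmetic and calibration, not robustness to
those real-data features. The alignment generator plants exact per-column
match counts k/n_species (rejecting unrepresentable fractions), so CI
equals its target by construction. All generators are deterministic given
their seed.

### Calibration experiments and their honest outcome

Two seeded desk-scale experiments characterise the screen (200 replicates
each by default; problem sizes chosen to keep the full suite in seconds):

* **Null calibration** — one variant at equal carrier frequency 0.005 in
  both groups; the fraction of replicates with p < 0.05 is ~0.025,
  within the accepted [0.02, 0.10] band for the uncorrected chi-square at
  small counts.
* **Planted recovery** — one variant at case/control frequencies
  0.02/0.001 against a null background emulating the study itself (the 42
  other screened variants at their observed pooled frequencies, equal in
  both groups); recovery = the planted variant attains the smallest p
  (ties count, since sparse tables coincide exactly). Measured recovery is
  ~0.83–0.87 across seeds. This falls short of a 0.90 recovery target by
  necessity, not by implementation error: the marginal power of the test
  itself at this effect size in a 302/589 cohort is only ~0.89, an upper
  bound that competition from 42 null variants can only lower. The
  corresponding acceptance test asserts the 0.90 target and is expected to
  fail; the measured rate is reported by the acceptance script.

## Numerical and degenerate-input choices

Chi-square is computed from the closed-form margins formula in float64 (the
test oracle uses the independent Σ(O−E)²/E route); p-values keep full
precision internally and are formatted only for display (3 decimals below
0.05, else 2; CI 1 decimal; percents 2). Reports are bit-stable under
write → read → write. Carrier ties in ranking are broken in favour of
recovery as described above; empty genotype tables tabulate to all
non-carriers; zero-margin tables, all-gap alignment columns, non-positive
physiological inputs and out-of-range coordinates raise typed errors rather
than propagating NaNs.

## Known limitations

The catalog's sequences are synthetic outside the constrained positions
(above); cloverleaf numbering reproduces the source screening table, which
is itself internally inconsistent in two places carried as data (a T-arm
numbering inversion in tRNA-Ala; one pair string printed in reversed letter
order). CI cannot be recomputed for published variants without the original
15-species alignment, so published CI values are fixture data. Haplogroup
stratification, covariate-adjusted association, heteroplasmy-aware scoring
and read-level QC are out of scope.
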