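# Methods

## The permutation test

The unit of measurement in a pooled screen is the sgRNA read count
$Y_{ij}$ ($i = 0$ control, $i = 1$ treatment). The test makes no
distributional assumption about these counts; significance comes entirely
from permutation of the sgRNA-to-gene assignment.

**Normalization.** A pseudocount (default 1) is added to every raw count,
then condition $i$ is scaled by $\mathrm{mean}(Y_{0+}, Y_{1+})/Y_{i+}$.
The pseudocount is applied uniformly to all cells — never selectively to
zeros — so it introduces no rank distortion, and it guarantees finite log
fold changes $r_j = \ln(Y_{1j}/Y_{0j})$. With pseudocount 0 the code
refuses to take logs of zero and points the user at the option.

**Gene score.** $R_g$ is the median of the gene's $r_j$ (even cardinality:
midpoint of the central pair). The median, rather than the mean, bounds the
influence of a single outlying or off-target guide.

**Common null.** Each permutation shuffles the gene-label vector uniformly
across sgRNAs while each sgRNA keeps its own count pair, so the multiset of
$r$ values entering every permutation is identical and the multiset of gene
sizes is preserved. All $G \times T$ permuted medians are pooled into one
null shared by all genes. A common null trades gene-level exactness (which
matters little when gene sizes are few and shared) for resolution: at
$G = 10{,}000$, $T = 10$ already yields $100{,}000$ null values, whereas
per-gene nulls of equal resolution would need $100{,}000$ permutations.
Genes of unequal size are handled correctly — block medians are computed
per size class — but the null is then a mixture over sizes.

**Two rounds.** Round-1 p-values are computed against the all-genes null;
genes with unadjusted $p < $ `removal_threshold` (default 0.05) in either
direction are excluded from the second label permutation, and final
p-values for all genes (including the excluded ones) are taken against the
cleaned null. The refinement exists because genuinely selected genes drag
extreme $r$ values into the null and mask weaker hits.

**p-value convention.** Strict inequalities define both tails, so scores
tied with null values count toward neither ($p^{pos} + p^{neg} +
\text{tie fraction} = 1$ before flooring). Both p-values are floored at
$1/(\text{null size} + 1)$: a finite permutation null cannot certify
$p = 0$, and Fisher combination requires $p > 0$. BH is applied separately
to the positive and negative p-value vectors, since the two directions are
reported as separate families.

**Replicates.** Each replicate is normalized, permuted, and tested
independently (its own seed, derived from the master seed via
`numpy.random.SeedSequence.spawn`), then per-gene p-values are combined
with Fisher's statistic $-2\sum_s \ln p_{gs} \sim \chi^2_{2S}$ and BH is
applied to the combined values. Replicates must share the gene universe;
anything else is a hard error rather than a silent intersection.

### Known calibration property of the two-round design

On data with *no* true effects, round-1 removal still discards the ~10% of
genes that are extreme by chance, which deflates the tails of the round-2
null and makes the final p-values slightly anti-conservative in the body:
we measure a mean ECDF deviation from uniformity of about +1.8% (40
effect-free simulations, 2,000 genes). The bias is far too small to survive
BH — effect-free screens yield essentially zero calls at FDR 5% — and it
vanishes exactly when `removal_threshold = 0`. The test suite pins both
facts: uniformity (KS) of the p-values with removal disabled, a < 4% bound
on the deviation with the default threshold, and the zero-false-call
property of the default procedure.

## Tunable parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| `n_permutations` (T) | 10 | permutations | 100,000-value null at genome scale; raise for small libraries |
| `removal_threshold` | 0.05 | unadjusted p | removes plausible hits from the round-2 null; 0 disables refinement |
| `pseudocount` | 1 | reads | finite $r_j$; uniform, so rank-neutral |
| `fdr_level` | 0.05 | BH level | conventional reporting level |

Either-direction round-1 significance triggers removal (a gene extreme in
one tail distorts the null for both).

## The simulator

The generator emulates the count-generating process of a sequenced pooled
screen, not its biology:

- **Library abundance.** $\gamma_{0j} \sim$ NB(3, 0.08) (failures before
  the 3rd success; mean $\approx 34.5$), zero-truncated by resampling since
  Dirichlet parameters must be positive — a right-skewed abundance profile
  like real libraries.
- **Effects.** $\gamma_{ij} = \exp(\alpha_j + \beta_j i)$, so
  $\gamma_{1j} = \gamma_{0j} e^{\beta_j}$ exactly. True-hit genes (50 per
  level at $\mu_g \in \{1.5, 1, 0.5, -1, -2, -3\}$, assigned to random gene
  indices to avoid positional artifacts) draw
  $\beta_j \sim N(\mu_g, 0.4^2)$, reflected to $\mathrm{sign}(\mu_g)$ —
  reflection rather than resampling keeps the stated magnitudes. Null genes
  have $\beta_j = 0$.
- **Off-targets.** A fraction of sgRNAs chosen uniformly library-wide
  (true-hit and null genes alike — the narrower convention can be audited
  through the per-sgRNA flag in the truth table) have $\beta_j$ replaced by
  $N(0, 0.4^2)$ draws.
- **Counts.** Per condition and replicate, one Dirichlet draw with
  parameters $\gamma_{ij}$ followed by one multinomial draw of `depth`
  reads. Moments: $E(Y_{ij}) = Y_{i+}\gamma_{ij}/\gamma_{i+}$ and
  $\mathrm{Var}(Y_{ij})$ equal to the multinomial variance times
  $(Y_{i+}+\gamma_{i+})/(1+\gamma_{i+})$; both are verified by Monte-Carlo
  oracle tests. Dividing all $\gamma_{ij}$ by a constant $d$ leaves the
  means unchanged and raises the variance factor (d = 10: high
  overdispersion; d = 5: the low-quality replicate setting).
- **Depth.** Sequencing depth is a free parameter of the study; the default
  is 300 reads of coverage per sgRNA per condition
  ($Y_{i+} = 300J$), a typical design target for screens. Absolute power
  figures (AUC, calls at a given FDR) depend on this choice.
- **Replicates.** Share one truth table and one intensity vector; only the
  DM sampling differs. This models re-sequencing/re-culturing of one
  experiment, not biological replication of effect sizes.

What the simulator does **not** model: PCR jackpotting beyond DM
overdispersion, guide-specific efficiency, copy-number effects, cell-cycle
or fitness interactions, and time-course dynamics. Passing benchmarks here
demonstrate statistical correctness of the test under overdispersed
multinomial noise, not performance on any particular real screen.

## Evaluation harness

ROC curves rank genes by the direction-specific p-value; positives are the
true hits of that direction and negatives include true hits of the opposite
direction (the convention is recorded on the report object and can be
flipped). Curves from repeated simulations are vertically averaged — TPR
interpolated on a 1,001-point FPR grid — and the AUC of the averaged curve
is reported. Recall/precision/F1 are computed at the BH level per dataset
and averaged with standard errors; an empty call set scores (0, 0, 0) by
convention. Per-dataset seeds derive deterministically from one master seed.

## Problem sizes used in the shipped studies

The replicate-combination study runs at full genome scale (10,000 genes,
3 sgRNAs/gene, 3 replicates, intensities / 5) over 10 seed families. The
calibration and monotonicity studies run at 2,000 genes with the true-hit
*fraction* preserved (10 genes per level), 20–24 datasets per setting —
scale choices made so the whole suite re-runs in well under a minute while
keeping Monte-Carlo error small relative to the effects asserted.

## Numerical and degenerate-input choices

- Empirical p-values use binary search on the sorted null; ties excluded
  from both tails by strict comparison.
- If round-1 removal would discard *every* gene, the round-1 null is reused
  (the refinement is undefined there).
- A condition whose counts are all zero after the pseudocount is rejected
  as a degenerate library.
- Combined Fisher p-values are clipped away from exact 0 (double underflow
  at extremely small inputs) before BH.
- All randomness flows from explicit `numpy.random.Generator` objects or
  seeds; fixed seed + fixed input gives bit-identical output.

## Known limitations

- The common null mixes gene sizes; with highly variable guides-per-gene,
  per-size nulls would be more exact.
- Power at default depth is *not* comparable across depths; treat AUC and
  call counts as functions of the full design.
- The two-round refinement's small null-data anti-conservatism (above) is
  inherent to threshold-based removal on unadjusted p-values.
- sgRNA-level inference is out of scope; so are copy-number correction and
  FASTQ-to-count quantification.
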