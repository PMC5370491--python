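# contamkit

Detection, quantification and correction of cross-contamination in
multi-sample sequencing projects.

Laboratories that process many samples — often from many species — in
parallel inevitably transfer small amounts of genetic material between
tubes, libraries and sequencing lanes. The contaminant reads are easy to
miss and, for non-model species without a reference genome, hard to
distinguish from genuine data. Left uncorrected they distort the most
common population-genetic quantities: they inflate apparent
heterozygosity, bias the inbreeding coefficient F_IT downward, and leak
alleles between individuals and species. `contamkit` is a toolkit for
molecular ecologists and population genomicists who want to measure this
problem in their own read data and correct for it at genotype-calling
time.

## What it computes

**Between-species screen.** Reads are mapped ungapped to an aligned panel
of species barcodes (cox1-style). Hits to a foreign species that is
diagnostic — barcode divergence above 5% — attest a contamination event.
Per-sample hit prevalences (per million reads), a dubious-sample flag, and
a directed species×species contamination matrix **M** (with
non-diagnostic pairs masked) summarize the screen.

**Within-species leakage.** A *homo-quartet* is a read-count vector with
a major state above 40 reads and a minor state of exactly one read — a
homozygote carrying one erroneous or foreign read. At monoallelic
positions these estimate the error matrix P(a, b) = h(a,b)/Σ_k h(a,k); at
biallelic positions the observed rate q_obs at which the minor state
coincides with the other segregating allele z is compared with its
error-only expectation q_exp = mean P(a, z), giving the allele-leakage
index

    λ = (q_obs − q_exp) / q_exp ,

zero without contamination. A between-batch variant λ′ counts only
homo-quartets at positions monoallelic within the focal individual's
batch, isolating leakage across batches (e.g. shipments).

**Contamination-aware genotyping.** Quartet likelihoods are multinomial
mixtures over the ten diploid genotypes with Hardy-Weinberg priors and
per-read state probabilities

    q_x[yz] = (1−γ)·(E[y,x]+E[z,x])/2 + γ·Σ_w f′_w E[w,x] ,

where E carries separate transition/transversion error rates, γ is the
probability a read originates from another individual, and f′ is the
non-focal read-frequency vector. Error rates are fit by maximum
likelihood; γ is selected on the grid {0, 0.05, 0.1, 0.2} by profile
likelihood (γ*). Standard estimators (π_S, π_N/π_S, F_IT, Tajima's D) are
computed from the calls to quantify how much correction matters.

**Metadata tests.** Species-pair predictors (lab_overlap,
same_technician, same_shipment, same_flowcell, same_lane) are tested
against **M** with seeded matrix randomizations, unconditional or
conditional on other predictors, to locate where contamination happened.

## Worked example

Simulate a six-individual dataset (20,000 coding positions, 60× coverage)
with 10% read leakage, then measure the leakage index and re-select γ:

```python
from contamkit.simulate import simulate_quartet_dataset
from contamkit.quartets import columns_from_array, extract_homo_quartets
from contamkit.leakage import leakage_result
from contamkit.genotyping import select_gamma

d = simulate_quartet_dataset(n_individuals=6, n_positions=20_000,
                             coverage=60, eps_ts=0.003, eps_tv=0.001,
                             gamma=0.1, seed=4)
records = extract_homo_quartets(columns_from_array(d.counts))
res = leakage_result(records)
print(f"homo-quartets: {len(records)} (biallelic: {res.h_bi})")
print(f"q_obs = {res.q_obs:.3f}, q_exp = {res.q_exp:.3f}, lambda = {res.lam:.2f}")
sel = select_gamma(d.counts)
print(f"gamma* = {sel.gamma_star}")
```

prints

```
homo-quartets: 23425 (biallelic: 1399)
q_obs = 0.909, q_exp = 0.335, lambda = 1.71
gamma* = 0.1
```

Read: of the 1,399 homo-quartets at positions where a second allele
segregates, 91% carry that allele as their single minor read, where the
error matrix alone predicts 34% — a leakage index of 1.71, far from the
contamination-free expectation of 0. The likelihood profile over the γ
grid then recovers the generating contamination rate (γ* = 0.1). On a
contamination-free simulation the same pipeline gives λ ≈ 0 and γ* = 0.

The same analyses are scriptable from the shell via the `contamkit`
command (`screen`, `matrix`, `leakage`, `genotype`, `popstats`,
`metatest`, `simulate`); every run writes a manifest with its inputs,
thresholds and seed.

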