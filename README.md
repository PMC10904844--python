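# hccmet

Computational pipeline for liver-cancer metabolism studies: cross-cohort
consensus calling of tumor-altered metabolic genes, atom-mapped ¹³C
isotopologue route prediction for central carbon metabolism,
expression-stratified Kaplan–Meier / log-rank survival analysis, and
Seahorse-style ATP-rate partitioning. It is aimed at computational
biologists who want these four procedures as tested, reusable code,
exercisable end to end on synthetic data with planted ground truth.

## What it computes

**Consensus metabolic genes.** Per cohort: Welch-t differential expression
on log2 intensities, gated at P < 0.001 and |log2FC| > 1.5, restricted to a
metabolism-annotated gene list; an adaptive per-cohort threshold
(mean |log2FC| of the cohort's DE output) then calls genes up
(log2FC ≥ +cutoff) or down (≤ −cutoff). Across cohorts, a gene is
*consistently altered* if it falls exclusively in one direction in ≥ 8 of
10 datasets.

**¹³C route predictions.** A carbon-level reaction library (glycolysis,
PDH/PC entry, first-turn oxidative TCA, reductive carboxylation, both
pentose-phosphate arms, glutaminolysis) propagates a tracer's positional
label pattern along declared routes; condensations convolve isotopologue
distributions, f(m+k) = Σⱼ f₁(m+j)·f₂(m+(k−j)). For U-¹³C₆-glucose and
U-¹³C₅-glutamine it reproduces the canonical mass shifts: lactate/alanine
m+3, citrate m+2 (PDH) / m+5 (PDH+PC), oxaloacetate m+3 (PC), succinate
m+2; glutamate m+5, m+4 TCA species (oxidative), citrate m+5 and aspartate
m+3 (reductive); 6-phosphogluconate m+6, ribose 5-phosphate m+5
(oxidative PPP) and m+3 (non-oxidative).

**Survival.** Kaplan–Meier S(t) = Π (1 − dᵢ/nᵢ) and the Mantel–Cox
statistic (Σ(O−E))²/ΣV ~ χ²₁, from formulas, over median or tertile
expression strata.

**ATP partition.** Mito/glyco stress-test metrics and the Mookerjee–Brand
style conversion J_glyc = max(0, ECAR·BF − c·OCR_ATP)·ATP/lactate,
J_ox = 2·(P/O)·OCR_ATP.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_consensus_calls.py
```

prints (ten cohorts of 5200 genes, 20 tumor / 20 normal, 200 planted genes
at 3.0 log2 units among a 2752-gene metabolic list):

```
C09: 200 genes pass the DE gate
consensus: {'consistent_up': 100, 'consistent_down': 100}; sensitivity 1.000
(200/200 planted recovered), 0 false consistent calls
```

i.e. every planted gene is recovered in its planted direction and no null
gene survives the 8-of-10 exclusive vote. Then

```sh
python analysis/03_tracer_predictions.py   # 16 route predictions (table below)
python analysis/04_survival_stratification.py
python analysis/05_atp_partition.py
```

give, for example,

```
median split: chi2 = 8.207, p = 0.00417 (low n=100, high n=100)
tertile split: chi2 = 7.517, p = 0.00611 (low n=67, high n=66)
mito: {'basal': 80.28, 'atp_linked': 60.33, 'proton_leak': 19.95,
       'maximal': 159.79, 'spare': 79.51}
ATP partition: J_glyc = 60.3, J_ox = 299.9, fraction_glyc = 0.167
```

— the high-expression stratum (hazard linked to expression with β = 0.5)
dies significantly faster, and the noisy 8-well plate recovers the profile
plateaus (true basal 80, ATP-linked 60, leak 20, maximal 160, spare 80)
to within sampling error. Outputs land under `results/analysis/`.

The same stages are available as a CLI (`hccmet run-all --seed 1 --outdir
results/run`, plus `simulate`, `diffexp`, `consensus`, `survival`, `trace`,
`atp`), writing a manifest with SHA-256 digests; a fixed seed reproduces
every output byte for byte. For instance:

```sh
hccmet trace --tracer U-13C5-glutamine
```

```
metabolite                   route                                           label  mass_shift  fraction
 glutamate        gln_to_glutamate                                  glutaminolysis           5       1.0
 succinate gln_oxidative_succinate                  oxidative glutamine metabolism           4       1.0
    malate    gln_oxidative_malate                  oxidative glutamine metabolism           4       1.0
 aspartate gln_oxidative_aspartate                  oxidative glutamine metabolism           4       1.0
   citrate   gln_oxidative_citrate oxidative glutamine metabolism, unlabeled AcCoA           4       1.0
   citrate   gln_reductive_citrate          reductive carboxylation, unlabeled CO2           5       1.0
 aspartate gln_reductive_aspartate          reductive carboxylation -> ACL -> GOT2           3       1.0
```

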