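# archseq

Ultra-deep hotspot re-sequencing analysis of **age-related clonal
hemopoiesis (ARCH)** — the expansion of blood-cell clones carrying
somatic leukemia-associated mutations in people without overt blood
disease.

`archseq` implements, as a tested pipeline, the computational core of a
hotspot screening study: quality-filtered allele counting over a
15-hotspot myeloid panel at amplicon depths of 1,000–10,000×,
VAF-threshold mutation calling with a binomial sequencing-error
false-positive model, a dedicated detector for the canonical NPM1 4-bp
TCTG duplication ("mutation A"), and cohort-level age-stratified
prevalence statistics with exact confidence intervals. A synthetic
read/cohort generator reproduces the study conditions so every stage is
testable offline, without raw sequencing data or a reference-genome
download.

## The method

For each interrogated codon position, only reads with **mapping quality
> 15** and **base quality > 25** at that position are counted. The
variant allele fraction is

> VAF = (reads reporting the most-frequent non-reference nucleotide) / (filtered depth)

A hotspot is **called** mutant in a sample when every codon position has
filtered depth ≥ 1,000 and the maximal site VAF is ≥ 0.008 — i.e. a
heterozygous autosomal clone comprising ≥ 1.6 % of blood leukocytes
(cell fraction = 2 × VAF). The probability that sequencing error alone
produces a call is

> P[X ≥ ⌈0.008·D⌉],  X ~ Binomial(D, e)

for filtered depth D and per-base substitution error rate e; at e ≈ 10⁻³
and D ≥ 1,000 this is of order 10⁻⁵ or far below, so calls at these
depths are essentially error-free.

NPM1 mutation A is a 4-bp duplication, invisible to substitution
counting; its detector counts reads whose alignment carries a 4-bp
insertion of TCTG within a ±5 bp window of the canonical insertion
point, over all quality-passing reads spanning the junction.

At cohort level, `archseq` bins individuals by age, estimates carrier
prevalence per bin with exact (Clopper–Pearson) 95 % intervals,
summarises clone VAF distributions, finds individuals with more than one
mutation (flagging convergent spliceosome-gene pairs), compares blood
indices between groups with Welch's unpaired t test, and exposes a
parameterised projection from hotspot-restricted prevalence to
all-driver prevalence (`1 − (1 − p)^r` or `min(1, r·p)`).

The package also ships a transcription of the study's published table of
112 clonal mutations (hotspot, protein change, VAF %, age, same-sample
symbol) as a programmatic fixture.

## Worked example

Spike a 4 % DNMT3A R882H clone into one simulated 5,000× sample with
realistic noise (substitution error 10⁻³, quality strata straddling the
filter bounds), then run the full calling pipeline:

```python
import archseq as a

panel = a.default_panel()
hs = panel.get("DNMT3A R882")

clone = a.CloneSpec(hs, "A", true_vaf=0.04, position=hs.positions[1])
spec = a.SimSampleSpec("donor_61", age_years=61, clones=(clone,),
                       depth=5000, seed=11)
sample = a.simulate_reads(spec, panel, a.ErrorModel())

calls = a.call_sample(sample)
for c in calls:
    if c.called or c.hotspot_label == "NPM1 L287":
        print(f"{c.hotspot_label:12s} vaf={c.vaf:.4f} depth={c.filtered_depth} "
              f"called={c.called} fp_prob={c.fp_prob:.2e}")
top = next(c for c in calls if c.called)
print("clone cell fraction: {:.1%}".format(a.vaf_to_cell_fraction(top.vaf)))
```

prints

```
DNMT3A R882  vaf=0.0359 depth=4259 called=True fp_prob=1.48e-20
NPM1 L287    vaf=0.0000 depth=4735 called=False fp_prob=7.83e-22
clone cell fraction: 7.2%
```

The spiked clone is recovered at its simulated VAF (0.0359 vs a true
0.04, within binomial sampling noise after quality filtering), the other
14 hotspots stay negative, and the attached false-positive probabilities
show that sequencing error cannot mimic such a call at this depth. The
called VAF converts to a clone comprising 7.2 % of leukocytes under the
heterozygous assumption.

A command-line interface mirrors the stages:

```bash
archseq simulate --n 100 --seed 1 --depth 5000 --out-dir sim/ --write-sam 2
archseq count    --sam sim/S00000.sam --out counts.tsv
archseq cohort   --out summary.json
```

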