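# mitoquant

Quantitative pipelines for studying **mitotic bookmarking** — the retention of
chromatin regulators on condensed mitotic chromosomes — in live *Drosophila*
embryos, built for the four bespoke measurements such studies rely on:

1. **% mitotic chromatin binding** from interphase/metaphase image pairs of
   GFP-fusion proteins,
2. **chromatin-binding kinetics** (bound fraction, residence time) from
   fluorescence correlation spectroscopy (FCS) autocorrelation curves, with
   observation-volume calibration from a fluorescein dilution series,
3. **RNA-seq gene categorization** across a four-genotype, three-replicate
   design, with the length/expression filters and fold-change/p-value decision
   tree used in such screens,
4. **genetic-rescue scoring** of balancer-chromosome intercrosses, including
   Mendelian expectations and Fisher exact tests of homeotic-phenotype
   frequencies.

Every stage has a seeded, ground-truthed synthetic-data generator (including a
Brownian-dynamics particle simulator that serves as a first-principles oracle
for the FCS model), so the whole pipeline can be exercised and validated
without any microscope or sequencer output.

## The measurements

**Imaging.** Each nucleus contributes an interphase frame and the following
metaphase frame. Images are rescaled so interphase nuclei are 37 px in
diameter (the metaphase nuclear area is then 52 px). Total signal is measured
in 37 px / 52 px circular areas; their ratio reports nuclear retention. A
46 × 16 px intensity profile is taken perpendicular to the metaphase plate,
normalized so its area equals the metaphase total signal, and the signal in
the chromatin zone (profile positions 16–30) above the nucleoplasmic baseline
(flank mean) is summed. Line means are expressed as a percentage of a
reference line, which defines 100%.

**FCS.** Binding is modelled as exchange between free diffusion (coefficient
*D<sub>f</sub>*) and an immobile chromatin-bound state with pseudo-first-order
association rate *k\*<sub>on</sub>* and dissociation rate *k<sub>off</sub>*:

- bound fraction = *k\*<sub>on</sub>* / (*k\*<sub>on</sub>* + *k<sub>off</sub>*)
- residence time = 1 / *k<sub>off</sub>*

Replicate curves per nucleus are screened for outliers (median-curve MAD
rule), averaged, and fitted by weighted nonlinear least squares with either a
pure-diffusion or the full reaction–diffusion autocorrelation for a 3-D
Gaussian observation volume. The volume is calibrated from fluorescein curves
fitted at fixed *D<sub>f</sub>* = 425 µm²/s via *V* = *n* / (N<sub>A</sub>·*c*).
Lines are compared by one-way ANOVA with Dunnett's many-to-one post-test.

**RNA-seq.** RPKM per sample; genes < 200 bp or with summed per-genotype mean
RPKM < 1.0 are removed. Each retained gene is classified by its ordered triple
of fold-change calls along the genotype chain (> twofold up / down / none),
giving a numbered category; counts are reported as "n_strict (n_total)" where
the strict count additionally requires p < 0.01 (t test over the three
replicates) on every relevant change.

**Rescue.** In a mut1/TM3 × mut2/TM3 intercross, balancer homozygotes die, so
full rescue corresponds to one third (33%) of scored adults being
transheterozygous; percent rescue = 100 × observed/expected. Bristle-phenotype
frequencies are compared with two-sided Fisher exact tests.

## Worked example

Quantify three synthetic lines with planted bound fractions 0.8 (reference),
0.4 and 0.1, five Poisson-noise nuclei each:

```python
from mitoquant.simulate.embryo import EmbryoSimParams, generate_embryo_pair
from mitoquant.mitotic_binding import quantify_lines

def line(bf, seed0, n=5):
    return [generate_embryo_pair(EmbryoSimParams(bound_fraction=bf, seed=seed0 + i))[0]
            for i in range(n)]

results = quantify_lines(
    {"ASH1-WT": line(0.8, 0), "dBAH": line(0.4, 100), "dBAH-mutAT1": line(0.1, 200)},
    reference_line="ASH1-WT",
)
for name, r in results.items():
    print(f"{name:12s} {r.percent_of_reference:6.1f} % +/- {r.sd:4.1f}  (n={r.n_nuclei})")
```

```
ASH1-WT       100.0 % +/-  0.7  (n=5)
dBAH           51.2 % +/-  1.0  (n=5)
dBAH-mutAT1    12.7 % +/-  0.4  (n=5)
```

The recovered percentages track the planted bound-fraction ratios (0.4/0.8 =
50%, 0.1/0.8 = 12.5%) within the per-line noise.

An FCS fit on one synthetic nucleus (five 3%-noise measurements, one planted
outlier, true *k\*<sub>on</sub>* = *k<sub>off</sub>* = 2 /s):

```python
from mitoquant.fcs_kinetics import ObservationVolume, average_curves, fit_kinetics, screen_outliers
from mitoquant.simulate.fcs import FcsSimParams, generate_acf_dataset

curves, _ = generate_acf_dataset(FcsSimParams(
    n_mean=10, Df=20, kstar_on=2.0, koff=2.0, n_curves=5,
    noise_sd=0.03, outlier_rate=0.2, seed=42))
kept, _ = screen_outliers(curves)
fit = fit_kinetics(average_curves(kept), "full_model", ObservationVolume(0.2, 5.0))
print(f"bound fraction = {fit.bound_fraction:.2f}   residence time = {fit.residence_time:.2f} s")
```

```
bound fraction = 0.52   residence time = 0.49 s
```

(true values 0.50 and 0.50 s).

Every stage is also exposed as a CLI subcommand (`mitoquant simulate-embryo`,
`quantify-mitotic`, `simulate-fcs`, `fit-fcs`, `calibrate-volume`,
`compare-groups`, `simulate-counts`, `rnaseq-categorize`, `simulate-cross`,
`rescue-score`, `bristle-test`, `run`).

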