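# sephkit

Quantitative analysis of bacterial cell division in filamentous
actinobacteria, built around three measurements that recur in studies of
FtsZ and its regulators:

1. **Z-ring dynamics** from time-lapse fluorescence microscopy of
   sporulating hyphae — kymographs along the hyphal midline, multi-Otsu
   background correction, detection of ladder-like Z-rings on the
   time-averaged intensity profile (amplitude filter at 100), ring widths
   as full width at half maximum (FWHM), per-ring ROI intensity traces,
   and spore-length statistics.
2. **ChIP-seq local enrichment** for DNA-binding division proteins — from
   per-base `samtools depth` tables, the enrichment in each 30 nt window
   (step 15 nt) relative to a 3000 nt background window centred on the
   same midpoint; Spearman replicate gating (ρ > 0.95), control-strain
   subtraction, and normal-theory significance of the subtracted values.
3. **FtsZ polymerization kinetics** — GTP turnover rates from
   malachite-green phosphate-release curves (linear-range fit through a
   Pi standard curve), the critical concentration Cc as the x-intercept of
   GTPase rate versus FtsZ concentration, co-sedimentation pellet
   fractions `100·P/(S+P)`, and cellular molar ratios from quantitative
   immunoblot calibration curves.

A synthetic-data module (`sephkit.synth`) generates inputs with planted
ground truth for every stage — Gaussian rings with linear
assembly/disassembly lifecycles, negative-binomial coverage with planted
enrichment regions, linear Pi-release series — so the whole pipeline is
testable end to end without any downloads.

## The core statistics

**Windowed enrichment.** For window start *s* on a contig of per-base
depths *d*:

    ratio(s) = mean(d[s : s+30]) / mean(d[c−1500 : c+1500]),  c = s + 15

with the background interval truncated at contig ends and the ratio
undefined where the background mean is zero. Replicate tracks are averaged
after the Spearman gate, the control track subtracted, and each difference
*x* scored as `z = (x − mean) / sd` against the track-wide moments with an
upper-tail normal *p*-value.

**FWHM ring width.** For a detected peak, the baseline is the mean of the
two flanking minima; the width is the distance between the two
half-maximum crossings (linear interpolation between samples) times the
pixel size. For a Gaussian profile of SD σ this converges to
`2·sqrt(2·ln 2)·σ ≈ 2.355 σ`.

**Critical concentration.** Ordinary least squares of rate on
concentration; `Cc = −intercept/slope`, with a 95% CI by delta-method
propagation of the coefficient covariance (t critical value, n−2 df).

## Worked example

```python
import numpy as np
from sephkit import chip, synth, zring
from sephkit.kinetics import critical_concentration, fit_standard, gtpase_rate

# ChIP: 20 kb contig, one 500 bp region enriched 8-fold, 3 replicates
truth = synth.CoverageTruth(contig_length=20_000, baseline_mean=50.0,
                            dispersion=5.0, regions=((10_000, 10_500, 8.0),),
                            n_replicates=3, seed=1)
reps, control, _ = synth.gen_coverage(truth)
enr = [chip.window_enrichment(r) for r in reps]
diff = chip.mean_and_subtract(enr, chip.window_enrichment(control))
sig = chip.significance(diff)
i = np.nanargmax(sig.z)
print(f"top window center: {sig.positions[i]} bp  z = {sig.z[i]:.2f}")

# imaging: one ring at 10 µm, peak amplitude 400, σ = 0.15 µm
ring = synth.RingTruth(position=10.0, t_assemble=0, t_peak=60,
                       t_disassemble=480, peak_amplitude=400, sigma=0.15)
tl = synth.TimeLapseTruth(rings=(ring,), background_level=50, noise_sd=10)
stack, _ = synth.gen_timelapse(tl, seed=1)
profile = zring.background_correct(stack).mean(axis=0)
(det,) = zring.detect_rings(profile, min_intensity=100, pixel_size=0.1)
det = zring.ring_width(profile, det, pixel_size=0.1)
print(f"ring at {det.position:.2f} um, FWHM {det.fwhm:.3f} um")

# kinetics: 3.5 µM enzyme turning over 1.12 GTP/enzyme/min
kt = synth.KineticsTruth(rate_per_enzyme=1.12, enzyme_conc=3.5, noise_sd=0.1)
series, standards, _ = synth.gen_kinetics(kt, seed=1)
curve = fit_standard(standards[["pi_uM", "absorbance"]].to_numpy())
print(f"GTPase rate: {gtpase_rate(series, curve).rate:.3f} GTP/enzyme/min")

conc = np.array([2.0, 2.5, 3.5, 4.5])
cc = critical_concentration(np.column_stack([conc, 1.9 * (conc - 1.43)]))
print(f"critical concentration: {cc.cc:.2f} uM")
```

prints

```
top window center: 10110 bp  z = 6.33
ring at 10.00 um, FWHM 0.296 um
GTPase rate: 1.120 GTP/enzyme/min
critical concentration: 1.43 uM
```

The top-scoring window falls inside the planted 10 000–10 500 bp region;
the ring is recovered at its planted position (the FWHM is slightly below
the ideal 2.355·σ = 0.353 µm because background correction clips the
Gaussian flanks — see `docs/methods.md`); the noiseless-limit kinetics
recover the generating rate and x-intercept exactly.

A command-line interface mirrors the library:

```sh
sephkit simulate coverage --seed 1 --out cov --length 20000 --region 10000:10500:8
sephkit chip enrich cov.rep1.depth.tsv --contig-length 20000 --out rep1.bedgraph
sephkit kinetics pellet -s 0.65 -p 0.35   # -> 35.0
```

## Reproducibility script

`scripts/acceptance.py` re-runs the three pipeline stages from scratch on
seeded synthetic data — coverage simulation through enrichment and
significance, time-lapse simulation through ring detection and FWHM, and
kinetics through rate and Cc estimation — printing a stage summary and
writing its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/sephkit/synth.py` — ground-truth generators
- `src/sephkit/zring.py` — kymographs, ring detection, FWHM, spore stats
- `src/sephkit/chip.py` — windowed enrichment, gating, significance, bedgraph
- `src/sephkit/kinetics.py` — rates, Cc, pellet fractions, molar ratios
- `src/sephkit/{io,config,cli}.py` — formats, run configuration, CLI
- `docs/methods.md` — models, conventions, numerical choices, limitations
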