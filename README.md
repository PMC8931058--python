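# silencescope

Single-molecule image quantification of miRNA-mediated gene silencing.

miRNAs silence their target mRNAs through RISC (an Argonaute protein loaded
with the miRNA) in three steps — RISC binding, translational repression, and
mRNA decay. In single-cell imaging experiments these steps are resolved one
mRNA at a time: smFISH marks each reporter mRNA as a diffraction-limited
spot, SunTag immunofluorescence marks nascent peptides (translation), and
AGO immunofluorescence marks RISC. `silencescope` is the analysis stack for
such experiments: 3D spot detection with sub-pixel Gaussian localization,
drift-corrected multichannel colocalization, four-class mRNA classification,
per-cell silencing metrics, and the rank-based statistics used to compare
conditions and pulse-chase time points. A ground-truthed synthetic-microscopy
generator emulates the underlying biology so the entire pipeline is testable
end to end.

It is aimed at quantitative RNA biologists and microscopy analysts who need
a scriptable, reproducible alternative to GUI tool chains for
smFISH/SINAPS/IF-FISH colocalization experiments.

## The quantities computed

With `M` counting spots and `I` summing integrated spot intensities in cell
*k* (cyto = cytoplasmic, coloc = colocalized with an mRNA):

- mRNA stability S(k) = M_Sun,cyto / M_Fluc,cyto (Fluc mRNAs are the
  internal control transcribed from the same bidirectional promoter)
- translational efficiency T_eff(k) = I_Sun,coloc,cyto / M_Sun,cyto
- translated fraction T_fra(k) = M_Sun,coloc,cyto / M_Sun,cyto
- RISC-binding efficiency A_eff(k) = I_AGO,coloc,cyto / M_Sun,cyto
- RISC-positive fraction A_fra(k) = M_AGO,coloc,cyto / M_Sun,cyto
- export efficiency E(k) = M_Sun,cyto / M_Sun,nuc
- ribosomes per translated mRNA R = i_Sun,coloc / median(i_Sun,free) —
  the median free-peptide intensity is the one-peptide calibration unit

Bulk versions pool cells as a **ratio of sums** (ΣM_Sun,cyto / ΣM_Fluc,cyto
etc.), which differs from the mean of per-cell ratios whenever denominators
vary. An mRNA is *translated* if a SunTag spot lies within 500 nm in 3D
after inter-channel drift correction, and *RISC-positive* if an AGO spot
lies within 250 nm; the tighter AGO gate limits chance coincidences with
the ~2000 free AGO spots per cell. Each mRNA lands in one of four classes:
RISC∓ × untranslated/translated.

## Worked example

Simulate and analyze a two-time-point pulse-chase of the triple-labeled
reporter (mRNA + SunTag + AGO), 50 cells per condition, +miR-21 vs a
seed-mutant control:

```python
import silencescope as ss

spec = ss.ExperimentSpec(design="triple", time_points_min=(0.0, 30.0),
                         n_cells_per_condition=50, seed=1)
bundle = ss.run_experiment(spec)

pc = bundle["per_cell"]
print(pc.groupby(["condition", "time_min"])[["T_eff", "T_fra", "A_eff", "A_fra"]]
        .median().round(3))
print(bundle["stats_mw"][["time_min", "metric", "tail", "p", "band"]]
        .to_string(index=False))
```

Output:

```
                    T_eff  T_fra  A_eff  A_fra
condition time_min
miR21     0.0       5.217  0.712  0.588  0.584
          30.0      2.783  0.462  0.605  0.571
mutant    0.0       5.861  0.707  0.146  0.133
          30.0      5.612  0.692  0.126  0.120

 time_min metric    tail            p band
      0.0  T_eff    less 5.006992e-02 n.s.
      0.0  T_fra    less 5.494213e-01 n.s.
      0.0  A_eff greater 4.749783e-16  ***
      0.0  A_fra greater 1.337037e-16  ***
     30.0  T_eff    less 8.073573e-16  ***
     30.0  T_fra    less 7.207416e-14  ***
     30.0  A_eff greater 6.104477e-18  ***
     30.0  A_fra greater 5.051528e-18  ***
```

Reading the numbers: immediately after the transcription pulse (0 min),
+miR-21 cells already show ~4.5× the control's RISC-binding efficiency
(A_eff 0.59 vs 0.15, one-tailed Mann–Whitney ***), while translation is
indistinguishable between conditions (T_eff n.s.) — RISC binds newly
exported mRNAs before repressing them. By 30 min, translational efficiency
in +miR-21 cells has halved (2.8 vs 5.6, ***). The mutant's ~13%
RISC-positive baseline is chance colocalization with free AGO spots under
the 250 nm gate. The same machinery runs `design="decay"` (stability S via
the Fluc internal control; decay appears only at 60 min) and
`mode="images"`, which renders 3D stacks and re-detects spots instead of
using the generator's spot tables.

A CLI wraps the same stages:

```bash
silencescope simulate --out run/ --mode spots --seed 9
silencescope colocalize --in run/ --suntag-gate 500 --ago-gate 250
silencescope scan-sites --utr utr.fa --mirnas top30.fa --audit
```

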