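# memtrap

Analysis pipeline for **membrane-trapped amyloid aggregation
intermediates** studied by nanodisc NMR — built around the human islet
amyloid polypeptide (hIAPP, amylin; `KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY`),
the 37-residue peptide whose membrane-assisted aggregation is linked to
type-2 diabetes. When hIAPP is incubated with lipid nanodiscs, a folded,
non-fibrillar intermediate can be trapped on the bilayer surface; this
package implements the computational side of characterizing such an
intermediate, for structural-biology and biophysics groups running the
same four experiment types:

1. **ThT aggregation kinetics** (`tht_kinetics`) — normalize plate-reader
   fluorescence traces, fit the four-parameter logistic
   `F(t) = F∞ + (F₀ − F∞) / (1 + e^{k(t − t₅₀)})`,
   extract the lag time by the tangent construction
   `t_lag = t₅₀ − 2/k`,
   and summarize fold changes in lag time across nanodisc conditions,
   with censoring for wells where fibrillation is never observed.
2. **Secondary chemical shifts** (`chemshift_ss`) — per-residue
   Δδ = δ_obs − δ_rc for ¹³Cα/¹³Cβ, the Δδ(Cα)−Δδ(Cβ) difference
   (positive in helix, negative in strand), a windowed SSP-style
   propensity score in [−1, 1], and strand/helix segment calls.
3. **Three-probe topology mapping** (`probe_topology`) — per-residue
   signal reductions `r_i = 1 − I_probe/I_ref` from HMQC intensities for
   nanodisc binding, Gd(III) solvent PRE and 5-DSA lipid-probe
   titrations; residues reduced more than the sample average count as
   affected, and the consensus rule (membrane evidence from ND/5-DSA,
   solvent evidence from Gd) labels each residue membrane / solvent /
   ambiguous / unclassified.
4. **SASA membrane orientation** (`sasa_orientation`) — Shrake–Rupley
   style quadrature SASA with deterministic golden-spiral point sets; the
   lipid-accessible area of each residue is SASA(peptide alone) −
   SASA(peptide in the membrane system), computed with coarse-grained
   radii enlarged by 0.21 nm; residues are labeled by environment
   preference and compared against the NMR topology call via an overlap
   coefficient.

A synthetic-data generator (`synthetic_data`) emulates all four input
kinds with known ground truth, so the entire pipeline is testable
without any experimental downloads. See `docs/methods.md` for the models,
parameter choices and limitations.

## Worked example

Run the whole pipeline on synthetic study-condition data:

```sh
memtrap run --config run.yaml
```

with `run.yaml`:

```yaml
seed: 2017
outdir: results
stages: {simulate: true, tht: true, ss: true, topology: true,
         sasa: true, agreement: true}
```

or step by step via the numbered drivers:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fit_tht_kinetics.py
python analysis/03_secondary_structure.py
python analysis/04_probe_topology.py
python analysis/05_sasa_orientation.py
```

which prints (seed 2017):

```
nanodisc_id  nanodisc_equiv  ...  mean_t_lag_min  sd_t_lag_min  fold_change fold_change_bound
        ND1               1 ...       648.95554      3.687003     3.264817               NaN
        ND1              10 ...             NaN           NaN          NaN         > 14.4889
       none               0 ...       198.77240      0.993892     1.000000               NaN

  strand residues 8-12
  strand residues 15-18
  strand residues 26-29

membrane-facing residues: [6, 11, 12, 13, 17, 18]
solvent-facing residues:  [19, 22, 23, 25, 26, 30, 31, 33, 34, 35, 36, 37]

lipid-preferring residues: [11, 12, 13, 14, 15, 16, 17, 18, 19]
overlap coefficient: 0.833
```

Reading the numbers: untreated peptide has a lag time of ~199 min; one
equivalent of the 90:10 PC/PG nanodisc slows aggregation 3.3-fold, and
ten equivalents block fibrillation entirely within the 48 h run (lag
reported only as a lower bound, > 14.5-fold). The chemical shifts
recover the three-strand architecture of the trapped intermediate, the
probe titrations assign the first two strands (plus T6/A13) to the
membrane face and the second loop/C-terminus to solvent, and the SASA
difference on the coarse-grained geometry marks residues 11–19 as
lipid-contacting — overlapping the NMR membrane set with coefficient
0.83 (5 of the 6 NMR membrane residues are also lipid-preferring by
SASA; T6 sits in the flexible N-terminus).

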