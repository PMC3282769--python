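# ptcsig

Sequence signatures, enzyme kinetics and structural metrics for
discriminating **putrescine transcarbamylase (PTC)** from **ornithine
transcarbamylase (OTC)**.

PTC and OTC both transfer a carbamyl group from carbamylphosphate (CP)
to an amine (putrescine or L-ornithine) and are so similar in sequence
and structure that PTC genes were long misannotated as OTCs. The two
enzymes do, however, differ in a handful of structure-backed sequence
traits, and those traits are decisive: swapping a single four-residue
loop converts the substrate preference, and a PTC-exclusive C-terminal
helix stabilizes the trimer. `ptcsig` packages those traits as an
annotation tool for anyone curating carbamoyltransferase sequences, plus
the quantitative methods used to characterize the enzymes: hyperbolic
kinetics fitting, equilibrium/inhibition analysis, and a small
structural geometry kernel.

## The classification rules

A candidate sequence is anchored to the family by the invariant
active-site tetrapeptides **STRT** (CP binding; position 52 in
*Enterococcus faecalis* PTC) and **HCLP** (amine binding; position 268),
searched as a pair with family-consistent spacing (190–240 residues).
Four traits then discriminate PTC from OTC:

| rule | PTC state | OTC state |
|---|---|---|
| `lysine_upstream` | non-lysine (e.g. Q) two residues before STRT | K two residues before STRT |
| `loop230` | `(Y/W)(G/W)(V/L/I)X` ~40 residues before HCLP | `xSMG` in the same window |
| `cterm_extension` | ≥ 60 residues past HCLP | ≤ 55 residues past HCLP |
| `helix13` | `(L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m)` in a helix-favoring C-terminal context | absent |

Motif notation: capitals are predominant residues, lower case marks
lower-frequency alternatives, `X` matches anything. A sequence is called
**PTC** only when all five rules (anchors + four traits) agree; **OTC**
when the three OTC-discriminant rules agree; otherwise it is reported as
an unclassified transcarbamylase (or not a transcarbamylase at all, when
the anchors are missing). Every verdict carries per-rule evidence.

## The quantitative methods

* **Saturation kinetics** — nonlinear least-squares fit of
  v = V<sub>max</sub>·S/(K<sub>m</sub>+S) (rates in U/mg, 1 U = 1 µmol
  product·min⁻¹; concentrations in mM), with catalytic efficiency
  V<sub>max</sub>/K<sub>m</sub> in U mg⁻¹ mM⁻¹.
* **Inhibition curves** — percent activity = 100/(1 + ([I]/IC₅₀)^h),
  with the Hill slope free or pinned.
* **Equilibrium** — for A + B ⇌ C + D with K<sub>eq</sub> =
  [C][D]/([A][B]), the closed-form conversion fraction of the limiting
  substrate.
* **Structural geometry** — PDB parsing (via gemmi), Kabsch
  superposition RMSD, Shrake–Rupley solvent-accessible surface area
  (probe 1.4 Å, deterministic spiral quadrature), interface burial, and
  metal coordination analysis (e.g. the octahedral Ni site on the PTC
  trimer threefold axis).
* **Synthetic fixtures** — seeded generators of PTC-like and OTC-like
  sequences with every trait implanted at the *E. faecalis* layout, and
  single-trait ablations (including the YGLY→VSMG loop swap and the
  stop-codon-style C-terminal truncation).

## Worked example

```bash
python examples/fit_kinetics.py
```

```
wild type / putrescine     Vmax =   813.00 U/mg   Km =   1.41 mM   Vmax/Km = 577.0 U mg^-1 mM^-1
engineered / ornithine     Vmax =    82.00 U/mg   Km =  32.00 mM   Vmax/Km = 2.6 U mg^-1 mM^-1
engineered / putrescine    Vmax =     1.13 U/mg   Km =  32.90 mM   Vmax/Km = 0.03 U mg^-1 mM^-1
```

Fitting noise-free saturation curves generated at the wild-type and
loop-swapped ("engineered") enzyme parameters recovers the generating
values exactly; the efficiencies show the 230-loop swap cutting
putrescine efficiency from 577 to 0.03 U mg⁻¹ mM⁻¹ while raising
ornithine efficiency to 2.6 — the loop controls which amine the enzyme
prefers.

```bash
python examples/classify_sequences.py
```

```
ptc_like_seed1: PTC (score 5/5)
    anchors          ptc_like   STRT/HCLP pair found (shared by PTC and OTC)
    lysine_upstream  ptc_like   Q at STRT-2
    loop230          ptc_like   PTC 230-loop pattern, no xSMG
    cterm_extension  ptc_like   tail 69 >= 60
    helix13          ptc_like   signature LAAFL at 312, propensity 1.32
...
ptc_like_seed1_ablate_loop230: TRANSCARBAMYLASE_UNCLASSIFIED (score 4/5)
```

The loop-swapped sequence stays family-positive but loses the PTC
verdict through exactly one rule — mirroring the engineered enzyme whose
substrate preference inverted.

There is also a CLI for shell use:

```bash
ptcsig generate --class ptc --n 50 --seed 1 --out fixtures.fasta
ptcsig classify --in fixtures.fasta --out report.tsv --json report.json
ptcsig fit-kinetics --model mm --in saturation.tsv
ptcsig struct interface --pdb trimer.pdb --sel-a A:320-337 --sel-b B:1-319
```

## Layout

```
src/ptcsig/
  seq_core.py              sequence records, FASTA I/O, global alignment
  motif_engine.py          degenerate-motif notation parser and scanner
  helix_propensity.py      Chou-Fasman window-averaged helix scoring
  signature_classifier.py  the five rules and the verdict policy
  synthetic_sequences.py   seeded PTC/OTC fixture generators and ablations
  kinetics.py              hyperbolic fits, efficiency, inhibition, equilibrium
  struct_metrics.py        PDB parsing, Kabsch RMSD, SASA, burial, metal sites
  cli.py                   ptcsig classify | generate | fit-kinetics | struct
examples/                  runnable narrative scripts, one per capability
docs/methods.md            models, parameter choices and limitations
```
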