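# cglrkit

Analysis toolkit for discovery screens of **cGAS-like receptors (cGLRs)**
— the animal pattern-recognition enzymes that sense pathogen-associated
molecular patterns (dsDNA, dsRNA, and likely others) and answer by
synthesizing a cyclic dinucleotide (CDN) second messenger that activates
STING. It is written for computational biologists reproducing or extending
the desk-scale analysis behind such screens: curating candidate enzymes
from proteomes, predicting ligand class from charge, identifying an
unknown CDN product from orthogonal biochemical readouts, and quantifying
STING binding.

## What it computes

* **Motif curation** (`cglrkit.motif`) — a parser and exhaustive scanner
  for the degenerate active-site grammar
  `h[QT]GS [X8-20] [DE]h [DE]h [X50-90] h[DE]h` (plus the `G[S/G]`
  activation loop and `[E/D]h[E/D] X50-90 [E/D]` catalytic triad), the
  three-criterion retention rule with externally supplied homology flags,
  and greedy centroid redundancy removal at identity ≥ 0.95, coverage = 1.
* **Isoelectric point** (`cglrkit.physchem`) — Henderson–Hasselbalch net
  charge Z(pH), pI by bisection on [0, 14], and the pI > 8.5
  nucleic-acid-sensor-like / pI < 7 acidic classification.
* **CDN chemistry** (`cglrkit.cdn`) — the 36-molecule candidate space over
  {A, C, G, U} with 2′/3′ linkage donors, free-acid formulas
  (NMP + NMP − 2 H2O), average/monoisotopic masses, and ESI adduct m/z.
* **Screen inference** (`cglrkit.screen`) — predicts the radiolabel / CIP /
  nuclease-P1 / mass signature of any candidate and inverts partial
  observations to the set of consistent products, with a
  distinguishability report for assay design.
* **Binding fits** (`cglrkit.binding`) — single-site isotherm
  f(c) = c/(c + Kd) fit to EMSA fraction-bound titrations by deterministic
  log-scale least squares.
* **Census** (`cglrkit.census`) — per-species cGLR/STING copy-number
  tables and domain-architecture prevalence with the < 0.5 % → "Other"
  folding rule.
* **Synthetic data** (`cglrkit.synth`) — seeded generators with recorded
  ground truth for every stage (planted-motif proteomes, screen
  observations, noisy binding curves, census tables).

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Identify the product of a uridine+adenosine-labeling enzyme whose product
resists CIP, loses the uridine label but keeps the adenosine label after
nuclease P1 + CIP, and shows m/z 634.07 in negative mode:

```python
import cglrkit as ck

obs = ck.ScreenObservation(
    labels_incorporated=frozenset("AU"),
    cip_resistant=True,
    p1_retention={"A": "retained", "U": "lost"},
    observed_mz=[(634.07, "[M-H]-")],
)
print(ck.infer_product(obs).names)
```

```
['2′3′-cUA']
```

— the mixed-linkage 2′–5′/3′–5′ cyclic UMP–AMP, c[U(2′,5′)pA(3′,5′)p]:
the protected 2′–5′ bond carries the adenosine α-phosphate, which is
exactly why the A label survives digestion. Its chemistry:

```python
cua = ck.parse_name("2'3'-cUA")
formula = ck.formula_of(cua)
avg, mono = ck.masses(formula)
print(formula, round(avg, 2), round(mono, 3))
print(ck.nominal_mz(ck.adduct_mz(mono, "[M-H]-")),
      ck.nominal_mz(ck.adduct_mz(mono, "[M-2H+Na]-")))
```

```
C19H23N7O14P2 635.38 635.078
634 656
```

Scan a synthetic proteome for the active-site motif and fit a noisy
binding curve:

```python
from cglrkit.synth import gen_motif_proteome, gen_binding_curve

pattern = ck.load_default_patterns()["active_site"]
proteome = gen_motif_proteome(n_pos=2, n_neg=1, pattern=pattern, seed=7)
hit = ck.scan(proteome[0].sequence, pattern, mode="first")[0]
print(hit.full_span)              # -> (195, 281)

fit = ck.fit_isotherm(gen_binding_curve(Kd=1e-6, noise_sd=0.05, seed=1))
print(f"{fit.Kd:.2g} M")          # -> 9.2e-07 M
```

The planted motif spans residues 195–281 of the first positive, and the
fitted dissociation constant recovers the simulated 1 µM Kd to within the
noise. A `cglrkit` console script exposes the same operations
(`cglrkit scan`, `curate`, `dedupe`, `pi`, `cdn`, `infer-product`,
`fit-emsa`, `census`, `simulate`); run `cglrkit --help`.

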