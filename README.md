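# pahmix

Competitive metabolism of polycyclic aromatic hydrocarbons (PAHs), from
microsomal assay to internal dose.

Humans are exposed to PAHs as mixtures, and the cytochrome-P450 enzymes
that bioactivate or detoxify them are shared between mixture components —
so one PAH can competitively inhibit another's metabolism. `pahmix`
implements the full quantitative chain needed to ask when that matters:

1. **Kinetics** (`pahmix.kinetics`) — initial metabolism rates from
   substrate-depletion time courses (exponential regression, nonparametric
   bootstrap CIs), and baseline rate-law fitting with BIC selection among

   - Michaelis–Menten: v = Vmax·S/(Km+S)
   - Michaelis–Menten + linear clearance: v = Vmax₁·S/(Km₁+S) + Clint₂·S
   - double Michaelis–Menten: v = Vmax₁·S/(Km₁+S) + Vmax₂·S/(Km₂+S)

   fitted by Gaussian maximum likelihood (≡ least squares with profiled σ),
   with parametric-bootstrap parameter CIs and Clint₁ = Vmax₁/Km₁.
2. **Inhibition** (`pahmix.inhibition`) — apparent competitive inhibition
   constants Ki (µM), placing the inhibitor against either the
   high-affinity phase (Km₁ → Km₁·(1+I/Ki)) or the linear-clearance phase
   (Clint₂ → Clint₂/(1+I/Ki)), selected by BIC; defined mixtures
   (Supermix-10, the ten most abundant Portland Harbor PAHs) are handled as
   lumped inhibitors.
3. **PBPK interaction** (`pahmix.pbpk`) — a two-compound flow-limited
   whole-body model (gut, liver, fat, richly/slowly perfused, blood) with
   mutual competitive inhibition of hepatic metabolism, scaled from
   microsomal parameters via 30 mg microsomal protein per g liver. The
   interaction metric is the per-compound ratio of blood-concentration
   AUCs with inhibition on vs. off, over a 16×16 oral dose grid
   (0.1 ng … 100 kg).

A seeded synthetic-assay generator (`pahmix.synth`) emulates the depletion
assays so every stage is testable without raw laboratory data, and
`pahmix.pipeline`/the CLI orchestrate the whole chain reproducibly. The
shipped defaults are the fitted human-liver-microsome parameters for
benzo[a]pyrene (BaP) and dibenzo[def,p]chrysene (DBC) and a 73 kg reference
human (see `docs/methods.md` for every default and its rationale).

## Worked example

Run the end-to-end demo (synthetic assays → rates → fits → Ki → PBPK grid):

```bash
pahmix run-all --outdir out --seed 20220706
```

which logs

```
INFO stage fits: BaP selected MM (BIC -133.28)
INFO stage fits: DBC selected MM (BIC -155.61)
INFO stage ki: BaP inhibited by DBC → Ki 0.343 µM (PHASE1)
INFO stage ki: DBC inhibited by BaP → Ki 0.0937 µM (PHASE1)
```

and writes `out/report.json` containing, among other things

```json
"example_auc_ratio_1pmol": {"BaP": 1.0000000048, "DBC": 1.0000000072},
"grid_max_ratio":          {"BaP": 52.5,         "DBC": 9.8}
```

Reading the numbers: the generating Ki values are 0.44 µM (DBC inhibiting
BaP) and 0.061 µM (BaP inhibiting DBC), and both placements were correctly
identified as phase-1 competition; the point estimates (0.343, 0.094 µM)
are biased because the demo keeps the realistic 30/60-minute assay windows,
where exponential regression systematically underestimates initial rates
on strongly depleting courses — the same reason BIC here prefers the plain
MM form (`docs/methods.md`, §1, discusses this estimator bias; the
rate-level selection studies in the test suite recover the generating
model in ≥90% of seeds). At trace oral doses (1 pmol of each compound) the
AUC ratios are 1 to eight decimal places — co-exposure does not alter
internal dose — while the grid maxima show that interaction emerges only
at doses in the 100 mg–1 g range, orders of magnitude above typical human
exposure. This is the package's headline scientific conclusion: competitive
metabolism of these PAHs is real but irrelevant at environmental doses,
consistent with the additivity assumption of the Relative Potency Factor
approach.

Single pieces are available as subcommands (`pahmix synth`,
`pahmix fit-kinetics`, `pahmix fit-inhibition`, `pahmix pbpk-simulate`,
`pahmix pbpk-grid`) or directly as library calls:

```python
from pahmix import (InhibitionPlacement, default_compounds,
                    default_physiology, auc_ratio, percent_inhibition)
from pahmix.refdata import MICROSOMAL_BASELINE

bap = MICROSOMAL_BASELINE["BaP"]
percent_inhibition(bap, InhibitionPlacement.PHASE1, S=0.14, I=1.0, ki=0.44)
# 0.448 — 1 µM DBC cuts BaP metabolism nearly in half in vitro

auc_ratio((0.25, 1e8), default_physiology(), default_compounds()).ratios
# {'BaP': 3.27, 'DBC': 1.00} — a 100 mg DBC dose triples the BaP blood AUC
```

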