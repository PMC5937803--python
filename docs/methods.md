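# Methods

## The model

`steroflow` executes mEPN pathway diagrams as stochastic signalling Petri
nets (SPNs): a qualitative dynamic formalism in which "signal" is read as the
accumulation of abstract tokens at nodes over discrete time blocks, with no
kinetic rate constants. Biochemical and protein nodes become token-holding
*places*; each process node becomes a *transition* whose inputs are its
entity predecessors and whose outputs are its entity successors; a direct
entity-to-entity edge — the notation's shorthand for an uncharacterised
event between two established molecules — becomes an implicit single-input/
single-output transition. Token-input nodes and annotation nodes (legends,
tissue boxes, unknown shapes) are excluded from the net; token inputs act
only through their injection schedules, and annotations are inert by
construction, so decorative diagram elements can never perturb dynamics.

### Firing semantics

SPN engines differ in how they schedule firing. `steroflow` uses synchronous
per-block semantics, chosen because they are order-independent, admit an
exact closed-form oracle on acyclic nets, and produce the one-transition-
per-block wave-front propagation seen in token-flow animations:

1. **Injection.** Every scheduled place `p` receives
   `max(0, c_p(t) · (1 + σ·z))` tokens, `z ~ N(0,1)` i.i.d. per place, block
   and run. Multiplicative noise on injections keeps the expected input
   equal to the scheduled activity (the clamp at zero is immaterial for
   σ ≲ 0.3) and makes σ = 0 an exact deterministic limit. Calibration was
   verified empirically: across replicate seeds, the z-statistic of the
   simulated mean against the noise-free trace is standard normal.
2. **Demand.** Each transition demands the minimum of its input places'
   post-injection tokens (an AND over prerequisites: a reaction cannot run
   beyond its scarcest substrate or its available enzyme).
3. **Proportional sharing.** If the summed demand on a place exceeds its
   tokens, every demand drawing on that place is scaled by the same factor
   (`tokens/load`); a transition's realised flux is its demand times the
   smallest scale factor among its inputs. This resolves competition for a
   shared substrate or a shared enzyme proportionally and guarantees
   non-negativity.
4. **Simultaneous application.** Consumptive transitions (the default)
   subtract the realised flux from *every* input place — catalysts included
   — and add it to every output place. A non-consumptive mode (inputs read
   but never consumed) is available as a sensitivity flag.

Tokens are non-negative reals, not integers: scheduled amounts are measured
enzyme activities (pmol/minute/million cells) and no rounding rule is
imposed.

Two consequences of consumptive semantics are worth stating explicitly:

* **Conservation.** A single-input/single-output transition moves tokens
  without creating or destroying them, so on nets of implicit transitions
  total resident tokens equal total injected-to-date exactly. A multi-input
  transition consumes the flux from *each* input while adding it once to
  each output, so enzyme tokens are genuinely spent — global token count is
  not conserved in enzyme-gated nets, by design.
* **Capacity carry-over.** An enzyme place injected faster than its
  transition fires accumulates unspent tokens, which remain available in
  later blocks. A per-block activity is therefore a replenishment rate, not
  a hard per-block ceiling; stage-level behaviour depends on cumulative
  enzyme supply as much as on instantaneous rates. This matters for the
  Leydig-cell crossover (below).

### Randomness and reproducibility

One master seed; each replicate run draws its noise from an independent
substream (`numpy` `SeedSequence.spawn`), so traces are bit-identical across
invocations and independent of run batching. All floating-point
accumulations walk the net's transitions in a fixed order, making the
deterministic limit bit-reproducible as well; the CLI writes a JSON manifest
(config, schedules, digest) from which re-runs reproduce summary CSVs
byte-for-byte.

## The curated models

The **human framework** covers the canonical reactions from cholesterol to
the five steroid classes (progestogens, corticosteroids, mineralocorticoids,
androgens, estrogens) following the standard endocrinology reviews; each
enzyme isoform is represented by a gene node (Ensembl URL metadata) and a
protein node per reaction site, each steroid by a hexagon node with
Chemspider URL metadata, and every reaction carries a citation string, so
the graph doubles as a visual bibliography. Tissue tags (adrenal
reticularis/glomerulosa/fasciculata, testis, ovary, prostate, placenta)
drive `tissue_subgraph` extraction. URL metadata are deterministic search
links; the package never performs web access.

The **rat Leydig-cell model** is androgen-focused and uses one protein node
per enzyme (CYP11A1, HSD3B, CYP17A1, HSD17B, SRD5A, AKR1C — aggregate
rodent symbols, no gene nodes): cholesterol → pregnenolone → progesterone →
17OH-progesterone → androstenedione; androstenedione → testosterone and
androstanedione → DHT (both HSD17B); androstenedione → androstanedione and
testosterone → DHT (both SRD5A); DHT → 3α-diol (AKR1C, terminal sink).
Because one protein node serves several reactions, CYP17A1 and HSD17B each
split their tokens between two competing transitions — an intended
consequence of the single-node convention.

`parameterize_leydig` maps a stage-activity table onto the three
developmental windows (blocks 1–20 progenitor, 21–50 immature, 51–100
adult), giving each enzyme the schedule `1-20,p;21-50,i;51-100,a`.
Cholesterol supply is a configurable constant schedule defaulting to twice
the table's largest activity: the premise of parameterising by enzyme
activity is that enzymes, not substrate, are rate-limiting. The Δ5 branch
(pregnenolone → 17OH-pregnenolone → DHEA) and backdoor/sulfation routes are
not part of the default rat model; they can be added as `ReactionTable`
rows.

## Synthetic data

### Fixtures and the independent oracle

`make_fixture` generates chains, branches, merges and random DAGs of
biochemical nodes connected by implicit transitions, with constant
injections at the sources, together with the noise-free expected trace
computed by `naive_expected_trace` — a deliberately plain, scalar,
dictionary-based recurrence that shares no code with the engine. On these
nets the expected behaviour is transparent (e.g. a 3-entity chain's sink
holds `a·(t−1)` tokens: injection is visible to flux within the same block,
then one block of lag per further transition; a 2-sink branch splits the
source equally), and the engine is required to match the oracle *exactly*
(bit-level, not approximately) at every place and block.

### Stand-in stage activities

The activity magnitudes of the cited rat Leydig developmental dataset are
not redistributable from this package, so `make_leydig_activities` draws
random tables that emulate the dataset's qualitative structure, with
magnitudes in the 0.5–50 pmol/min/million-cells decade span typical of
developmental enzyme panels. The maturational programme is encoded as
*ratio bounds* between (enzyme, stage) pairs:

* HSD17B rises sharply into adulthood (adult/immature fold 7–12) from a
  near-silent progenitor baseline (progenitor/immature 0.05–0.3);
* the androgen-inactivating activities dominate the immature cell
  (SRD5A/HSD17B 3–8, progenitor ≥ immature) and collapse in the adult
  (immature/adult fold 10–40 for SRD5A and AKR1C), with AKR1C supplied at
  0.6–1.0× immature HSD17B;
* the upstream cascade (CYP11A1, HSD3B, CYP17A1) is non-decreasing with
  maturation and carries capacity floors above the androstenedione-consuming
  activities (doubled for CYP17A1, which serves two sequential reactions),
  so substrate supply is never the bottleneck.

Plain stage *orderings* (HSD17B adult > immature, SRD5A immature > adult,
…) are not sufficient to fix the downstream steroid phenotype: under
consumptive semantics the 3α-diol sink integrates all HSD17B-mediated flux
during the immature stage, and unspent AKR1C tokens carried into adulthood
keep converting DHT, so without fold gaps and supply floors a table can
satisfy every ordering yet leave 3α-diol ahead of testosterone throughout
adulthood. The bounds above mirror the order-of-magnitude activity switches
reported for maturing rat Leydig cells and make the crossover a provable
consequence of the programme — which is the point of the test: every
constraint-satisfying table must reproduce it. Conversely,
`violate=True` swaps the immature and adult activities of the switch
enzymes (HSD17B, SRD5A, AKR1C) and demonstrably breaks the crossover, so
the property is not vacuously true of any table.

Generation solves the bounds as a difference-constraint system in log
space: the transitive closure (Floyd–Warshall) yields the tightest interval
for each variable given those already assigned; variables are sampled
log-uniformly inside their intervals, so any satisfiable constraint set is
sampled without rejection and infeasibility is detected exactly (a positive
cycle), reported with a conflicting pair of variables.

### What the synthetic data do not emulate

Fixtures are acyclic with constant injections; they exercise the firing
semantics, not biological realism. The activity tables reproduce the
*pattern* of the rat developmental data, not its numeric values; absolute
token counts in the Leydig simulations are therefore not predictions of
steroid concentrations, and only orderings and qualitative shapes (stage
dominance, knockout accumulation) carry meaning. Passing tests show the
engine is exact against its oracle and that the curated topology plus the
maturational programme entail the published qualitative phenotypes; they do
not validate rate-level agreement with any specific measured dataset.

## Numerical and design choices

* Variance across runs is the sample variance (ddof = 1): runs are i.i.d.
  replicates. A single run reports zero variance.
* Schedule notation accepts en-dash or hyphen-minus on input and emits
  hyphens; blocks not covered by a segment inject zero (which is also the
  knockout semantics — knockout removes a schedule rather than erroring on
  later look-ups). Inclusive bounds on both ends.
* Statistical consistency of noisy runs against the σ = 0 trace is asserted
  at the trace level (per-run time-averaged tokens per place, 3 standard
  errors from 500 replicates) plus the accumulating sink's final block: a
  per-cell 3-SE assertion across all ~10² places × blocks would be expected
  to fail by multiplicity for a perfectly calibrated engine.
* GraphML is emitted as plain GraphML with an explicit `kind` key alongside
  the shape mapping, so re-reading is never ambiguous; yEd's extension
  vocabulary is accepted on input. Node ids are authoritative; labels may
  repeat (enzymes duplicated per reaction site). Coordinates are metadata,
  never semantics.
* `SimulationConfig` defaults (100 blocks, 500 runs, σ = 0.1, consumptive)
  are the reference experiment; `steroflow simulate --model rat-leydig`
  with default flags runs it. Problem sizes in the test and acceptance
  batteries (100 fixtures × 40 blocks, 20 activity tables × 500 runs) keep
  the full verification suite in the seconds-to-minutes range on one CPU.

## Known limitations

* The firing semantics are a documented reconstruction of the SPN method:
  published engines may randomise transition firing order rather than
  injection amounts, so numeric agreement with any specific tool is not
  claimed — only the qualitative outputs are.
* No continuous-time or ODE semantics; "time block" is an abstract unit
  mapped to developmental stages only by convention.
* The human framework is a curated core, not an exhaustive reaction atlas
  (no fetal pathway, no placental isoform kinetics, no sulfation/backdoor
  routes by default).
* Tissue subgraphs are tag-driven: they reflect the curation, not an
  expression dataset.
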