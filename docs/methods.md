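# Methods

## The model

`moanet` implements an ensemble network-modelling approach to drug
mechanism of action (MoA).  The object of study is a directed
protein–protein interaction network over which a drug's
activation/inhibition signal propagates from its targets toward the
protein effectors of a disease.  The network is treated like a
multilayer perceptron laid over the graph: each link carries a weight
*w* ∈ [−1, 1], and a stimulus (drug targets clamped at +1 for
activation, −1 for inhibition) is propagated synchronously:

    x_v(t+1) = clip( Σ_{u→v} w_{uv} · x_u(t) , −1, +1 )

Clamped nodes hold their stimulus value at every step; proteins of the
*basal* disease motive start at their disease sign but update freely
(so a treatment can modulate the baseline state); all other nodes start
at 0.  The saturating-linear clamp was chosen over tanh because it is
odd, bounded, and yields exact rational values for hand-checkable
examples; the update is the synchronous recurrence reading of a
"perceptron over the graph", with a fixed depth (default 3 steps) that
covers the target→effector path lengths the planted mechanisms use.
Whether the original formulation layers the network by path length or
runs a recurrent scheme is not decidable from its public description;
the synchronous recurrence is one consistent reading and is flagged as
such.

## Training and the ensemble

The training data is a *truth table*: stimulus → expected-response
rules (drug targets vs the signed effectors of conditions they treat or
cause).  Because the rules are always far fewer than the link weights,
the trained model is a *population* of solutions rather than a single
optimum.  Each solution is found by simulated annealing:

* proposal — redraw one edge weight uniformly in [−1, 1], keeping the
  sign of edges whose activation/inhibition direction is known a
  priori;
* objective — the solution's accuracy: the fraction of rules complied
  with.  A rule is complied with when strictly more than a fraction
  *f* = 0.5 of its response proteins show the expected sign with
  magnitude ≥ ε = 0.1 (the per-rule predicate is a design choice; the
  magnitude threshold reuses the scoring threshold for consistency);
* acceptance — Metropolis with geometric cooling (T₀ = 0.05, factor
  0.998, 2000 iterations by default; chosen so the temperature decays
  to ~10⁻³ over one run, with T₀ of the order of one accuracy
  quantum at the default rule count).

Drug *bioflags* — proteins known to respond to a drug downstream
without being targets — are appended as extra response requirements to
that drug's rules and count in its compliance fraction.

Solutions with accuracy **strictly above 0.9** are retained, sampling
with derived seeds (attempt *k* uses `seed + k`) until the target of
**250** retained solutions is reached; the model's accuracy is the mean
over retained solutions.  Solutions are retained independently —
diversity comes from seed variation only.  One shared ensemble is
trained over the whole truth table (not per-drug models), matching the
reading that the final model's accuracy is the mean over all considered
solutions.

## Measures

With the ensemble-mean activity profile of a stimulus, each disease
motive (a set of effectors with disease signs ±1) is scored by:

* **reversed** effectors (#Eff): activity of opposite sign to the
  disease sign and |activity| ≥ 0.1 (boundary inclusive); activity
  exactly 0 is neither reversed nor anti-reversed;
* **anti-reversed** (#-Eff): pushed further in the disease direction at
  the same magnitude (named but not defined in the source description;
  defined here as the mirror of the reversal rule);
* **T-Signal**: mean over effectors of (−disease_sign × activity).
  The original T-Signal formula is unpublished (delegated to earlier
  method papers); this definition is odd, bounded in [−1, 1], and zero
  on null profiles — the minimal properties its usage requires;
* **W-Signal**: ((1 + #Eff)/(1 + #-Eff)) · (#Eff/BED_p) + T, where
  BED_p is the motive's effector count.  The typeset source equation is
  ambiguous; this grouping matches the stated pondering of correctly
  vs incorrectly moved effectors, reduces to T when nothing is
  reversed, and is isolated in a single function so it can be swapped.
  Per-motive BED_p is used when comparing drugs across motives.

A combination of two drugs is evaluated by clamping the union of both
target sets (conflicting signs on a shared target are an error) and is
called **synergistic** on a motive when its W-Signal strictly exceeds
both single-drug W-Signals.

Per-protein modulation (the heatmap view) classifies each effector as
modulated by drug A, drug B, both, or neither at |0.3| thresholds for
both modulation and between-drug difference.  In the literal reading
adopted here, two means that both pass the threshold but differ by at
least it, with exactly equal magnitudes, fall to "neither"; the tie
cannot decide a direction and is vanishingly rare on continuous means.

**MoA extraction**: per solution, the qualifying mechanisms are simple
directed paths of at most the propagation depth from a stimulus protein
to an effector whose every edge has |weight| ≥ ε.  An edge's *support*
is the fraction of solutions in which it lies on at least one
qualifying path; paths are ranked by their minimum edge support (ties
lexicographic) and the union of the top k is reported.  Capping path
length at the propagation depth keeps extracted mechanisms realizable
by the dynamics.

**Enrichment**: up- (activity ≥ 0.1) and down- (≤ −0.1) regulated
protein sets are tested per annotation collection with the upper-tail
hypergeometric test, after excluding terms of ≥ 500 proteins.  The
printed description of the down threshold ("≤ 0.1") would overlap the
up set and is read as ≤ −0.1; the threshold is configurable.  Each
(direction × collection) family is Benjamini–Hochberg adjusted
independently (significance q < 0.05); terms significant in both
directions are reported as *modulated*.  The universe is every protein
of the loaded network — the model's closed world.  Only
over-representation is tested.

## Synthetic data

No real interactome, disease characterization or training database is
distributable, so the generator emulates all five inputs with planted
ground truth:

* **network** — preferential attachment (heavy-tailed like real
  interactomes; Erdős–Rényi available as an alternative), edges
  oriented from newer to existing nodes, hence acyclic.  The default
  uses 200 nodes with attachment parameter m = 5: m = 5 is the
  smallest value at which three drug targets verifiably deliver
  signal ≥ 0.2 to the ~72 downstream proteins the default effector and
  bioflag counts require.
* **true weights** — random signs with magnitudes in [0.5, 1]; the
  signs become the network's act/inh edge annotations, so the sign
  structure of the problem is knowable (as it is for a curated
  interactome) while the magnitudes must be learned.
* **effectors** — chosen among nodes that verifiably receive
  |activity| ≥ 0.2 from a drug's targets under true-weight propagation,
  alternating between the drugs so each has a planted mechanism;
  disease signs are set opposite to the drug-induced sign and every
  selection is re-verified by propagating over the final basal state.
  The default scale mirrors the study's object counts: 4 motives
  (3 response + 1 basal) over 70 rows with 66 unique proteins, one
  drug with 2 activating targets and one with 1 inhibiting target, a
  20-rule truth table, and 250 retained solutions.
* **truth table** — one rule per drug (targets → expected reversed
  effector signs) plus distractor rules whose responses are read off
  true-weight propagation from random stimuli.  The true weights
  therefore comply with every rule at zero noise, while random weights
  score ≈ 0.5, so >90% accuracy is informative.  Response signs flip
  independently with probability η (default 0).
* **annotations** — one planted term per drug (its planted effector
  set) plus random decoy terms; an oversized ≥500-protein term is
  added when the network is large enough to contain one.

What passing tests on these fixtures shows: that the machinery —
propagation, constraint training, retention filtering, scoring, path
extraction, enrichment — recovers planted mechanisms under the stated
conditions.  What it does not show: performance on a real, cyclic,
noisy interactome with curated truth tables, where compliance ceilings,
path multiplicity and annotation redundancy are all harsher.

## Numerical choices and problem sizes

* Propagation uses dense matrices (the default network is 200 nodes);
  all rules are propagated as columns of one state matrix inside the
  annealing loop, which matches the per-rule reference implementation
  exactly (asserted in the tests).
* All randomness flows through `numpy.random.default_rng` seeds;
  identical configuration + seed reproduces ensembles bit-for-bit.
* Degenerate inputs: empty truth tables, empty ensembles, empty
  stimulus (all-zero fixed point), rules referencing proteins missing
  from the network (dropped with a warning; the rule is dropped when a
  side empties), self-loops and duplicate edges (dropped with a
  warning).
* Test-scale runs use a 20-node fixture (2 motives, 2 drugs, 8 rules)
  for annealing-dependent properties and the 200-node default fixture
  for the end-to-end ensemble checks.

## Known limitations

* The acyclic synthetic topology cannot represent feedback loops; on
  cyclic networks the synchronous recurrence is well-defined but the
  fixed depth truncates long-range feedback.
* The per-rule compliance predicate, the T-Signal formula and the
  W-Signal grouping are this package's explicit readings of an
  under-specified source; each is isolated in one function.
* Simulated annealing makes no global-optimality claim; the retention
  filter, not the optimizer, defines solution validity.
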