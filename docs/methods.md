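# Methods

## Model

Associative learning is modelled as an anamorphism (unfold) of a coalgebra
over the state space P × G, where P is the set of finite lists of training
events and G the set of association networks — directed graphs whose edges
(s, σ, t) carry a real associative strength σ and a co-occurrence count.
The coalgebra's halting predicate is "the pair list is empty"; its
observation is the merge μ(firstpair, g) of the first event into the current
network; its next-state map is ν = ⟨τ, μ⟩ (drop the head of the list, keep
the merged network). Unfolding from (p₀, g₀) yields the temporal snapshot
stream [g₁, …, g_n], one network per event, with g₀ excluded (it is the
caller's input and trivially recoverable). Because anamorphisms are
productive, snapshot k depends only on the first k events — the k-th
observation is fixed before the rest of the list is consumed, which is what
licenses reading the output list as a time series of one evolving network.

The internal-memory variant `learn_int` is the exponential transpose
(currying) of the external model: a map from pair lists to
network-transformers, extensionally equal to `learn_ext` by the
product–exponential bijection. Only this operational currying contract is
implemented; no general adjoint-fold machinery is exposed.

Two classical productions of the same computation, the right-recursive
`rlearn_fold` and the iterative `ilearn_loop`, return only the final
network. They are deliberately independent code paths (explicit recursion
and an explicit while-loop over head/tail) and serve as oracles: the test
suite checks that both agree with the last snapshot of `learn_ext` on
hundreds of random finite inputs, under both merge rules.

## Merge rules and parameters

**Halfway rule.** First co-occurrence of a pair creates the edge at σ₀;
every later co-occurrence applies σ ← (1 + σ)/2. For any σ₀ ∈ (0, 1) the
strength increases strictly and monotonically toward the fixed point 1,
coming within 10⁻⁶ of it in at most 30 updates. Default σ₀ = 0.5 (unitless
strength), chosen so the first update lies on the same trajectory as the
recurrence: σ_n = 1 − 2⁻ⁿ after n updates from creation. Updates on
distinct (source, target) pairs commute, so permuting a list of all-distinct
pairs leaves the final network unchanged.

**Rescorla–Wagner rule.** A trial is a non-empty set of present cues, an
outcome, and an optional per-trial asymptote λ. The summed prediction
ΣV runs over the present cues' strengths toward the outcome (absent edges
count as 0), then each present cue X receives
V_X ← V_X + α_X · β · (λ − ΣV). Defaults: per-cue salience α from a map
with fallback α = 0.3 (α, β ∈ [0, 1]), learning rate β = 1, asymptote
λ = 1. Single-cue acquisition therefore follows the closed form
V_n = λ(1 − (1 − αβ)ⁿ), which the tests verify to 10⁻⁹ for n ≤ 100, and a
cue pre-trained to asymptote blocks a novel compound partner (ΔV_B = 0
exactly at V_A = λ). Strengths are intentionally not clipped to [0, 1]:
over-expectation drives them down and conditioned inhibition below zero.
Networks built by the two rules are distinguished by the rule that produced
them, not by any flag on the network.

**Decay.** Both rules accept a multiplicative decay d ∈ (0, 1] applied to
every edge strength before each merge (d = 1, the default, is no decay).
Normalization variants are out of scope.

## Network types and narrow systematicity

A `NetworkType` partitions the vertex vocabulary into named classes —
either closed (an explicit vocabulary) or open (members written
`class:value`) — and declares the set of (source-class, target-class)
signatures over which a merge function exists, plus whether conjunction
vertices are representable. `validate_pair` reports either an
unrepresentable-vertex violation or a forbidden-signature violation;
`learn_ext` validates the whole list up front and refuses type-violating
lists before any learning, because partial learning would misstate what
"no update rule is defined over these networks" means. A `default_class`
catch-all makes a fully permissive type expressible. Maps between vertex
vocabularies are applied as graph homomorphisms (`apply_type_map`);
collisions merge edges keeping the maximum strength and the summed count
(the count semantics is this package's choice — total co-occurrences
represented).

The shipped species types encode selectivity as signatures: rats allow
odour→food only; quail allow colour→food and colour→illness (the
coloured-water aversion) and nothing odour-based; pigeons allow colour→food
and tone→shock-avoidance but neither crossed pair.

## Elemental vs configural encoding

`encode_trial` turns a stimulus→outcome trial into training events. The
elemental schema emits one event per stimulus attribute, each cue
independently predictive. The configural schema builds one conjunction
vertex from the attribute values, joined with "∧" in lexicographic order —
sorting is the canonical order because it is the only one recoverable from
a bare value tuple, making the id invariant under presentation order. A
configural encoding against a type without conjunction vertices raises an
unrepresentable-conjunction error.

This makes the XOR structure of the colour×shape→response map operational:
elementally, every colour and shape co-occurs equally often with both
responses, so all recall queries tie forever; configurally, the four
conjunction cues are distinct and the map is learned in one block.

## Rote learning to criterion

`train_to_criterion` presents every mapping entry once per block, order
shuffled by a seeded `random.Random`, learns with `learn_ext` from the
accumulated network, then tests recall of every encoded cue. A recall tie
counts as incorrect — a conservative choice so chance behaviour can never
pass criterion. One presentation per pair per block is assumed. The
returned result carries the final network, the blocks used (None on
failure) and the last block's accuracy.

## Synthetic two-list conditions

`generate_pairlist` emits the two lists of the classic transfer designs.
[AB, CD] draws 2n distinct cues and 2n distinct targets and splits them, so
the lists share no vertex. [AB, ABr] keeps list 1's cues and targets and
re-pairs them under a derangement (no fixed point, hence no repeated pair);
the derangement is found by seeded rejection sampling capped at 200
shuffles with a rotation fallback, so generation is total and
seed-deterministic. The generator is structural only: no human or animal
trials-to-criterion counts are emulated, because the designs are specified
by their combinatorial structure, not by quantitative learning curves. What
passing tests show is therefore that the *capacities* behave as the theory
says (equal blocks-to-criterion for structurally equivalent lists, ties
under elemental XOR, refusal under forbidden signatures) — not that any
particular empirical learning-rate is reproduced.

## Numerical and serialization choices

Evaluation of any unfold carries a mandatory step budget (default 10,000)
so a non-halting coalgebra can never hang; the resulting stream records
whether the halting predicate or the budget stopped it, and budget-k output
is always a prefix of budget-k′ output for k′ > k. `fold` is
right-associated (the safe general convention for non-associative
combines); an empty fold with no initial value is an explicit error.
Recall tie-breaking is lexicographic on target id and the full tie-set is
always exposed. Network JSON is written with sorted keys and floats in
shortest round-trip (repr) form: identical runs are byte-identical and
read(write(x)) == x holds exactly, which a fixed significant-digit format
could not guarantee. Pair lists travel as TSV to avoid quoting issues with
Unicode glyph vertex ids, which are kept verbatim (ASCII aliases live in
fixture metadata).

## Known limitations

- Only the operational currying contract of the transpose is provided; no
  categorical machinery (functors, universal morphisms) is modelled.
- Normalization terms and neural-population realizations of the species
  types are out of scope; decay is the only strength-dynamics extension.
- The backpropagation-based merge is a noted extension point, not
  implemented.
- Training order for ws1 is only partially fixed by its source; the
  remainder follows the mapping's printed order — a documented convention.
- List context in the [AB, ABr] condition can be expressed via configural
  encoding with a context attribute, but no quantitative target for it is
  modelled.
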