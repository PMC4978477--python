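# coalearn

Coalgebraic (corecursive) models of associative learning, for computational
cognitive-science work on the *systematicity of learning*: why an agent able
to rote-learn one list of cue–target pairs can, in general, learn any
structurally equivalent list — and why some mappings (configural XOR
discriminations, species-forbidden cue–outcome signatures) fall outside that
equivalence class.

`coalearn` is a library plus a small CLI. It provides:

- **Recursion-scheme combinators** — `unfold` (anamorphism), `fold`
  (catamorphism), product pairing `⟨f, g⟩` and the exponential transpose
  (currying), with the classic *repeat* and *count* coalgebras.
- **Typed association networks** — directed graphs whose edges carry an
  associative strength σ and a co-occurrence count, with species/schema
  network types that declare which (cue-class → target-class) edges are
  representable at all.
- **Merge rules** — the *halfway* co-occurrence update σ ← (1 + σ)/2
  (created at σ₀ on first occurrence, climbing monotonically toward 1) and a
  *Rescorla–Wagner* rule for compound trials,
  ΔV_X = α_X · β · (λ − Σ_present V), which reproduces acquisition curves and
  blocking.
- **Learning anamorphisms** — the external-memory model `learn_ext` unfolds
  the coalgebra ⟨halt = "pair list empty", emit = μ(firstpair, g),
  ν = ⟨τ, μ⟩⟩ into the temporal snapshot stream [g₁, …, g_n]; the
  internal-memory model `learn_int` is its exponential transpose. The
  classical recursive (`rlearn_fold`) and iterative (`ilearn_loop`)
  productions of the same computation serve as equivalence oracles.
- **Rote-learning simulation** — `train_to_criterion` runs shuffled
  presentation blocks until a full recall test passes, with elemental vs
  configural trial encodings and an ablation utility that removes the shared
  merge component (all learning capacities factoring through it fail
  together; recall on already-built networks survives).
- **Fixtures and a generator** — built-in worked examples (the bread/butter
  list, the ws1/ws2 word→shape maps, the colour×shape configural map,
  rat/quail/pigeon selectivity types) and a seeded generator for the
  [AB, CD] and [AB, ABr] two-list conditions.

## Worked example: the bread/butter trace

Train the halfway rule on the three-pair list
`[(bread, butter), (knife, fork), (knife, butter)]` from the empty graph:

```sh
coalearn fixture --name bread_butter --export .
coalearn learn --pairs bread_butter.tsv --merge halfway --sigma0 0.5 \
    --snapshots snaps.jsonl --final final.json
```

prints

```
3 snapshots; final network: 4 vertices, 3 edges
```

One network snapshot is emitted per training event — the stream
[g₁, g₂, g₃]. `snaps.jsonl` holds one JSON network per line; g₁ contains the
single edge bread→butter at σ₀ = 0.5, and the final network g₃ has three
edges with knife pointing at both fork and butter:

```
{"edges": [{"count": 1, "source": "bread", "strength": 0.5, "target": "butter"}], "vertices": ["bread", "butter"]}
{"edges": [{"count": 1, "source": "bread", "strength": 0.5, "target": "butter"}, {"count": 1, "source": "knife", "strength": 0.5, "target": "fork"}], "vertices": ["bread", "butter", "fork", "knife"]}
{"edges": [{"count": 1, "source": "bread", "strength": 0.5, "target": "butter"}, {"count": 1, "source": "knife", "strength": 0.5, "target": "butter"}, {"count": 1, "source": "knife", "strength": 0.5, "target": "fork"}], "vertices": ["bread", "butter", "fork", "knife"]}
```

Recall then picks the strongest associate of a cue:

```sh
$ coalearn recall --network final.json --cue bread
butter
$ coalearn recall --network final.json --cue knife
knife: tie among {butter, fork} (strength 0.500000)
```

knife ties because both of its associations were seen exactly once — the
full tie-set is always exposed so callers can treat ties as chance.

The same from Python:

```python
from coalearn import (AssociationNetwork, LearningModel, fixture,
                      learn_ext, recall)

fxt = fixture("bread_butter")
model = LearningModel(network_type=fxt.network_type)
stream = learn_ext(model, fxt.pair_list, AssociationNetwork.empty())
len(stream)                          # 3
recall(stream[-1], "bread").prediction   # 'butter'
recall(stream[-1], "knife").tie_set      # frozenset({'butter', 'fork'})
```

Other things to try: `coalearn simulate --condition AB_ABr --n-pairs 4
--seed 3` (trials-to-criterion for a re-paired second list),
`coalearn demo rw --trials 20` (Rescorla–Wagner acquisition and blocking
curves as CSV), and `coalearn learn --network-type G_Rat` on a colour→food
list, which exits nonzero: no merge function is defined over rat-typed
networks for that signature.

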