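# tmcomplexity

Measure the **statistical complexity** of symbolic sequences produced by
small Turing machines — and steer it.

Machines with the same description length (same number of states #Q and
tape symbols #Σ) can write tapes of wildly different statistical texture:
blank monotony, short repetitive cycles, or patterns a statistical model
can barely predict. This package quantifies that texture with the
**Normalized Compression** of the tape under the **best-order adaptive
Markov model**, maps it across entire machine spaces, localizes it inside
individual tapes, and includes a stochastic optimizer that raises (or
lowers) a tape's statistical complexity while the machine's rule table —
its algorithmic description — keeps a fixed size. The same measure applies
unchanged to DNA sequences in FASTA, where its robustness to substitutions
and block permutations can be stress-tested.

It is aimed at researchers in algorithmic information theory, complexity
science, and compression-based sequence analysis (including genomics uses
of complexity profiling).

## The model

A machine here is a rule table δ over (state, read symbol) cells, each cell
holding a (write symbol, head move ∈ {left, stay, right}, next state)
triple. Every machine starts on an all-blank tape (blank = `0`) in state 0,
has no accepting states, and is halted externally after a fixed number of
iterations. The space for a pair (#Q, #Σ) contains

    TNTM = (3 · #Σ · #Q)^(#Σ · #Q)

machines, enumerated by a mixed-radix total order: the all-(0,0,0) table is
machine 0 and each id maps bijectively to a table.

A tape x over alphabet A is scored with an adaptive order-k finite-context
model with Laplace smoothing,

    P(s | ctx) = (n(ctx, s) + α) / (n(ctx) + α·|A|),   α = 1,

updated online in one pass. The compressed size and Normalized Compression
are

    C(x) = Σᵢ −log₂ P(xᵢ | xᵢ₋ₖ..xᵢ₋₁),     NC(x) = C(x) / (|x| · log₂|A|),

with the best order selected as the k ∈ {2,…,9} minimizing NC. NC ≈ 1
means incompressible; NC → 0 means trivially regular. Two local variants
decompose the global score: the **normal profile** C⃗(xᵢ) = N⃗(xᵢ)/log₂|A|
(per-position code lengths, summing exactly to C(x)) and the **dynamic
profile** D⃗(x,t) = NC of the tape as it exists at iteration t.

## Worked example

```python
>>> from tmcomplexity import MachineSpec, id_to_matrix, run_machine, best_order_nc
>>> spec = MachineSpec(2, 2)          # 2 states, binary alphabet
>>> spec.total_machines
20736
>>> m = id_to_matrix(2287, spec)      # one specific rule table
>>> rec = run_machine(m, 50_000)      # 50,000 iterations, blank start
>>> rec.amplitude                     # cells of tape actually written
184
>>> res = best_order_nc(rec.tape, alphabet_size=2)
>>> round(res.nc, 5), res.best_order, round(res.total_bits, 1)
(0.13845, 2, 25.5)
```

Machine 2287 visits only 184 tape cells in 50,000 steps — it keeps
rewriting a small region — and the tape it leaves behind costs 25.5 bits
under the best model (order 2), i.e. NC ≈ 0.138: mostly regular, with a
residue of structure that resists the statistical model. Compare a plain
step pattern:

```python
>>> r = best_order_nc("0" * 500 + "1" * 500)
>>> round(r.nc, 5)
0.02989
```

The same operations are exposed on the command line:

```bash
tmcomplexity sweep --states 2 --alphabet 2 --iterations 50000 --out records.tsv
tmcomplexity nc --input genome.fasta
tmcomplexity optimize --states 10 --alphabet 2 --tape-iterations 2000 \
    --rule-iterations 1000 --seed 1 --out trace.jsonl
tmcomplexity assess --input step --mode uniform --seed 1 --out heatmap.tsv
```

`sweep` writes one TSV row per machine (id, amplitude, bits, nc, best_k)
and prints the aggregate mean/std table; every output file is paired with a
`.config.json` sidecar holding the exact run configuration.

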