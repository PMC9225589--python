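# Methods

## Model

`protocode` implements a staged-accretion model of the genetic code in a
peptide/RNA world. Its objects are deliberately minimal: a codon is a
triplet over {U, C, A, G} (dually a digit triplet under U=1, C=2, A=3,
G=4); a code table is a codon→symbol mapping; a tRNA is an adaptor
holding a 5′→3′ anticodon and, once charged, one amino-acid symbol.

Three nested tables are fixed data:

* **GNC** — GGC→G, GCC→A, GAC→D, GUC→V (the GADV repertoire).
* **SNS** — the sixteen codons with strong (G/C) first and third bases,
  adding E, Q, L, P, H and R to reach ten amino acids.
* **UG** — the standard genetic code: 61 sense codons for 20 amino acids
  plus UGA/UAA/UAG, written with the stop letters J/X/Z (opal, ochre,
  amber). Stops are treated as codons that entered the repertoire by
  anticodon–codon pairing but never received amino-acid deliveries, so
  they exist only at the UG stage and terminate translation there.

Nesting (assignments only accumulate), the S-N-S membership rule, and
equality of the UG table with the canonical standard code (cross-checked
against Biopython's table in the tests) are enforced invariants, not
emergent results.

## Encoding simulation

A stage run is a discrete-event process over the stage's sense codons.
Each cycle:

1. one sense codon is drawn uniformly at random (encoded codons keep
   receiving deliveries — harmless, and the paper-style start/end-cycle
   pictures only require the white→blue transitions);
2. its cognate tRNA is charged: with probability 1 − ε the stage table's
   amino acid, otherwise (a *mischarge*) a uniformly random other stage
   amino acid, flagged on the event;
3. the delivered symbol is appended to the codon's frequency memory.

A codon becomes **encoded** once it has at least `min_observations`
deliveries and its modal symbol holds at least `modal_fraction_threshold`
of them; the encoded state is monotone. A run ends at full convergence
of the stage's sense codons or at `max_cycles`, in which case the result
is reported unconverged with its residual white set rather than raised.
Stages chain GNC → SNS → UG; a later stage starts from a *converged*
bank of its predecessor, carrying all counts and states forward.

`recovered_code` reads the learned code back out of a bank: each
observed codon maps to its modal amino acid, ties broken toward the
earliest-observed symbol (deterministic, and logged when it happens);
unobserved codons are excluded rather than guessed.

### Parameters

| parameter | default | rationale |
|-----------|---------|-----------|
| `error_rate` ε | 0.0 | mischarge probability per delivery; bounded to [0, 0.5) so the cognate symbol stays modal in the limit |
| `min_observations` | 1 | adequate for noiseless runs; ≈ 25 gives a comfortable majority-vote margin at ε = 0.1 |
| `modal_fraction_threshold` | 0.95 | (0.5, 1]; lowered to ≈ 0.6 for noisy runs, where the expected cognate share is 1 − ε |
| `max_cycles` | 100 000 | generous budget; a noiseless UG stage needs ~61·H₆₁ ≈ 290 cycles, a noisy one (ε = 0.1, 25 obs) a few thousand |
| `seed` | none | a single numpy `Generator` drives both codon draws and charging, making traces bit-reproducible |

With ε = 0 and `min_observations = 1`, a stage run is exactly a
coupon-collector process; for the four GNC codons the expected
convergence time is 4·H₄ = 25/3 ≈ 8.33 cycles, which the tests verify as
a mean over 1,000 seeded runs.

## Strand assembly and translation

`enumerate_arrangements`/`enumerate_chain_pairs` reproduce the
desk-scale combinatorics of early chain formation (4! = 24, C(4,2) = 6,
6! = 720); both are capped at 8 items and cross-checked against a
brute-force recursive enumerator in the tests. The printed counts match
the permutation/pair reading exactly, which is why the operations are
named "arrangements" and "pairs" rather than "combinations".

`assemble_strands` draws codons uniformly with replacement from a
stage's sense set. Lengths are uniform over codon counts inside a
nucleotide range, rounded inward (ceil/floor) so stated bounds are
honored; defaults are 30–80 nt for the GNC/SNS pre-mRNA era and
70–100 nt for the first UG-stage mRNA genes.

`translate` reads 5′→3′ from position 0 in a fixed frame. There is no
initiation machinery — AUG is just methionine — because the model
predates it. At GNC/SNS, codons outside the stage table (including the
future stops) follow an `unknown_policy`: `error` (default, naming the
codon and offset), `skip`, or `mark`, which inserts `?` — not `X`, since
X is the ochre stop letter in this scheme. Peptides never contain stop
letters; termination is metadata.

## Synthetic data

The generator (`assemble_strands`, wrapped by `generate_fixture`)
emulates random wet/dry-cycle linkage of stage-appropriate codons into
strands of realistic early-gene length. It does **not** emulate codon
usage bias, replication or selection dynamics, wobble reading, or any
thermodynamics of ligation — so passing tests show internal consistency
of the codec/tables/simulation machinery on uniformly random strands,
not statistical properties of real genes. Fixtures are plain FASTA/JSON,
byte-deterministic given their embedded parameters.

## Numerical and design choices

* Uniform codon draws and a uniform mischarge kernel are the
  minimal-assumption choices; no delivery rates are part of the model.
* Anticodons are stored 5′→3′ and computed as reverse complements, the
  standard orientation convention; it makes anticodon-of-anticodon an
  involution.
* One tRNA species per sense codon and one synthetase per amino acid
  (4 distinct pre-aaRS at the GNC stage, for symmetry with the later
  stages). Wobble decoding is out of scope.
* DNA tolerance: `T` is accepted as `U` on input everywhere; output is
  always RNA. Ambiguity codes (N, R, Y, …) are rejected, not resolved.
* The numeric listing of the first-stage codons in one published source
  contains an internal inconsistency (GGC given as 443); the codec
  follows the declared bijection strictly, under which GGC = 442 and
  GGA = 443.
* Test problem sizes (1,000-run recovery sweeps, 10,000-charge binomial
  checks) were chosen as the smallest that give 3-standard-error
  resolution on the quantities asserted.

## Limitations

* The convergence criterion (count + modal-fraction threshold) is a
  modeling choice; the source narrative only says codons "remembered"
  their amino acids. Permanence under selection is represented simply
  as the monotone encoded state.
* ε ≥ 0.5 is rejected outright rather than modeled; near ε = 0.5 the
  majority-vote guarantee degrades and recovery would require very
  large `min_observations`.
* No population structure, fitness, or replication — one memory bank,
  one environment.
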