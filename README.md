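# shifttyper

Recognition of amino-acid residue types from NMR chemical-shift spin
systems of intrinsically disordered proteins, using a shared-covariance
Gaussian (linear discriminant) classifier, plus the two workflows it
enables:

1. **Chain mapping** — enumerate the probable amino-acid sequences of a
   spin-system chain from per-position classifier posteriors and filter
   them against the protein sequence, discarding impossible placements.
2. **Assignment transfer** — carry residue assignments from a reference
   (H, N) peak list to an experimental one, using proximity *and*
   class consistency of the preceding residue instead of plain
   nearest-neighbor matching.

## Method summary

Training data are per-residue spin systems over seven canonical shifts
(HN, N, CO, CA, CB, HA, HB), read from BMRB NMR-STAR entries or a plain
tabular format.  Per class the mean and population covariance are
estimated; classes share a pooled (count-weighted average) covariance.
The per-class linear score is

    f_k(x) = mu_k' S^-1 x - 1/2 mu_k' S^-1 mu_k + ln(pi_k)

with priors `pi_k = n_k/N`; posteriors are the softmax of the scores.
Columns are Pareto-scaled (mean-centered, divided by the square root of
the standard deviation) jointly over training and query values.  Queries
with missing shifts are routed through *restricted* models retrained on
the available columns only.  A quadratic (per-class covariance) variant
is included for comparison.

Three standard shift subsets are supported: `i` = HN, N, CA, CO;
`ii` = CA, CB, HA, HB; `iii` = all seven.

## CLI

```sh
shifttyper simulate --length 140 --sd-scale 0.3 -o sim/   # synthetic fixture data
shifttyper train -t entries/*.str -s ii -o model/          # fit + save JSON model
shifttyper classify -t train.tsv --spins spins.tsv -o out/ # type unknown spin systems
shifttyper loo -t a.str -t b.str ... -s iii --mode restricted -o loo/
shifttyper importance -t train.tsv -s iii --repeats 1000 --seed 1 -o imp/
shifttyper map-chains -t train.tsv --spins spins.tsv --chains chains.tsv \
    --fasta protein.fasta -o map/
shifttyper transfer -t train.tsv -s ii --reference ref.list \
    --experimental exp.list --spins preceding.tsv -o tr/
```

Every run writes TSV reports plus a `manifest.json` recording the
configuration and input digests; identical inputs, config and seed give
byte-identical outputs.

Tabular spin-system files have a header with `id`, optional `type`,
`position`, `source`, and any of the seven shift names; empty cells mean
missing.  Chains tables have `chain_id`, `members` (semicolon-separated
spin-system ids, N-to-C) and optional `pre`.

## Layout

- `src/shifttyper/types.py` — domain types (spin systems, subsets, chains, peaks)
- `src/shifttyper/io/` — NMR-STAR, tabular, FASTA, Sparky readers/writers
- `src/shifttyper/lda.py` — scaling, class statistics, linear/quadratic scoring,
  restricted models, model JSON serialization
- `src/shifttyper/evaluation.py` — leave-one-out, confusion charts,
  permutation importance
- `src/shifttyper/chains.py` — candidate enumeration and sequence filtering
- `src/shifttyper/transfer.py` — peak-list assignment transfer
- `src/shifttyper/synthetic.py` — class-conditional Gaussian fixture generator
- `src/shifttyper/cli.py` — the `shifttyper` command
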