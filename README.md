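# mtpopgen

Population-genetic analysis of aligned mtDNA (control-region) haplotype
data: molecular diversity indices, AMOVA / pairwise Φ<sub>ST</sub> with
permutation tests and Wright's gene-flow transformation, Tajima's D and
Fu's Fs with simulated significance, mismatch-distribution
sudden-expansion fitting with calendar dating, median-joining haplotype
networks, and a coalescent simulator for generating synthetic datasets
with known truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance checks (exact desk-scale
values, oracle equivalence against independent brute-force
implementations, null calibration, parameter recovery, and structure
properties). One check — the haplotype count of the deposited GenBank
sequences ON470395–ON470439 — needs a one-time download on a connected
machine (`python scripts/fetch_genbank.py`); it fails with an explanatory
message when the file is absent.

## CLI

Full analysis from an aligned FASTA plus a two-column `sample<TAB>population`
map:

```sh
mtpopgen run --fasta aln.fasta --popmap pops.tsv --group ES=E,S \
    --seed 42 --out results/
```

This writes `diversity.tsv`, `fst_nm.tsv` (pairwise Φ<sub>ST</sub>, p,
Nm with category), `amova.tsv`, `neutrality_mismatch.tsv` (D, Fs, τ, θ0,
θ1, expansion time in years), `network.tsv` + `network.graphml`
(median-joining network), and `manifest.json` recording every parameter.
Reruns with the same seed are byte-identical.

Stage subcommands: `diversity`, `fst`, `amova`, `neutrality`, `mismatch`,
`network`, `simulate` — e.g.

```sh
mtpopgen simulate --seed 1 --out sim/              # synthetic dataset
mtpopgen fst --fasta aln.fasta --popmap pops.tsv --pair E W --seed 1
mtpopgen mismatch --fasta aln.fasta --popmap pops.tsv --pop W --seed 1
```

## Conventions

- Sites containing `-` or `N` in any sequence are removed before analysis
  (complete deletion; `pairwise` policy available in the library).
- Haplotype identity is exact string equality on the analyzed sites.
- The fixation index is the distance-based Φ<sub>ST</sub> of the AMOVA
  framework with pairwise nucleotide-difference distances; permutation
  p-values use the (hits+1)/(n+1) estimator with `≥ observed` ties.
- Gene flow Nm = (1/Φ<sub>ST</sub> − 1)/2, categorized high (≥ 1.0),
  medium (0.250–0.99), low (< 0.250).
- Expansion dating uses τ = 2ut with per-sequence rate u = L·r, where r is
  a divergence rate per site per year (default 3.6 × 10⁻⁸).
- Alignment columns are 1-based in every report, 0-based internally.

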