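# ethnosurvey

Quantitative analysis of free-list ethnobotanical interviews: who cites which
plant, how early in the list, for what use, and how similar two survey areas
are.  The package is aimed at ethnobiologists comparing wild-plant knowledge
between communities from long-format citation tables (one row per interview ×
taxon × use category), and ships a seeded generator of realistic synthetic
surveys so every stage of the pipeline can be exercised when raw interview
data cannot be shared.

## Indices

With N interviews in scope, FC(j) the number of interviews citing taxon j,
L_i the length of interview i's free list and R_ij the rank of j in it:

- **RFC** (relative frequency of citation): `RFC_j = FC_j / N`
- **UR** (use reports): `UR_j = Σ_u |{interviews reporting (j, u)}|` over the
  seven use categories u ∈ {E, A, M, T, C, AF, O}
- **Smith's S** (salience): `S_j = (1/N) Σ_i (L_i − R_ij + 1) / L_i`,
  summing over the lists that cite j
- **CV** (cultural value): `CV_j = (uses_j / 7) · (FC_j / N) · Σ_u IUc_ju / N`
  where uses_j is the number of distinct categories reported for j and
  IUc_ju the number of interviews reporting use u of j
- **Fic** (informant consensus factor) per category:
  `Fic = (n_ur − n_taxa) / (n_ur − 1)`, undefined when n_ur < 2
- **JI** (Jaccard similarity, percent): `JI = 100 · C / (A + B − C)` for
  per-area inventory counts A, B with C shared

Quantitative tables are computed after the standard filter that keeps only
taxa cited by at least two interviews; the filter preserves the interview
roster and the original free-list ranks, so N and L are those of the survey
as conducted.

## Worked example

```
$ python analysis/01_simulate.py --seed 2019
wrote results/simulated_citations.csv (3023 records, seed 2019)
  Izola: 30 interviews, 27.37 taxa/interview (range 10-49)
  Komen: 30 interviews, 29.43 taxa/interview (range 10-66)
  taxa: 189 cited, 177 with FC >= 2
  filtered inventory overlap: JI = 64.41%
```

The generator simulated 60 interviews over a 199-taxon pool (70% shared
between areas); 189 taxa were cited at least once and 177 at least twice, and
the two filtered area inventories overlap by a Jaccard similarity of 64%.

```
$ python analysis/02_indices.py
top 5 taxa by RFC (pooled):
  Maquisia specimen012         RFC=1.00  S=0.834  UR=100  CV=1.190
  ...
informant consensus by use category (pooled):
category      n_ur  n_taxa     Fic
E             1444     177    0.88
A              437     141    0.68
```

`Maquisia specimen012` was cited by every interview (RFC = 1.00) and early in
most lists (S = 0.834).  The food/drink category E shows high informant
consensus (Fic = 0.88): many reports concentrated on relatively few taxa.
`analysis/03_compare_areas.py` adds the cross-area Jaccard curve (overall /
top-50% / top-20% of taxa by pooled FC), per-category similarities, ranked
top-10 tables per index, and two-sample t-tests of taxa-per-interview and
uses-per-taxon.

The same pipeline is available as a CLI:

```
ethnosurvey simulate --seed 42 --out sim.csv
ethnosurvey compute sim.csv --outdir results/
ethnosurvey validate sim.csv
ethnosurvey fixture --out benchmark.csv
```

`ethnosurvey fixture` emits a deterministic benchmark survey whose overlap
structure is assigned constructively — after filtering, 147 and 119 area
taxa sharing 109, hence JI = 100·109/157 = 69.43% — so the full chain can be
checked against a known answer (`analysis/04_benchmark_fixture.py` does
exactly that and prints the expected 69.43 / 157).

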