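# oligofish

Design toolkit for **pre-labeled fluorescent oligonucleotide probes** used in
fluorescence *in situ* hybridization (FISH). Short (~24–31 nt) 5′-fluorophore
oligos hybridize in minutes at room temperature and need no enzymatic
labeling, which makes them ideal for routine karyotyping with universal
targets (rDNA, telomere repeats) and for species-specific tandem repeats
mined from whole-genome sequencing reads. This package covers the
computational side of that workflow, for plant/animal cytogeneticists and
anyone designing hybridization oligo panels:

- **Degenerate consensus building** — map homologous sequences from many taxa
  onto a reference repeat unit (semi-global affine alignment, accepted when
  ≥ 50 nt align identically), accumulate a per-column conservation profile,
  and emit an IUPAC degenerate consensus whose ambiguity codes cover every
  base above a frequency threshold.
- **Melting temperature under hybridization conditions** — the empirical
  GC/length closed form with salt and formamide corrections,

  `Tm = 81.5 + 16.6·log10([Na+]) + 0.41·(%GC) − 675/L − 0.65·F`

  where `[Na+] = 0.195 × (SSC fold)` and `F` is % formamide. For a degenerate
  pool the Tm range follows from GC bounds; coefficients can be re-fitted to
  a printed probe table (`calibrate_model`).
- **Probe scanning** — all consensus windows of 24–31 nt with no `N`, pool
  size ≤ 256, the whole Tm range inside 39–53 °C (at 2×SSC / 50% formamide),
  and high conservation; ranked and greedily spaced.
- **Tandem-repeat probes** — phase-truncated concatemers of a monomer, e.g.
  (TTTAGGG)₄ truncated to 29 nt for plant telomeres.
- **Panel assembly** — pool probes per target into fluorophore cocktails
  (e.g. 45S→Cy3, 5S→Alexa Fluor 488, telomere→ATTO425), enforce one emission
  channel per target, and cap probe counts on very bright tandem targets to
  avoid filter crosstalk. A packaged table of 26 probes (12 × 45S rDNA,
  12 × 5S rDNA in angiosperm/gymnosperm/cranial-vertebrate lineage variants,
  telomere, and the ginseng Pgms1 minisatellite) ships with the package.
- **Minisatellite read screen** — ungapped matching of WGS reads against the
  cyclic concatemer of a short monomer (all phases, both strands), yielding
  per-sample mapped fractions and presence calls for species-specificity
  screens.
- **Synthetic data** — seeded generators for homolog families with planted
  conserved windows and for read sets with planted repeat fractions, so the
  whole pipeline is testable without downloads.

## Worked example

```python
import oligofish as of

# a homolog family with a planted 30-nt conserved window (columns 286-315)
anc, homs, truth = of.simulate_family(of.FamilySpec(seed=42))
profile = of.build_profile(homs, anc)          # 60 homologs vs ancestor
cons = of.build_consensus(profile)             # degenerate IUPAC consensus
probes = of.scan_probes(cons, profile)         # Tm- and conservation-filtered
for i, p in enumerate(probes[:3], 1):
    print(f"probe {i}: {p.sequence}  pos {p.start}…{p.end}  Tm {p.tm:.1f}")
```

prints

```
probe 1: ATCCTGTATGTTAGCGCATTGGGCCCCA  pos 13…40  Tm 40.1
probe 2: GGGTATTGAGCCTCCTCTCCGTCGGAT  pos 75…101  Tm 41.5
probe 3: GGAACTCACAAACACCTCAAGTGACAGGG  pos 149…177  Tm 40.1
```

— eight probes in total, each 24–31 nt with Tm inside 39–53 °C at 2×SSC /
50% formamide, at least 20 nt apart; one of them sits on the planted
conserved window. Degenerate pools report a Tm interval instead:

```python
print(f"{of.tm_range('TCGAAGACGATYAGATACCGTCSTAGT'):.1f}")   # 35.4–37.0
```

(the Y and S codes give GC bounds 12–13, hence a 1.5 °C range). Screening a
10,000-read sample with 1% planted Pgms1 concatemer reads:

```python
reads = of.simulate_reads(of.ReadSimSpec(seed=11, sample_name="carrier"))
rep = of.screen_sample(reads, "ACATTCTTGAT")
print(f"{rep.sample_name}: {rep.mapped_reads}/{rep.evaluable_reads} mapped, present={rep.present}")
# carrier: 100/10000 mapped, present=True
```

The same steps are available from the shell:

```bash
oligofish simulate family --seed 42
oligofish consensus --reference family.ancestor.fa --homologs family.homologs.fa --min-match 50
oligofish design --consensus consensus.fa --profile consensus.profile.tsv --ssc 2 --formamide 50
oligofish tandem --monomer TTTAGGG --target-len 29
oligofish cocktail --spec experiment.toml
oligofish screen --monomer ACATTCTTGAT --reads sample.fa
```

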