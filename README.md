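# ampliphy

Degenerate primer design, in-silico PCR, pairwise identity and
neighbor-joining phylogeny for marker-gene surveys.

Universal PCR primers that amplify one gene across a whole bacterial
genus are a workhorse of culture-collection screening and taxonomy:
conserved stretches of a multiple alignment are turned into degenerate
oligonucleotides (IUPAC ambiguity codes standing for several bases),
the primers are used to amplify the marker from many strains, and the
amplified fragments are compared by percent identity and placed on a
distance tree. `ampliphy` implements that workflow end to end for
computational use — the motivating case is a six-primer panel against
bifidobacterial bile salt hydrolase (*bsh*) genes, shipped with the
package, but every stage is generic.

The core pieces, in the field's standard notation:

- **Degeneracy** of an IUPAC oligo = ∏ per-position code sizes;
  primer–template compatibility = non-empty base-set intersection per
  position, with a strict 3′ anchor (default: last 3 bases exact) and a
  total mismatch budget (default 2).
- **Product length** is inclusive of both primer footprints: a forward
  footprint at reference positions 1–20 paired with a reverse footprint
  at 505–524 predicts a 524 bp product.
- **Percent identity** = 100 · matches / columns of an optimal global
  affine-gap alignment (match +1, mismatch −1, gap open −2, extend −1),
  terminal overhangs excluded; distance p = 1 − identity/100, with an
  optional Jukes–Cantor correction d = −(3/4) ln(1 − 4p/3).
- **Neighbor joining** (Saitou–Nei): iteratively join the pair
  minimizing Q(i,j) = (n−2) d(i,j) − r(i) − r(j); exact on additive
  matrices. **Bootstrap support** of an edge = percentage of
  column-resampled replicate trees containing the same leaf
  bipartition.
- A **simulator** evolves a root gene down a known tree under JC69 and
  re-plants concrete expansions of the primer footprints in every leaf,
  so the whole pipeline can be validated against ground truth offline.

## Worked example

Simulate a six-taxon *bsh*-like gene family, screen it with the
packaged panel, and build a bootstrap tree:

```sh
$ ampliphy simulate --leaves 6 --seed 7 --out-dir demo
6 templates -> demo/templates.fasta

$ ampliphy pcr --templates demo/templates.fasta \
    --fwd Bif-bshA-1F --rev Bif-bshD-2R --out demo/amplicons.tsv
6 amplicons -> demo/amplicons.tsv

$ cat demo/amplicons.bands.tsv
template_id n_products bands_bp positive
T2          1          524      True
T3          1          524      True
T6          1          524      True
T1          1          524      True
T4          1          524      True
T5          1          524      True

$ ampliphy identity --in demo/templates.fasta --out demo/identity.tsv
identity range 74.4-87.8 % -> demo/identity.tsv

$ ampliphy tree --in demo/templates.fasta --bootstrap 200 --seed 7 \
    --out demo/tree.nwk
tree with 6 leaves, 200 replicates -> demo/tree.nwk

$ cat demo/tree.nwk
(T3:0.101842,T6:0.0992105,(T2:0.109605,(T1:0.0568421,(T4:0.0542105,T5:0.0678947)100:0.0247368)100:0.0582895)90:0.00881579);
```

Every template carries the four conserved panel sites, so each yields
exactly one 524 bp band (the screening product: forward footprint 1–20,
reverse footprint 505–524). The identity range reflects the simulated
divergence; internal node labels are bootstrap percentages out of 200
replicates. A template without the conserved sites — a gene the panel
does not target — produces `positive = False` and no band, the
negative-control behavior.

The packaged panel itself:

```sh
$ ampliphy panel list
name         sequence_5to3            orientation degeneracy anchor tm_min tm_max
Bif-bshA-1F  ATGTGCACWGSYGTYCGTTT     forward     16         1      58     62
Bif-bshB-2F  TTCGGCCGYAAYCTCGAYTGGAG  forward     8          46     70     76
Bif-bshC-1R  TCGAYGACGATGCTDCG        reverse     6          448    52     56
Bif-bshD-2R  GGYTGRTTGGTVAGCACRTC     reverse     24         505    58     66
Bif-bshE-3F  TTCGGCCGYAAYCTYGAYTGG    forward     16         46     62     70
Bif-bshF-3R  TCGAYGACGATGSTDCG        reverse     12         448    52     56
```

`ampliphy design --aln family.fasta --reference <id> --out-dir out`
runs the other direction: conserved-block detection on your own
alignment, emitting a primer table with degeneracies, reference
anchors and Wallace-rule Tm windows.

All of this is equally usable as a library; see `docs/methods.md` for
the models, defaults and their rationale.

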