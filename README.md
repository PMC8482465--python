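# apmsmist

Interactor calling for affinity-purification mass spectrometry (AP-MS)
experiments, built around the MiST (Mass spectrometry Interaction
STatistics) score. The package takes a MaxQuant `proteinGroups.txt`
label-free quantification (LFQ) table plus an experimental design (which
runs belong to which bait, biological replicate, and technical replicate),
and produces per-bait lists of high-confidence binding partners, a
shared/unique comparison between baits, network and heatmap exports, and a
simple annotation over-representation analysis. It ships a synthetic-data
generator with known ground truth so every stage is testable end to end.

It is written for proteomics analysts running pull-down experiments of the
common "two related baits plus an IgG mock control" shape — for example
paralogous transcription factors immunoprecipitated from the same cell
population in triplicate.

## The method

Preprocessing follows the standard Perseus recipe: rows flagged as
potential contaminants, reverse decoy hits, or proteins only identified by
a modification site are removed; LFQ intensities are log2-transformed
(zeros are "not quantified" and treated as missing); technical replicates
are collapsed to their median; rows are kept only if they have at least
*k* = 3 valid values in at least one bait group.

Each bait's pull-down is then scored with MiST. With the de-logged
intensities normalized per run so each run's abundances sum to 1, a prey's
fractions *a₁…aₙ* across a bait's *n* biological replicates give three
components, each in [0, 1]:

- **Reproducibility** R = −Σ pᵢ·log_n(pᵢ), where pᵢ = aᵢ/Σaⱼ — the
  normalized Shannon entropy of the prey across replicates (1 for uniform
  presence, 0 for single-replicate presence);
- **Abundance** A = (1/n)·Σ aᵢ — mean normalized intensity, missing
  observations counting as 0;
- **Specificity** S = A(bait) / Σ_baits A — the share of the prey's total
  abundance attributable to this bait, the IgG control scored like any
  other bait.

The composite score is w_R·R + w_A·A + w_S·S with the published
MiST-trained weights (0.309, 0.006, 0.686, renormalized) as defaults. A
prey is called an interactor of a test bait when its bait score is ≥ 0.75
**and** its IgG score is ≤ 0.75 (both inequalities non-strict). Calls are
then screened against a contaminant-frequency repository — how often each
protein appeared across a panel of control IP experiments (126 by
default) — and retained only when that frequency is strictly below 40%.
Surviving calls are ranked by mean log2 enrichment of the bait IP over the
IgG IP.

By default each test bait is scored against the control in its own
bait/IgG pair (`scoring: per_control_pair`). This matters whenever two
baits share genuine partners: joint specificity across both baits would
split a shared partner's S in half and make it uncallable at the 0.75
threshold. Joint all-bait scoring is available with `scoring: joint`.

## Worked example

Simulate a small dataset with known truth, run the pipeline, and compare
the two baits:

```
$ cat sim.yaml
n_preys: 300
n_true_per_bait: 25
n_shared_true: 10
n_frequent_background: 40
$ apms simulate --config sim.yaml --out data --seed 42
$ cat run.yaml
protein_groups: data/proteinGroups.txt
design: data/design.tsv
repository: data/contaminant_repository.tsv
outdir: out
$ apms run --config run.yaml
rows in: 306
after flag filter: 300
after valid-value filter: 299
FOSL1: 25 interactors
FOSL2: 25 interactors
shared: 10
$ apms compare --calls-a out/calls_FOSL1.tsv --calls-b out/calls_FOSL2.tsv
FOSL1: 25 calls (15 unique)
FOSL2: 25 calls (15 unique)
shared: 10
```

The 306 input rows include 6 flagged decoys, removed first; one more row
fails the valid-value filter. All 25 planted interactors per bait are
recovered (10 of them shared, as planted), and the 40 planted frequent
background binders are eliminated — sticky proteins that sneak past the
MiST thresholds are caught by the repository filter. Each call in
`out/calls_FOSL1.tsv` carries its provenance:

```
prey        bait   score         igg_score     repo_frequency  rank_stat
PREY00021   FOSL1  0.9602860257  0.3414138849  0.007936507937  6.50262458
PREY00022   FOSL1  0.9555549788  0.3405697365  0.03174603175   6.431759714
```

`out/` also contains the collapsed log2 matrix, the full MiST record
table, SIF + node-attribute network files, heatmap-ready matrices with
missing values as `NA`, and `report.json` with per-stage survivor counts
and SHA-256 digests of every artifact. `apms enrich` runs a hypergeometric
over-representation test with Holm (Bonferroni step-down) correction
against GMT annotation sets.

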