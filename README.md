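# cpsort

Multi-class protein targeting prediction for diatoms and other algae with
complex plastids.

Nucleus-encoded proteins of plastids surrounded by four membranes travel
through the secretory pathway and carry a **bipartite targeting signal**: a
cleavable signal peptide followed by a transit peptide.  The same route
serves the **periplastidic compartment (PPC)** — the space between the
second and third plastid membranes, the former cytosol of the engulfed red
algal endosymbiont.  General-purpose predictors (TargetP, SignalP) see only
the signal peptide; `cpsort` layers on top of their output and scores the
conserved sequence motif around the signal-peptidase cleavage site to decide
whether an SP-bearing protein continues to the plastid, to the PPC, or stays
in the rest of the secretory pathway.  Mitochondrial (mTP) and untargeted
verdicts of the upstream predictor are forwarded unchanged, giving a
five-way classification: *plastid, PPC, SP-other, mitochondrion, other*.

It is intended for genome annotators and cell biologists working on
stramenopiles, cryptophytes, haptophytes and related lineages with complex
plastids of red algal origin.

## The scoring model

A scoring matrix is trained from aligned 25-residue windows spanning
positions −5..−1 (last signal-peptide residues) and +1..+20 (start of the
transit peptide; cleavage occurs between −1 and +1).  With f_i(a) the
observed frequency of residue *a* at column *i*:

    H_i   = − Σ_a f_i(a) · log₂ f_i(a)              (column entropy, bits)
    e_n   = (s − 1) / (2 · ln 2 · n),  s = 20       (small-sample correction)
    R_i   = log₂ 20 − (H_i + e_n)                   (information content)
    score_i(a) = f_i(a) · R_i                        (contribution, bits)

For each SP protein the 25-column window is scored at the predicted
cleavage site and its neighbours (±2 by default); the best-scoring site is
kept and the **transit-peptide score** (columns +1..+20 only) drives the
decision tree:

* transit score > 2.0 bits **and** the +1 residue is F, Y, W or L →
  *plastid, high confidence* (the hard-wired aromatic/leucine check);
* transit score > 0.0 bits → *plastid, low confidence*;
* otherwise, if a PPC matrix is configured: PPC transit score ≥ threshold
  and +1 **not** F/Y/W/L → *PPC* (PPC pre-sequences lack the conserved +1
  phenylalanine);
* otherwise → *SP-other*.

A *simple score cut-off* mode replaces the tiers with one threshold and no
+1 check, for custom matrices in organisms where the +1 constraint does not
hold.  Evaluation utilities provide K×K confusion matrices, the Gorodkin
R_K multi-class correlation, and per-class precision/recall/F1.

The package is organised as scikit-learn-style estimators —
`CleavageSiteMatrix` (fit a matrix from training windows) and
`TargetingClassifier` (configure thresholds, predict categories) — with
plain functions (`build_scoring_matrix`, `predict_batch`, `gorodkin_rk`, …)
layered on top, plus a `cpsort` command-line tool.

The packaged default matrices are rebuilt at load time from bundled
training-window files that mirror the published training-set sizes (166
plastid windows, 31 PPC windows).  The bundled windows are *synthetic*
stand-ins sampled from the package's profile generator (the real training
sequences are experimentally localised diatom proteins that are not
redistributed here); supply your own windows via `build-matrix` for real
analyses.

## Worked example

Simulate a small proteome with planted targeting signals (including the
matching emulated TargetP 2 short-format file), then classify it:

```bash
$ cpsort simulate --plan plan.yaml --seed 42 --conservation 0.9 -o sim
wrote 10 proteins to sim
$ cpsort predict sim/proteins.fasta --pred-file sim/targetp2.short -o results.tsv
classified 10 proteins -> results.tsv
$ head -6 results.tsv | cut -f1-9
id	input_category	cleavage_site	window_score	transit_score_plastid	transit_score_ppc	plus1_residue	category	confidence
syn0001_plastid	SP	16	21.618028	12.549786	0.000000	L	plastid	high
syn0002_plastid	SP	20	26.397966	17.329725	0.000000	F	plastid	high
syn0003_plastid	SP	18	25.312852	16.244610	0.000000	F	plastid	high
syn0004_PPC	SP	18	6.054348	0.000000	12.767458	E	PPC	none
syn0005_PPC	SP	23	9.068242	0.000000	15.472690	G	PPC	none
```

Reading the first row: the upstream predictor called an SP with cleavage
site 16; the best 25-residue window there scores 21.6 bits against the
plastid matrix, of which 12.5 bits come from the 20 transit-peptide
columns.  That exceeds the 2.0-bit high-confidence threshold and the +1
residue (L) passes the F/Y/W/L check, so the protein is called *plastid,
high confidence*.  The PPC-class proteins score 0 bits against the plastid
matrix but 12–15 bits against the PPC matrix, with a charged +1 residue —
hence *PPC*.

The same steps from Python:

```python
from cpsort import TargetingClassifier, read_fasta, parse_predictor_output

proteins = read_fasta("sim/proteins.fasta")
preds = {p.id: p for p in parse_predictor_output("sim/targetp2.short", "targetp2")}
clf = TargetingClassifier().fit()          # packaged plastid + PPC matrices
X = [(prot, preds[prot.id]) for prot in proteins]
print(clf.predict(X))                       # ['plastid' 'plastid' ... 'PPC' ...]
```

Other subcommands: `build-matrix` (train a matrix from 25-residue windows
in FASTA), `evaluate` (confusion matrix, R_K, per-class metrics from an
id/truth/predicted TSV, with optional category aggregation), `plot`
(per-position contribution figures, SVG/PNG).

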