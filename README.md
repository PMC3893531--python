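# stacklogo

Sequence logos for multiple sequence alignments and profile hidden Markov
models, built in one framework: the same letter-stack, gap-parameter and
rendering machinery serves both input kinds, so an alignment logo and the
logo of the profile HMM built from that alignment are directly comparable.

`stacklogo` is aimed at people who curate or inspect sequence families —
protein domains, RNA families, transposable elements — and want to see, per
position, how conserved the column is, which letters carry that
conservation, and (for profiles) how likely deletions and insertions are.

## The quantities drawn

For a column with estimated letter distribution **p** over an alphabet of
*L* letters (4 nucleotides or 20 amino acids) and a background distribution
**q**, the stack height is the column's information content (relative
entropy, in bits):

```
D(p‖q) = Σᵢ pᵢ · log₂(pᵢ / qᵢ)
```

`D` is 0 when the column looks like background and is maximal, `−log₂ qᵢ`,
for a column invariant in the letter that is rarest under the background:
2 bits for uniform-background DNA, ≈ 6.2 bits for an invariant tryptophan
column under the BLOSUM62-associated (Robinson–Robinson) amino background.

Three letter-height modes are available:

* **info_all** — every observed letter gets height `pᵢ · D` (the classic
  logo);
* **info_above_bg** — the same total height `D`, divided only among letters
  with positive log-odds score `sᵢ = log₂(pᵢ/qᵢ)`, which removes the smear
  of below-background letters that strong priors produce;
* **score** — each positive-scoring letter is drawn with height `sᵢ`; the
  stack total is then just a sum of scores with no conservation meaning.

Alignment columns can be estimated from **observed** counts, from
Henikoff–Henikoff position-based **weighted** counts (down-weighting
redundant sequences), or from weighted counts combined with a Dirichlet
prior (**weighted_prior**), whose posterior means pull sparse columns
toward the background. A column becomes a logo position when its occupancy
reaches `symfrac` (default 0.5; `symfrac 0` keeps every non-empty column).

Profile HMMs in HMMER3 text format are read directly: match-state emission
distributions give the stacks, and the transition table gives the three
gap rows drawn under the logo — occupancy (probability of visiting the
match state), insert probability (m→i), and expected insert length
`1/(1−ε)` from the insert self-transition ε — each cell shaded as a heat
map (blue = low occupancy, red = high insert values).

## Worked example

```python
import io
from stacklogo import read_alignment, build_logo

sto = """# STOCKHOLM 1.0
seq1 ACG-T
seq2 ACGAT
seq3 AC--T
//
"""
msa = read_alignment(io.StringIO(sto), "stockholm")
logo = build_logo(msa, method="observed", symfrac=0)
for pos in logo.positions:
    top = pos.stack[-1]
    print(f"pos {pos.position} (column {pos.source_column}): "
          f"info {pos.info_content:.2f} bits, occupancy {pos.occupancy:.2f}, "
          f"top letter {top[0]} ({top[1]:.2f} bits)")
```

prints

```
pos 1 (column 1): info 2.00 bits, occupancy 1.00, top letter A (2.00 bits)
pos 2 (column 2): info 2.00 bits, occupancy 1.00, top letter C (2.00 bits)
pos 3 (column 3): info 2.00 bits, occupancy 0.67, top letter G (2.00 bits)
pos 4 (column 4): info 2.00 bits, occupancy 0.33, top letter A (2.00 bits)
pos 5 (column 5): info 2.00 bits, occupancy 1.00, top letter T (2.00 bits)
```

Every residue-bearing column becomes a position (`symfrac=0`), each column
happens to be invariant in its observed letters (hence 2.00 bits under the
uniform DNA background), and the occupancy row records that columns 3 and 4
are mostly gaps. With `symfrac=0.5` position 4 (occupancy 0.33) would be
dropped; with `method="weighted_prior"` the single-residue column 4 would
be flattened toward background and lose most of its information content.

The same pipeline runs from the shell:

```sh
stacklogo build --in family.sto --method observed --symfrac 0 --json logo.json
stacklogo build --in family.hmm --mode score --svg logo.svg --png logo.png
stacklogo build --in family.hmm --overview overview.svg --overview-range 51:160
stacklogo fixtures --out-dir demo --seed 42   # synthetic inputs to play with
```

`--json` writes a versioned document carrying, per position, the stack, the
full per-letter probabilities and log-odds scores, occupancy and insert
values, and the source alignment column — everything an interactive viewer
needs for click-to-inspect display. `--svg`/`--png` draw the static image
with the gap-parameter table; `--overview` compresses letters into colored
bars so hundreds of positions fit one panel.

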