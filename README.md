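# zfdkit

Analysis toolkit for **zinc finger deaminase (ZFD) base editing**: simulation
of amplicon and whole-mitochondrial-genome sequencing reads with a planted
C·G→T·A deamination signal, alignment-based quantification of editing and
indel frequencies, genome-wide off-target calling with the specificity-ratio
statistic, and ZFD target-site / architecture design.

## Background

ZFDs are pairs of fusion proteins, each combining a custom zinc-finger
DNA-binding array with one inactive half of the split double-strand-DNA
cytidine deaminase DddA_tox_ and a uracil glycosylase inhibitor. When the two
monomers bind their half-sites (typically 12 bp each), the deaminase
reconstitutes over the intervening *spacer* (≈7–15 bp) and converts
cytosines there to uracil, read out after replication as C→T (or, for
cytosines on the opposite strand, G→A in reference coordinates). Because no
DNA backbone is cut, essentially no indels are produced. Editing prefers
cytosines preceded by a 5′ T (the **TC context**), works on both nuclear
and mitochondrial DNA, and — at high editor doses — produces genome-wide
off-target C·G→T·A edits in mtDNA whose abundance is summarized by the
**specificity ratio**

```
specificity ratio = mean editing frequency at on-target Cs
                    ───────────────────────────────────────
                    mean editing frequency at called off-target Cs
```

where off-target sites are C/G positions with a conversion rate ≥ 1%, after
excluding positions converted at ≥ 50% in *all* samples (cell-line SNVs) and
the on-target spacer itself.

Everything here runs on synthetic reads generated by the package's own
seeded simulator, which plants a known editing signal (per-position rates,
strand, context preference, heteroplasmy fractions, dose scaling) and emits
the ground truth separately, so recovery can be verified end to end. Real
FASTQ/FASTA/SAM/BED inputs are accepted through the same interfaces.

## Worked example

Quantify C→T editing across an 8-bp spacer from 10,000 simulated reads of a
200-nt amplicon (TC-context cytosines planted at rate 0.30, CC at 0.10,
GC at 0.05, 0.1% sequencing error):

```python
import numpy as np
from zfdkit import (Interval, align_records, build_pileup, indel_frequency,
                    make_editing_model, simulate_reads, substitution_table,
                    window_c2t)

rng = np.random.default_rng(11)
left = "".join(rng.choice(list("ACGT"), 90))
reference = left + "TCATCCGC" + "".join(rng.choice(list("ACGT"), 102))
spacer = Interval(90, 98)

model = make_editing_model(reference, spacer,
                           context_defaults={"TC": 0.30, "CC": 0.10, "GC": 0.05},
                           seq_error_rate=0.001)
reads, truth = simulate_reads(reference, model, 10_000, seed=7)
alignments = align_records(reads, reference)
table = substitution_table(build_pileup(alignments, reference), reference)
print(window_c2t(table, spacer).to_string(index=False))
print(f"window indel frequency: {100 * indel_frequency(alignments, spacer):.3f}%")
```

Output:

```
 pos label strand context   freq  missing
  92   C_2      +      TC 0.3019    False
  95   C_5      +      TC 0.2987    False
  96   C_6      +      CC 0.0969    False
  97   C_7      -      GC 0.0510    False
  98   C_8      +      GC 0.0496    False
window indel frequency: 0.000%
```

Each row is one spacer cytosine: `C_n` numbers it from the spacer's 5′ end
on the displayed strand, `strand` says which strand carries the edited C
(`-` rows are read as G→A in plus coordinates), and `freq` is the measured
conversion frequency — each within sampling error of its planted rate. The
indel frequency stays at zero because deamination never cuts the DNA; only
the substitution-error channel is active.

The same library drives whole-mtDNA off-target analysis
(`zfdkit.offtarget`: conversion tables, SNV masking, ≥1% calls, specificity
reports, context matrices, dose series) and design
(`zfdkit.design`: 24-architecture enumeration, site scanning, ZFN→ZFD
finger conversion, R(-5)Q variant). The `zfdkit` command line exposes
`simulate`, `amplicon`, `mito` and `design` subcommands driven by a YAML
manifest (see `zfdkit <cmd> --help`).

## Layout

- `src/zfdkit/simulate.py` — references, pTarget constructs, editing models, read simulators
- `src/zfdkit/align.py` — semi-global affine-gap alignment, pileups
- `src/zfdkit/quant.py` — substitution tables, editing windows, alleles, clones
- `src/zfdkit/offtarget.py` — genome-wide conversion, masking, calls, specificity
- `src/zfdkit/design.py` — architectures, site scanning, finger plans, QQ variant
- `src/zfdkit/pipeline.py`, `cli.py` — manifest-driven runs and the CLI
- `docs/methods.md` — models, conventions and numerical choices
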